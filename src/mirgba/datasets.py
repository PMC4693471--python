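"""Bundled reference tables.

The package ships the published catalogue of 21 circulating miRNAs with
significant genotype-by-age interaction in serum of Ames dwarf and
normal mice: per-miRNA family assignment, average CPM, and signed fold
change / p-value / FDR for the age effect within each genotype and for
the interaction, plus the reported pattern letter. These printed
numbers serve as worked-example inputs for the pattern classifier, the
signed interaction fold-change arithmetic and the family accounting.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_gba_table", "reference_family_map"]


def load_reference_gba_table() -> pd.DataFrame:
    """The 21-row serum GbA miRNA catalogue, indexed by mature miRNA."""
    ref = resources.files("mirgba.data").joinpath("ames_serum_gba_mirnas.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return df.set_index("mirna")


def reference_family_map() -> dict[str, str]:
    """Mature-miRNA -> family map implied by the reference catalogue."""
    df = load_reference_gba_table()
    return df["family"].to_dict()
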