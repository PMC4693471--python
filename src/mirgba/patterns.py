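"""Genotype-by-age (GbA) expression-pattern classification.

A feature enters the GbA set when its interaction fold change and FDR
pass the inclusion thresholds. Its direction of change with age is then
assessed separately within each genotype (signed FC magnitude and raw
p-value thresholds), giving a (direction in Normal, direction in Dwarf)
pair. The four combinations observed in serum get letter labels:

    A = (up, none)    B = (down, none)
    C = (down, up)    D = (none, up)

any other combination gets a descriptive ``other(dirN,dirD)`` label.
Boundary semantics follow the reporting convention: fold-change
thresholds are inclusive (>= for the age effect, > for the interaction),
p-value and FDR thresholds strict (<).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PatternThresholds", "classify", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = (
    "fc_normal",
    "p_normal",
    "fc_dwarf",
    "p_dwarf",
    "fc_gba",
    "fdr_gba",
)

_LETTER = {
    ("up", "none"): "A",
    ("down", "none"): "B",
    ("down", "up"): "C",
    ("none", "up"): "D",
}


@dataclass(frozen=True)
class PatternThresholds:
    """Inclusion and direction thresholds for GbA pattern calls."""

    age_fc_min: float = 1.5
    age_p_max: float = 0.05
    gba_fc_min: float = 1.5
    gba_fdr_max: float = 0.10

    def __post_init__(self):
        if self.age_fc_min <= 0 or self.gba_fc_min <= 0:
            raise ValueError("fold-change thresholds must be positive")
        for v in (self.age_p_max, self.gba_fdr_max):
            if not 0 < v <= 1:
                raise ValueError("p/FDR thresholds must lie in (0, 1]")


def _direction(fc: np.ndarray, p: np.ndarray, t: PatternThresholds) -> np.ndarray:
    sig = (np.abs(fc) >= t.age_fc_min) & (p < t.age_p_max)
    return np.where(sig, np.where(fc > 0, "up", "down"), "none")


def classify(
    de_results: pd.DataFrame,
    thresholds: PatternThresholds = PatternThresholds(),
) -> pd.DataFrame:
    """Call GbA patterns from a per-feature three-contrast result table.

    ``de_results`` must carry signed fold changes and p-values for the
    age effect within each genotype plus the interaction FC and FDR
    (columns ``fc_normal, p_normal, fc_dwarf, p_dwarf, fc_gba,
    fdr_gba``). If a ``pattern`` column of previously reported labels is
    present, rows whose strict call disagrees are flagged in a
    ``conflict`` column rather than overridden.

    Returns a DataFrame indexed like the input with columns
    ``included``, ``direction_normal``, ``direction_dwarf``, ``label``
    and ``conflict``. Non-included features carry an empty label.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in de_results.columns]
    if missing:
        raise ValueError(f"de_results is missing required columns: {missing}")
    t = thresholds
    fc_gba = de_results["fc_gba"].to_numpy(dtype=float)
    fdr_gba = de_results["fdr_gba"].to_numpy(dtype=float)
    included = (np.abs(fc_gba) > t.gba_fc_min) & (fdr_gba < t.gba_fdr_max)

    dir_n = _direction(
        de_results["fc_normal"].to_numpy(float),
        de_results["p_normal"].to_numpy(float),
        t,
    )
    dir_d = _direction(
        de_results["fc_dwarf"].to_numpy(float),
        de_results["p_dwarf"].to_numpy(float),
        t,
    )
    labels = np.array(
        [
            _LETTER.get((n, d), f"other({n},{d})") if inc else ""
            for n, d, inc in zip(dir_n, dir_d, included)
        ],
        dtype=object,
    )
    out = pd.DataFrame(
        {
            "included": included,
            "direction_normal": np.where(included, dir_n, "none"),
            "direction_dwarf": np.where(included, dir_d, "none"),
            "label": labels,
        },
        index=de_results.index,
    )
    if "pattern" in de_results.columns:
        reported = de_results["pattern"].astype(str).to_numpy()
        out["conflict"] = included & (reported != labels)
    else:
        out["conflict"] = False
    return out
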