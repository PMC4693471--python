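"""GbA differential abundance of 5' tRNA halves at the isoacceptor level.

A thin application of the same NB GLM machinery used for miRNAs to
isoacceptor-aggregated 5'-half counts (rows like "His-GTG"). tRNA-half
catalogues are small, so the report uses deliberately relaxed default
thresholds (raw P < 0.05, FDR < 0.28); these are exploratory cut-offs,
exposed as parameters rather than endorsed.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .model import GbaModel, GbaResults

__all__ = ["trna_gba"]


def trna_gba(
    isoacceptor_counts: pd.DataFrame,
    design: pd.DataFrame,
    p_max: float = 0.05,
    fdr_max: float = 0.28,
    lib_sizes=None,
    **fit_kwargs,
) -> tuple[pd.DataFrame, GbaResults]:
    """GbA analysis of isoacceptor-level 5'-half counts.

    All-zero isoacceptor rows carry no information and are excluded
    (noted in ``report.attrs['excluded_all_zero']``). Returns the
    filtered report -- rows passing the raw-P/FDR thresholds on the
    interaction -- together with the full :class:`GbaResults` so the
    unfiltered table stays available. The underlying computation is the
    identical normalization/dispersion/GLM/LRT path used for miRNA
    counts.
    """
    counts = isoacceptor_counts.copy()
    zero = counts.sum(axis=1) == 0
    excluded = list(counts.index[zero])
    counts = counts.loc[~zero]
    if len(counts) < 2:
        warnings.warn(
            "fewer than 2 non-zero isoacceptors; results will be unstable",
            stacklevel=2,
        )
    if len(counts) == 0:
        raise ValueError("no non-zero isoacceptor rows to analyze")
    results = GbaModel(counts, design, lib_sizes=lib_sizes).fit(**fit_kwargs)
    table = results.table
    keep = (table["p_gba"] < p_max) & (table["fdr_gba"] < fdr_max)
    report = table.loc[keep].copy()
    # direction of the age effect within each genotype at the same
    # relaxed significance (FC magnitude >= 1.5, raw P below p_max)
    for suffix in ("normal", "dwarf"):
        fc = report[f"fc_{suffix}"]
        p = report[f"p_{suffix}"]
        sig = (fc.abs() >= 1.5) & (p < p_max)
        report[f"direction_{suffix}"] = np.where(
            sig, np.where(fc > 0, "up", "down"), "none"
        )
    report.attrs["excluded_all_zero"] = excluded
    return report, results
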