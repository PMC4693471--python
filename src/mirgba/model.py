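"""The GbA differential-abundance model and its fitted results.

:class:`GbaModel` ties the count-level machinery together for the 2x2
serum design: TMM normalization, Cox-Reid dispersion estimation, NB GLM
fitting with the design ``~Genotype + Genotype:Age`` (Young and Normal
as references), and likelihood-ratio tests for the three contrasts of
interest -- the age effect within Normal mice (coefficient 3), the age
effect within Dwarf mice (coefficient 4), and the genotype-by-age
interaction (contrast (0, 0, -1, 1), i.e. the difference of the two
age effects). :class:`GbaResults` carries the per-feature estimates,
p-values and BH FDRs (adjusted within each contrast family separately),
exposes pattern classification, and renders report tables on the signed
fold-change scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import families as fam
from .dispersion import DispersionEstimates, estimate_dispersions
from .glm import NBGLMFit, fit_nbglm, lrt
from .normalization import mean_cpm, tmm_norm_factors
from .patterns import PatternThresholds, classify
from .simulate import DESIGN_COLUMNS, design_matrix
from .stats import bh_fdr, signed_fc

__all__ = ["GbaModel", "GbaResults", "CONTRASTS"]

# contrast name -> (coefficient index | contrast vector)
CONTRASTS = {
    "age_in_normal": 2,
    "age_in_dwarf": 3,
    "gba": np.array([0.0, 0.0, -1.0, 1.0]),
}


class GbaModel:
    """NB GLM of feature counts under the genotype-by-age design.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer feature x sample matrix; columns must match the design's
        sample ids.
    design : pandas.DataFrame
        Study design with columns ``sample_id``, ``genotype`` in
        {Normal, Dwarf} and ``age`` in {Young, Old}.
    lib_sizes : array-like, optional
        Per-sample sequencing depths; column sums by default.

    Examples
    --------
    >>> counts, design, truth = simulate_counts(SimulationConfig(seed=1))
    >>> res = GbaModel(counts, design).fit()
    >>> res.table.head()
    """

    def __init__(self, counts: pd.DataFrame, design: pd.DataFrame, lib_sizes=None):
        if not isinstance(counts, pd.DataFrame):
            counts = pd.DataFrame(counts)
        missing = {"sample_id", "genotype", "age"} - set(design.columns)
        if missing:
            raise ValueError(f"design table is missing columns: {sorted(missing)}")
        if list(counts.columns) != list(design["sample_id"]):
            counts = counts.loc[:, list(design["sample_id"])]
        y = counts.to_numpy()
        if np.any(y < 0):
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.design = design.reset_index(drop=True)
        self.design_matrix = design_matrix(self.design)
        cells = design.groupby(["genotype", "age"]).size()
        if (cells < 2).any():
            raise ValueError(
                "each genotype x age cell needs >= 2 samples for dispersion "
                "estimation"
            )
        if lib_sizes is None:
            lib_sizes = y.sum(axis=0)
        self.lib_sizes = np.asarray(lib_sizes, dtype=float)
        if np.any(self.lib_sizes <= 0):
            raise ValueError("library sizes must be positive")

    @classmethod
    def from_tsv(cls, counts_path, design_path) -> "GbaModel":
        """Build the model from counts and design TSV files."""
        from .io import read_counts_tsv, read_design_tsv

        counts = read_counts_tsv(counts_path)
        design = read_design_tsv(design_path)
        return cls(counts, design)

    def fit(
        self,
        dispersion: str | float = "tagwise",
        prior_df: float = 10.0,
        min_cpm: Optional[float] = None,
    ) -> "GbaResults":
        """Normalize, estimate dispersions, fit the GLM and run the LRTs.

        Parameters
        ----------
        dispersion : {"tagwise", "trended", "common"} or float
            Which dispersion estimate the GLM and tests use; a float
            fixes it (useful for calibration studies and oracles).
        prior_df : float
            Prior degrees of freedom of the tagwise shrinkage.
        min_cpm : float, optional
            If given, features with mean CPM below it are dropped
            before fitting. Off by default: low-abundance features are
            retained, as single-digit-CPM species can still carry
            interaction signal.
        """
        counts = self.counts
        y = counts.to_numpy(dtype=float)
        lib = self.lib_sizes
        factors = tmm_norm_factors(y, lib)
        offsets = np.log(lib * factors)
        X = self.design_matrix.to_numpy()

        cpm_mean = mean_cpm(y, lib, factors)
        if min_cpm is not None:
            keep = cpm_mean >= min_cpm
            counts = counts.loc[keep]
            y = y[keep]
            cpm_mean = cpm_mean[keep]

        estimates: Optional[DispersionEstimates] = None
        if isinstance(dispersion, str):
            estimates = estimate_dispersions(y, X, offsets, prior_df=prior_df)
            if dispersion == "common":
                phi = estimates.common
            elif dispersion == "trended":
                phi = estimates.trended
            elif dispersion == "tagwise":
                phi = estimates.tagwise
            else:
                raise ValueError(f"unknown dispersion mode {dispersion!r}")
        else:
            phi = float(dispersion)
            if phi < 0:
                raise ValueError("dispersion must be non-negative")

        glm_fit = fit_nbglm(y, X, offsets, phi)
        if not glm_fit.converged.all():
            warnings.warn(
                f"{int((~glm_fit.converged).sum())} features did not converge; "
                "last IRLS iterate used",
                stacklevel=2,
            )

        table = pd.DataFrame({"cpm": cpm_mean}, index=counts.index)
        for name, which in CONTRASTS.items():
            if isinstance(which, (int, np.integer)):
                stat, pval, log2fc = lrt(y, X, offsets, phi, coef=which, fit=glm_fit)
            else:
                stat, pval, log2fc = lrt(
                    y, X, offsets, phi, contrast=which, fit=glm_fit
                )
            suffix = {"age_in_normal": "normal", "age_in_dwarf": "dwarf", "gba": "gba"}[
                name
            ]
            table[f"log2fc_{suffix}"] = log2fc
            table[f"fc_{suffix}"] = signed_fc(log2fc)
            table[f"p_{suffix}"] = pval
            table[f"fdr_{suffix}"] = bh_fdr(pval)

        return GbaResults(
            model=self,
            table=table,
            norm_factors=factors,
            offsets=offsets,
            dispersions=estimates,
            dispersion_used=np.broadcast_to(
                np.asarray(phi, dtype=float), (y.shape[0],)
            ).copy(),
            glm_fit=glm_fit,
        )


@dataclass
class GbaResults:
    """Fitted GbA differential-abundance results.

    ``table`` holds one row per feature with mean CPM and, for each of
    the three contrasts, the log2 and signed fold change, the raw LRT
    p-value and the BH FDR (columns suffixed ``_normal``, ``_dwarf``,
    ``_gba``). Fold changes are kept at full precision here; rounding
    to the 1-decimal reporting convention happens only in
    :meth:`report`.
    """

    model: GbaModel
    table: pd.DataFrame
    norm_factors: np.ndarray
    offsets: np.ndarray
    dispersions: Optional[DispersionEstimates]
    dispersion_used: np.ndarray
    glm_fit: NBGLMFit = field(repr=False, default=None)

    def classify_patterns(
        self, thresholds: PatternThresholds = PatternThresholds()
    ) -> pd.DataFrame:
        """GbA pattern calls (see :mod:`mirgba.patterns`)."""
        return classify(self.table, thresholds)

    def report(
        self,
        thresholds: PatternThresholds = PatternThresholds(),
        family_map: Optional[dict] = None,
        include_all: bool = False,
    ) -> pd.DataFrame:
        """Display-ready table of included GbA features.

        Signed fold changes are rounded to 1 decimal and p/FDR to 3
        decimals, mirroring the reporting convention; ``include_all``
        keeps non-included features too.
        """
        calls = self.classify_patterns(thresholds)
        out = pd.DataFrame(index=self.table.index)
        if family_map is not None:
            out["family"] = fam.map_families(list(self.table.index), family_map)
        out["cpm"] = self.table["cpm"].round(0).astype(int)
        for suffix in ("normal", "dwarf", "gba"):
            out[f"fc_{suffix}"] = self.table[f"fc_{suffix}"].round(1)
            out[f"p_{suffix}"] = self.table[f"p_{suffix}"].round(3)
            out[f"fdr_{suffix}"] = self.table[f"fdr_{suffix}"].round(3)
        out["pattern"] = calls["label"]
        out["conflict"] = calls["conflict"]
        if include_all:
            return out
        return out.loc[calls["included"]]

    def summary(self) -> str:
        """Human-readable fit summary."""
        t = self.table
        n_feat = len(t)
        design = self.model.design
        lines = [
            "Genotype-by-age NB GLM results",
            "=" * 38,
            f"features: {n_feat}    samples: {len(design)}",
            "design: ~Genotype + Genotype:Age "
            f"(columns: {', '.join(DESIGN_COLUMNS)})",
        ]
        if self.dispersions is not None:
            d = self.dispersions
            lines.append(
                f"dispersion: common={d.common:.4f} (BCV {d.bcv:.3f}), "
                f"tagwise median={np.nanmedian(d.tagwise):.4f}"
            )
        else:
            lines.append(
                f"dispersion: fixed at {float(np.median(self.dispersion_used)):.4f}"
            )
        lines.append(
            "TMM factors: "
            + ", ".join(f"{f:.3f}" for f in self.norm_factors)
        )
        calls = self.classify_patterns()
        inc = calls["included"]
        lines.append(
            f"GbA features (|FC|>1.5, FDR<0.1): {int(inc.sum())} of {n_feat}"
        )
        if inc.any():
            counts = calls.loc[inc, "label"].value_counts().sort_index()
            lines.append(
                "patterns: " + ", ".join(f"{k}={v}" for k, v in counts.items())
            )
        return "\n".join(lines)
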