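"""Library-size normalization for small-RNA count matrices.

Trimmed mean of M-values (TMM) scale factors and counts-per-million.
TMM picks a reference sample, computes gene-wise log expression ratios
(M) and average log abundances (A) against it for each other sample,
double-trims the M and A distributions, and averages the surviving M
values with inverse asymptotic-variance (delta-method binomial) weights.
Factors are rescaled so their geometric mean is exactly 1, which keeps
CPM comparable across runs.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["tmm_norm_factors", "cpm", "mean_cpm"]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
    weighted: bool,
) -> float:
    """TMM factor (log2 scale) of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if not np.any(keep):
        warnings.warn(
            "sample shares no co-expressed features with the reference; "
            "normalization factor set to 1",
            stacklevel=3,
        )
        return 0.0
    o = obs[keep] / lib_obs
    r = ref[keep] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic variance of M under binomial sampling (delta method)
    v = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (lib_ref - ref[keep]) / (
        lib_ref * ref[keep]
    )
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = int(np.floor(n * logratio_trim)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * sum_trim)) + 1
    hi_a = n + 1 - lo_a
    rank_m = np.argsort(np.argsort(m, kind="mergesort"), kind="mergesort") + 1
    rank_a = np.argsort(np.argsort(a, kind="mergesort"), kind="mergesort") + 1
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2):
        return 0.0
    if weighted:
        w = 1.0 / v[keep2]
        f = np.sum(w * m[keep2]) / np.sum(w)
    else:
        f = np.mean(m[keep2])
    if not np.isfinite(f):
        return 0.0
    return float(f)


def tmm_norm_factors(
    counts,
    lib_sizes=None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors.

    Parameters
    ----------
    counts : array-like, shape (n_features, n_samples)
        Raw non-negative counts.
    lib_sizes : array-like, optional
        Per-sample library sizes; column sums by default.
    logratio_trim, sum_trim : float
        Fraction trimmed from *each* tail of the M and A distributions
        (defaults 30% and 5%).
    weighted : bool
        Use inverse asymptotic-variance precision weights.

    Returns
    -------
    numpy.ndarray
        Positive per-sample factors with geometric mean 1. Effective
        library size is ``lib_size * factor``.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("counts must be a features x samples matrix with >= 2 samples")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if lib_sizes is None:
        lib = y.sum(axis=0)
    else:
        lib = np.asarray(lib_sizes, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")

    # reference: sample whose upper-quartile CPM is closest to the mean
    with np.errstate(invalid="ignore"):
        uq = np.array(
            [np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])]
        )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.array(
        [
            _tmm_pair(
                y[:, j], y[:, ref_idx], lib[j], lib[ref_idx],
                logratio_trim, sum_trim, weighted,
            )
            for j in range(y.shape[1])
        ]
    )
    factors = np.exp2(log_factors)
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def cpm(counts, lib_sizes=None, norm_factors=None) -> np.ndarray:
    """Counts per million over effective library sizes.

    ``cpm = count / (lib_size * factor) * 1e6``. Doubling all counts and
    library sizes leaves the result unchanged.
    """
    y = np.asarray(counts, dtype=float)
    lib = y.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    f = np.ones_like(lib) if norm_factors is None else np.asarray(norm_factors, float)
    return y / (lib * f) * 1e6


def mean_cpm(counts, lib_sizes=None, norm_factors=None) -> np.ndarray:
    """Per-feature average CPM across samples (the report's CPM column)."""
    return cpm(counts, lib_sizes, norm_factors).mean(axis=1)
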