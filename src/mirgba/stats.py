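"""Small statistical helpers shared across the analysis.

Implements the signed fold-change convention used throughout serum
small-RNA reports (a ratio r < 1 is printed as -1/r, so FC = 1 means no
change and the sign carries the direction), and the Benjamini-Hochberg
step-up adjustment used for every multiple-testing correction in the
pipeline.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bh_fdr", "signed_fc", "signed_fc_to_log2", "gba_fc"]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Parameters
    ----------
    p_values : array-like
        Raw p-values in [0, 1]. NaN entries propagate to NaN and are not
        counted in the number of tests.

    Returns
    -------
    numpy.ndarray
        Monotone step-up adjusted values, capped at 1, same order as the
        input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    pf = p[finite]
    m = pf.size
    if m == 0:
        return out
    order = np.argsort(pf, kind="mergesort")
    ranked = pf[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    result = np.empty(m)
    result[order] = adj
    out[finite] = result
    return out


def signed_fc(log2fc):
    """Convert a log2 fold change to the signed fold-change convention.

    FC = 2**log2fc when log2fc >= 0, else -2**(-log2fc); FC(0) = 1, so
    |FC| >= 1 always and the sign encodes the direction of change.
    """
    lfc = np.asarray(log2fc, dtype=float)
    fc = np.where(lfc >= 0, np.exp2(lfc), -np.exp2(-lfc))
    return fc if fc.ndim else float(fc)


def signed_fc_to_log2(fc):
    """Inverse of :func:`signed_fc`: signed fold change back to log2."""
    f = np.asarray(fc, dtype=float)
    if np.any(np.abs(f) < 1):
        raise ValueError("signed fold changes have magnitude >= 1")
    lfc = np.where(f >= 0, np.log2(np.abs(f)), -np.log2(np.abs(f)))
    return lfc if lfc.ndim else float(lfc)


def gba_fc(fc_dwarf, fc_normal):
    """Signed genotype-by-age interaction fold change.

    The interaction is the difference of the within-genotype age effects
    on the log2 scale, reported back on the signed fold-change scale:
    ``signed_fc(log2fc_dwarf - log2fc_normal)``.
    """
    return signed_fc(
        np.asarray(signed_fc_to_log2(fc_dwarf))
        - np.asarray(signed_fc_to_log2(fc_normal))
    )
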