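"""Permutation enrichment of tissue-specific miRNA signatures.

Tests whether a focal miRNA set (the GbA miRNAs) overlaps a tissue
signature more than random sets of the same size drawn from a stated
miRNA universe. Each permutation draws |focal| miRNAs without
replacement and records the overlap with the signature; the empirical
p-value uses the +1 pseudocount convention so it is never exactly zero:

    P = (1 + #{permutation overlap >= observed}) / (1 + n_perm)

Because sampling without replacement makes the null overlap exactly
hypergeometric, an exact mode is offered as a fast path; the default
remains the permutation estimate (one million draws).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats as sps

__all__ = ["EnrichmentResult", "permutation_enrichment"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed overlap and its enrichment p-value."""

    observed: int
    p_value: float
    n_focal: int
    n_signature_in_universe: int
    n_universe: int
    n_perm: Optional[int]  # None for the exact hypergeometric path
    seed: Optional[int]


def permutation_enrichment(
    gba_set: Iterable[str],
    signature: Iterable[str],
    universe: Iterable[str],
    n_perm: int = 1_000_000,
    seed: Optional[int] = None,
    exact: bool = False,
    chunk: int = 20_000,
) -> EnrichmentResult:
    """Enrichment of a signature within the focal miRNA set.

    Parameters
    ----------
    gba_set : focal miRNAs; must be a subset of ``universe``.
    signature : tissue signature miRNAs; members outside the universe
        are ignored for the null (the subset relation is reported via
        ``n_signature_in_universe``, not assumed).
    universe : the miRNA vocabulary permuted over. Which universe is
        appropriate (all detected miRNAs vs all annotated) is a design
        choice of the caller.
    n_perm : number of random draws (default one million).
    exact : compute the hypergeometric tail instead of permuting.
    """
    uni = sorted(set(map(str, universe)))
    focal = set(map(str, gba_set))
    if not focal <= set(uni):
        raise ValueError("gba_set must be a subset of the universe")
    if len(focal) > len(uni):
        raise ValueError("focal set larger than the universe")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sig_in_uni = set(map(str, signature)) & set(uni)
    observed = len(focal & sig_in_uni)
    M, S, n = len(uni), len(sig_in_uni), len(focal)

    if exact:
        p = float(sps.hypergeom.sf(observed - 1, M, S, n))
        return EnrichmentResult(observed, p, n, S, M, None, seed)

    rng = np.random.default_rng(seed)
    indicator = np.zeros(M, dtype=bool)
    sig_index = {m: i for i, m in enumerate(uni)}
    for m in sig_in_uni:
        indicator[sig_index[m]] = True
    exceed = 0
    remaining = n_perm
    while remaining > 0:
        c = min(chunk, remaining)
        # draw c independent size-n subsets via random-key partial sort
        keys = rng.random((c, M))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        overlaps = indicator[idx].sum(axis=1)
        exceed += int(np.count_nonzero(overlaps >= observed))
        remaining -= c
    p = (1 + exceed) / (1 + n_perm)
    return EnrichmentResult(observed, float(p), n, S, M, n_perm, seed)
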