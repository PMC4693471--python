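"""Per-gene miRNA overtargeting analysis and network construction.

A gene is "overtargeted" by a focal miRNA set (here, the GbA miRNAs)
when significantly more of its predicted targeting miRNAs belong to the
focal set than expected under sampling without replacement from the
interaction universe. For a gene targeted by n of the universe's M
miRNAs, of which k are among the K focal miRNAs, the upper-tail
hypergeometric probability

    P = sum_{i=k}^{min(n, K)} C(K, i) C(M-K, n-i) / C(M, n)

is computed per gene and BH-adjusted across genes. Interactions are
collapsed to binary miRNA-gene pairs before testing: multiple predicted
sites for the same pair would violate the without-replacement sampling
model. The significant set (P < 0.05 and FDR < 0.10), optionally
restricted further by a functional gene-set filter, defines the edges
of the exported miRNA-mRNA network.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["InteractionUniverse", "overtarget_test", "build_network"]


class InteractionUniverse:
    """Binary miRNA -> gene interaction universe.

    Built from a DataFrame with ``mirna`` and ``gene`` columns (extra
    columns such as context scores are carried along but ignored by the
    test). Duplicate pairs -- e.g. multiple predicted sites -- are
    collapsed. When a family map is supplied, miRNA tokens are
    normalized to family tokens first, which lets mature-miRNA queries
    match family-keyed universes.
    """

    def __init__(
        self,
        interactions: pd.DataFrame,
        family_map: Optional[Mapping[str, str]] = None,
    ):
        cols = set(interactions.columns)
        if not {"mirna", "gene"} <= cols:
            raise ValueError("interactions need 'mirna' and 'gene' columns")
        df = interactions[["mirna", "gene"]].astype(str)
        self.family_map = dict(family_map) if family_map else None
        if self.family_map:
            df = df.assign(mirna=df["mirna"].map(lambda m: self.family_map.get(m, m)))
        self.pairs = df.drop_duplicates().reset_index(drop=True)
        self.mirnas = set(self.pairs["mirna"])
        self.genes = set(self.pairs["gene"])
        self._gene_targets = {
            g: set(sub["mirna"]) for g, sub in self.pairs.groupby("gene")
        }

    @property
    def m(self) -> int:
        """Distinct miRNA vocabulary size M."""
        return len(self.mirnas)

    def gene_targets(self, gene: str) -> set[str]:
        return self._gene_targets.get(gene, set())

    def normalize_query(self, mirnas: Iterable[str]) -> tuple[set[str], list[str]]:
        """Intersect a query miRNA set with the vocabulary.

        Returns (present, absent); family normalization is applied when
        a family map is attached.
        """
        q = list(mirnas)
        if self.family_map:
            q = [self.family_map.get(m, m) for m in q]
        present = {m for m in q if m in self.mirnas}
        absent = sorted({m for m in q if m not in self.mirnas})
        return present, absent


def overtarget_test(
    universe: InteractionUniverse | pd.DataFrame,
    gba_mirnas: Iterable[str],
    p_max: float = 0.05,
    fdr_max: float = 0.10,
) -> pd.DataFrame:
    """Hypergeometric overtargeting test for every gene in the universe.

    Returns a DataFrame indexed by gene with columns ``k`` (focal
    miRNAs targeting the gene), ``n`` (all miRNAs targeting it), ``K``
    (focal miRNAs in the universe), ``M`` (universe vocabulary size),
    ``p``, ``fdr`` and ``significant`` (P < p_max and FDR < fdr_max).
    Focal miRNAs absent from the universe vocabulary are dropped and
    listed in ``result.attrs['absent_mirnas']``; an empty intersection
    is an error.
    """
    if not isinstance(universe, InteractionUniverse):
        universe = InteractionUniverse(universe)
    focal, absent = universe.normalize_query(gba_mirnas)
    if not focal:
        raise ValueError(
            "none of the focal miRNAs occur in the universe vocabulary: "
            f"{absent}"
        )
    M = universe.m
    K = len(focal)
    genes = sorted(universe.genes)
    k = np.empty(len(genes), dtype=int)
    n = np.empty(len(genes), dtype=int)
    for i, gene in enumerate(genes):
        targets = universe.gene_targets(gene)
        n[i] = len(targets)
        k[i] = len(targets & focal)
    p = sps.hypergeom.sf(k - 1, M, K, n)
    res = pd.DataFrame(
        {"k": k, "n": n, "K": K, "M": M, "p": p, "fdr": _bh(p)},
        index=pd.Index(genes, name="gene"),
    )
    res["significant"] = (res["p"] < p_max) & (res["fdr"] < fdr_max)
    res.attrs["absent_mirnas"] = absent
    return res.sort_values("p")


def _bh(p):
    from .stats import bh_fdr

    return bh_fdr(p)


def build_network(
    significant_genes: Sequence[str],
    gba_mirnas: Iterable[str],
    universe: InteractionUniverse | pd.DataFrame,
    functional_gene_sets: Optional[Mapping[str, Iterable[str]]] = None,
    mirna_signs: Optional[Mapping[str, str]] = None,
) -> nx.DiGraph:
    """Directed miRNA -> gene network over the double-filtered interactions.

    Edges are the universe interactions between focal miRNAs and
    significantly overtargeted genes; if functional gene sets are
    supplied, genes are additionally restricted to set members (the
    second filter) and tagged with the sets they belong to. Node
    attributes carry the role ("mirna"/"gene") and, when provided, the
    miRNA's GbA sign.
    """
    if not isinstance(universe, InteractionUniverse):
        universe = InteractionUniverse(universe)
    focal, _ = universe.normalize_query(gba_mirnas)
    genes = set(map(str, significant_genes)) & universe.genes
    if functional_gene_sets:
        members = {}
        for name, gene_set in functional_gene_sets.items():
            for g in gene_set:
                members.setdefault(str(g), []).append(name)
        genes &= set(members)
    graph = nx.DiGraph()
    for _, row in universe.pairs.iterrows():
        mirna, gene = row["mirna"], row["gene"]
        if mirna in focal and gene in genes:
            graph.add_edge(mirna, gene)
    for node in graph.nodes:
        if node in focal:
            graph.nodes[node]["role"] = "mirna"
            if mirna_signs and node in mirna_signs:
                graph.nodes[node]["gba_sign"] = mirna_signs[node]
        else:
            graph.nodes[node]["role"] = "gene"
            if functional_gene_sets:
                graph.nodes[node]["gene_sets"] = ",".join(members.get(node, []))
    return graph
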