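"""Synthetic data generators with known ground truth.

Three independent generators stand in for the study's raw inputs:

* :func:`simulate_counts` draws feature x sample NB count matrices for
  a 2x2 genotype (Normal / Dwarf) by age (Young / Old) serum design,
  with features planted in the four genotype-by-age (GbA) interaction
  patterns -- A (up with age in Normal, flat in Dwarf), B (down in
  Normal, flat in Dwarf), C (down in Normal, up in Dwarf), D (flat in
  Normal, up in Dwarf) -- the remainder null;

* :func:`simulate_reads` draws aligned-read intervals over a toy
  genome of miRNA and tRNA loci, miRNA reads 20-24 nt and tRNA reads
  30-33 nt anchored at the tRNA 5' end (the circulating 5'-half
  species), with a configurable class split (default 76% tRNA / 24%
  miRNA);

* :func:`simulate_universe` draws a binary miRNA -> gene interaction
  universe in which designated "planted" genes receive an excess of
  interactions from the focal GbA miRNA set.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationRecord, AnnotationSet, ReadRecord

__all__ = [
    "SimulationConfig",
    "ReadSimConfig",
    "make_design",
    "simulate_counts",
    "simulate_reads",
    "simulate_universe",
    "DESIGN_COLUMNS",
]

GENOTYPES = ("Normal", "Dwarf")
AGES = ("Young", "Old")
PATTERNS = ("A", "B", "C", "D")
DESIGN_COLUMNS = ("Intercept", "GenotypeDwarf", "Normal:AgeOld", "Dwarf:AgeOld")

# amino acid / anticodon pairs cycled over when naming synthetic tRNA loci
_ISOACCEPTORS = (
    ("His", "GTG"), ("Cys", "GCA"), ("Lys", "CTT"), ("Asp", "GTC"),
    ("Pro", "AGG"), ("Pro", "TGG"), ("Gly", "GCC"), ("Glu", "CTC"),
    ("Val", "CAC"), ("Ala", "AGC"),
)


@dataclass
class SimulationConfig:
    """Parameters of the NB count simulation.

    The defaults mirror the study conditions: five female mice per
    genotype x age cell, NB dispersion 0.16 (biological CV 0.4, typical
    for serum small-RNA counts), baseline abundances spanning roughly
    3-2000 CPM, and planted interaction fold changes of magnitude >= 1.5.
    """

    n_features: int = 500
    n_per_cell: int = 5
    baseline_log_mean_range: tuple[float, float] = (-18.0, -9.0)
    dispersion: float = 0.16
    lib_size_range: tuple[float, float] = (1e6, 3e6)
    frac_pattern_a: float = 0.02
    frac_pattern_b: float = 0.06
    frac_pattern_c: float = 0.02
    frac_pattern_d: float = 0.01
    effect_size_fc: float = 4.0
    genotype_effect_log2: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 1 or self.n_per_cell < 2:
            raise ValueError(
                "need at least 1 feature and 2 samples per cell "
                "(dispersion estimation requires replication)"
            )
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        fracs = (
            self.frac_pattern_a,
            self.frac_pattern_b,
            self.frac_pattern_c,
            self.frac_pattern_d,
        )
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ValueError("pattern fractions must be non-negative and sum to <= 1")
        if self.effect_size_fc < 1:
            raise ValueError("effect_size_fc is a fold-change magnitude >= 1")
        if not (0 < self.lib_size_range[0] <= self.lib_size_range[1]):
            raise ValueError("lib_size_range must be positive and ordered")


def make_design(n_per_cell: int = 5) -> pd.DataFrame:
    """Balanced 2x2 study design table (sample_id, genotype, age)."""
    rows = []
    for genotype in GENOTYPES:
        for age in AGES:
            for i in range(n_per_cell):
                rows.append(
                    {
                        "sample_id": f"{genotype[0]}_{age[0]}_{i + 1}",
                        "genotype": genotype,
                        "age": age,
                    }
                )
    return pd.DataFrame(rows)


def design_matrix(design: pd.DataFrame) -> pd.DataFrame:
    """Model matrix for ~Genotype + Genotype:Age with Young/Normal reference.

    Columns: Intercept, GenotypeDwarf, Normal:AgeOld, Dwarf:AgeOld. The
    last two are the within-genotype age effects; their difference is
    the GbA interaction.
    """
    g = design["genotype"].to_numpy()
    a = design["age"].to_numpy()
    bad_g = set(g) - set(GENOTYPES)
    bad_a = set(a) - set(AGES)
    if bad_g or bad_a:
        raise ValueError(f"unknown genotype/age levels: {bad_g | bad_a}")
    X = pd.DataFrame(
        {
            "Intercept": np.ones(len(design)),
            "GenotypeDwarf": (g == "Dwarf").astype(float),
            "Normal:AgeOld": ((g == "Normal") & (a == "Old")).astype(float),
            "Dwarf:AgeOld": ((g == "Dwarf") & (a == "Old")).astype(float),
        },
        index=design["sample_id"],
    )
    return X


def _pattern_effects(pattern: str, e: float) -> tuple[float, float]:
    """(log2FC in Normal, log2FC in Dwarf) for a planted pattern."""
    return {
        "A": (e, 0.0),
        "B": (-e, 0.0),
        "C": (-e, e),
        "D": (0.0, e),
        "null": (0.0, 0.0),
    }[pattern]


def simulate_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw an NB count matrix with planted GbA patterns.

    Returns ``(counts, design, truth)``: an integer feature x sample
    DataFrame, the design table, and a per-feature truth table with the
    planted pattern label and realized log2 fold changes. Identical
    config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = make_design(config.n_per_cell)
    n_samples = len(design)

    G = config.n_features
    n_a = int(round(G * config.frac_pattern_a))
    n_b = int(round(G * config.frac_pattern_b))
    n_c = int(round(G * config.frac_pattern_c))
    n_d = int(round(G * config.frac_pattern_d))
    labels = (
        ["A"] * n_a + ["B"] * n_b + ["C"] * n_c + ["D"] * n_d
        + ["null"] * (G - n_a - n_b - n_c - n_d)
    )

    e = float(np.log2(config.effect_size_fc))
    lfc_n = np.array([_pattern_effects(p, e)[0] for p in labels])
    lfc_d = np.array([_pattern_effects(p, e)[1] for p in labels])

    lo, hi = config.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, size=G)
    lib = np.exp(
        rng.uniform(*np.log(np.asarray(config.lib_size_range)), size=n_samples)
    )

    is_dwarf = (design["genotype"] == "Dwarf").to_numpy()
    is_old = (design["age"] == "Old").to_numpy()
    log2_rel = (
        baseline[:, None]
        + config.genotype_effect_log2 * is_dwarf[None, :]
        + lfc_n[:, None] * ((~is_dwarf) & is_old)[None, :]
        + lfc_d[:, None] * (is_dwarf & is_old)[None, :]
    )
    mu = lib[None, :] * np.exp2(log2_rel)

    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    features = [f"feat_{i + 1:04d}" for i in range(G)]
    counts_df = pd.DataFrame(counts, index=features, columns=design["sample_id"])
    truth = pd.DataFrame(
        {
            "feature": features,
            "pattern": labels,
            "log2fc_normal": lfc_n,
            "log2fc_dwarf": lfc_d,
            "baseline_log2_rel": baseline,
        }
    ).set_index("feature")
    return counts_df, design, truth


@dataclass
class ReadSimConfig:
    """Parameters of the aligned-read simulation.

    ``class_fractions`` must sum to 1 over the classes drawn; defaults
    follow the serum profile in which tRNA-derived reads dominate
    miRNA-derived reads roughly 76:24. tRNA reads are 30-33 nt 5'
    halves; miRNA reads are 20-24 nt, peaked at 21-22.
    """

    n_reads: int = 10_000
    class_fractions: dict = field(
        default_factory=lambda: {"tRNA": 0.76, "miRNA": 0.24}
    )
    n_mirna_loci: int = 40
    n_trna_loci: int = 20
    samples: Sequence[str] = ("S1",)
    seed: int = 0

    def validate(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")
        fr = self.class_fractions
        if any(not 0 <= f <= 1 for f in fr.values()) or abs(sum(fr.values()) - 1) > 1e-9:
            raise ValueError("class fractions must lie in [0,1] and sum to 1")
        if fr.get("miRNA", 0) > 0 and self.n_mirna_loci < 1:
            raise ValueError("miRNA reads requested but no miRNA loci configured")
        if fr.get("tRNA", 0) > 0 and self.n_trna_loci < 1:
            raise ValueError("tRNA reads requested but no tRNA loci configured")


_MIRNA_LEN = np.arange(20, 25)
_MIRNA_LEN_P = np.array([0.10, 0.25, 0.35, 0.20, 0.10])
_TRNA_LEN = np.arange(30, 34)
_TRNA_LEN_P = np.array([0.20, 0.35, 0.30, 0.15])


def synthetic_annotations(config: ReadSimConfig) -> AnnotationSet:
    """Deterministic toy annotation set: non-overlapping miRNA and tRNA loci."""
    records = []
    pos = 1000
    for i in range(config.n_mirna_loci):
        strand = "+" if i % 2 == 0 else "-"
        records.append(
            AnnotationRecord("chrS", pos, pos + 24, strand, f"mmu-mir-syn-{i + 1}", "miRNA")
        )
        pos += 24 + 200
    for i in range(config.n_trna_loci):
        strand = "+" if i % 2 == 0 else "-"
        aa, ac = _ISOACCEPTORS[i % len(_ISOACCEPTORS)]
        copy = i // len(_ISOACCEPTORS) + 1
        records.append(
            AnnotationRecord(
                "chrS", pos, pos + 72, strand, f"tRNA-{aa}-{ac}-{copy}-1", "tRNA"
            )
        )
        pos += 72 + 200
    return AnnotationSet(records)


def simulate_reads(config: ReadSimConfig) -> tuple[list[ReadRecord], AnnotationSet]:
    """Draw aligned reads over the toy genome.

    miRNA reads start at the 5' end of a random miRNA locus with length
    20-24; tRNA reads are anchored exactly at the tRNA 5' terminus with
    length 30-33 (5' halves). Reads are spread uniformly over the
    configured samples.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    annotations = synthetic_annotations(config)
    mirnas = [r for r in annotations.records if r.rna_class == "miRNA"]
    trnas = [r for r in annotations.records if r.rna_class == "tRNA"]

    classes = list(config.class_fractions)
    probs = np.array([config.class_fractions[c] for c in classes])
    draw = rng.choice(len(classes), size=config.n_reads, p=probs)
    samples = list(config.samples)
    sample_draw = rng.integers(0, len(samples), size=config.n_reads)

    reads: list[ReadRecord] = []
    for i, ci in enumerate(draw):
        cls = classes[ci]
        if cls == "miRNA":
            locus = mirnas[rng.integers(0, len(mirnas))]
            length = int(rng.choice(_MIRNA_LEN, p=_MIRNA_LEN_P))
        elif cls == "tRNA":
            locus = trnas[rng.integers(0, len(trnas))]
            length = int(rng.choice(_TRNA_LEN, p=_TRNA_LEN_P))
        else:
            raise ValueError(f"unsupported read class {cls!r}")
        if locus.strand == "+":
            start, end = locus.start, locus.start + length
        else:
            start, end = locus.end - length, locus.end
        reads.append(
            ReadRecord(
                chrom=locus.chrom,
                start=start,
                end=end,
                strand=locus.strand,
                read_id=f"read_{i + 1}",
                sample=samples[sample_draw[i]],
            )
        )
    return reads, annotations


def simulate_universe(
    n_mirnas: int,
    n_genes: int,
    targets_per_gene_dist=(20, 80),
    planted_genes: int | Sequence[str] = 0,
    gba_set_size: int = 10,
    enrichment: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a binary miRNA -> gene interaction universe.

    Non-planted genes draw their targeting miRNAs uniformly from the
    vocabulary; planted genes draw them with the focal GbA miRNAs
    upweighted by ``enrichment``, producing genuinely overtargeted
    genes. ``targets_per_gene_dist`` is either an integer (fixed number
    of targeting miRNAs per gene) or an inclusive (low, high) range
    sampled uniformly.

    Returns ``(universe, truth)``: a two-column (mirna, gene) DataFrame
    and a truth table flagging planted genes and GbA miRNAs.
    """
    if gba_set_size > n_mirnas:
        raise ValueError("gba_set_size cannot exceed the miRNA vocabulary size")
    if n_mirnas < 1 or n_genes < 1:
        raise ValueError("need at least one miRNA and one gene")
    rng = np.random.default_rng(seed)
    mirnas = np.array([f"mmu-miR-s{i + 1}" for i in range(n_mirnas)])
    genes = np.array([f"Gene{i + 1:05d}" for i in range(n_genes)])
    gba = set(mirnas[:gba_set_size])

    if isinstance(planted_genes, (int, np.integer)):
        if planted_genes > n_genes:
            raise ValueError("more planted genes than genes")
        planted = set(genes[:planted_genes])
    else:
        planted = set(planted_genes)
        if not planted <= set(genes):
            raise ValueError("planted genes must be a subset of the gene set")

    weights_plain = np.ones(n_mirnas)
    weights_planted = np.where(np.isin(mirnas, list(gba)), enrichment, 1.0)
    rows = []
    for gene in genes:
        if isinstance(targets_per_gene_dist, (int, np.integer)):
            k = int(targets_per_gene_dist)
        else:
            lo, hi = targets_per_gene_dist
            k = int(rng.integers(lo, hi + 1))
        k = min(max(k, 1), n_mirnas)
        w = weights_planted if gene in planted else weights_plain
        idx = rng.choice(n_mirnas, size=k, replace=False, p=w / w.sum())
        rows.extend((mirnas[j], gene) for j in idx)
    universe = pd.DataFrame(rows, columns=["mirna", "gene"])
    truth = pd.DataFrame(
        {
            "gene": genes,
            "planted": [g in planted for g in genes],
        }
    ).set_index("gene")
    truth.attrs["gba_mirnas"] = sorted(gba)
    return universe, truth
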