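"""Profiling of aligned small-RNA reads against sncRNA annotations.

Reads are 0-based half-open genomic intervals with strand; annotations
are intervals labelled with an sncRNA class (miRNA, tRNA, rRNA, snRNA,
snoRNA, scRNA, other). A read is assigned to the same-strand annotation
with maximal overlap, ties broken by a fixed class priority (miRNA >
tRNA > other sncRNA classes), and reads with no same-strand overlap are
"unannotated". tRNA-overlapping reads are further partitioned into
fragment classes: 5'/3' tRNA halves (30-40 nt anchored within a few
nucleotides of the respective mature-tRNA terminus, the 5' halves being
the dominant circulating species) and the shorter 5'/3' tRFs (16-25 nt),
everything else an unanchored tRNA fragment. Genomic coordinates are
used throughout, so the post-transcriptional CCA tail of mature tRNAs
is ignored.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "ReadRecord",
    "AnnotationRecord",
    "AnnotationSet",
    "FragmentClass",
    "FragmentThresholds",
    "length_histogram",
    "annotate_read",
    "class_fractions",
    "classify_trna_fragment",
    "isoacceptor_counts",
    "parse_isoacceptor",
    "CLASS_PRIORITY",
]

SNCRNA_CLASSES = ("miRNA", "tRNA", "rRNA", "snRNA", "snoRNA", "scRNA", "other")
# tie-break order when overlaps are equal: smaller rank wins
CLASS_PRIORITY = {c: i for i, c in enumerate(SNCRNA_CLASSES)}


@dataclass(frozen=True)
class ReadRecord:
    """An aligned small-RNA read (0-based half-open, stranded)."""

    chrom: str
    start: int
    end: int
    strand: str
    read_id: str = ""
    sample: str = "S1"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"read {self.read_id}: end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"read {self.read_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class AnnotationRecord:
    """An annotated sncRNA locus."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    rna_class: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"annotation {self.name}: end must exceed start")
        if self.rna_class not in CLASS_PRIORITY:
            raise ValueError(f"unknown sncRNA class {self.rna_class!r}")

    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


_ISOACCEPTOR_PATTERNS = (
    # GtRNAdb style: tRNA-His-GTG-1-1, tRNA-iMet-CAT-2-1
    re.compile(r"tRNA-([A-Za-z]{3,4})-([A-Za-z]{3})"),
    # UCSC style: chr1.trna5-HisGTG
    re.compile(r"trna\d+-([A-Za-z]{3,4}?)([ACGTacgt]{3})$"),
)


def parse_isoacceptor(name: str) -> Optional[tuple[str, str]]:
    """Extract (amino_acid, anticodon) from a tRNA gene name.

    Understands both the GtRNAdb dialect (``tRNA-His-GTG-1-1``) and the
    UCSC dialect (``chr1.trna5-HisGTG``); returns None if neither
    matches.
    """
    for pat in _ISOACCEPTOR_PATTERNS:
        m = pat.search(name)
        if m:
            return m.group(1), m.group(2).upper()
    return None


class AnnotationSet:
    """Indexed collection of sncRNA annotations (per-chromosome trees)."""

    def __init__(self, records: Iterable[AnnotationRecord]):
        self.records = list(records)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for rec in self.records:
            self._trees[rec.chrom].addi(rec.start, rec.end, rec)

    def __len__(self) -> int:
        return len(self.records)

    def overlapping(self, read: ReadRecord) -> list[AnnotationRecord]:
        """Same-strand annotations overlapping a read."""
        tree = self._trees.get(read.chrom)
        if tree is None:
            return []
        return [
            iv.data
            for iv in tree.overlap(read.start, read.end)
            if iv.data.strand == read.strand
        ]


class FragmentClass(str, Enum):
    five_prime_half = "five_prime_half"
    three_prime_half = "three_prime_half"
    five_prime_tRF = "five_prime_tRF"
    three_prime_tRF = "three_prime_tRF"
    other_tRNA_fragment = "other_tRNA_fragment"


@dataclass(frozen=True)
class FragmentThresholds:
    """Size ranges and terminal-anchor tolerance for tRNA fragments.

    ``anchor_tol`` is the maximal distance (nt) between a read terminus
    and the corresponding tRNA terminus for the read to count as
    anchored there. Halves span 30-40 nt, tRFs 16-25 nt.
    """

    anchor_tol: int = 3
    half_range: tuple[int, int] = (30, 40)
    trf_range: tuple[int, int] = (16, 25)


def length_histogram(reads: Iterable[ReadRecord]) -> dict[int, int]:
    """Read-length histogram; totals to the number of reads."""
    return dict(Counter(r.length for r in reads))


def annotate_read(read: ReadRecord, annotations: AnnotationSet) -> str:
    """Class of the same-strand annotation with maximal overlap.

    Ties go to the higher-priority class (miRNA > tRNA > the rest);
    returns "unannotated" when nothing on the same strand overlaps.
    """
    best = None
    best_key = None
    for ann in annotations.overlapping(read):
        overlap = min(read.end, ann.end) - max(read.start, ann.start)
        key = (-overlap, CLASS_PRIORITY[ann.rna_class])
        if best_key is None or key < best_key:
            best_key = key
            best = ann
    return best.rna_class if best is not None else "unannotated"


def class_fractions(
    reads: Iterable[ReadRecord],
    annotations: AnnotationSet,
    classes: Sequence[str] = ("miRNA", "tRNA"),
) -> dict[str, float]:
    """Proportion of reads per class among reads annotated to ``classes``.

    The returned proportions sum to 1; raises if no read annotates to
    any of the named classes.
    """
    counts = Counter()
    for read in reads:
        cls = annotate_read(read, annotations)
        if cls in classes:
            counts[cls] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no reads annotated to the requested classes")
    return {c: counts.get(c, 0) / total for c in classes}


def _anchored(a: int, b: int, tol: int) -> bool:
    return abs(a - b) <= tol


def classify_trna_fragment(
    read: ReadRecord,
    trna: AnnotationRecord,
    thresholds: FragmentThresholds = FragmentThresholds(),
) -> FragmentClass:
    """Assign a tRNA-overlapping read to exactly one fragment class.

    5' halves are 30-40 nt with their 5' terminus within ``anchor_tol``
    of the tRNA 5' terminus (strand-aware); 3' halves are symmetric at
    the 3' end; 5'/3' tRFs are 16-25 nt anchored the same way; anything
    else is an unanchored tRNA fragment.
    """
    if read.chrom != trna.chrom or read.strand != trna.strand:
        raise ValueError("read and tRNA must overlap on the same strand")
    if min(read.end, trna.end) - max(read.start, trna.start) <= 0:
        raise ValueError("read does not overlap the tRNA interval")
    t = thresholds
    length = read.length
    at5 = _anchored(read.five_prime(), trna.five_prime(), t.anchor_tol)
    at3 = _anchored(read.three_prime(), trna.three_prime(), t.anchor_tol)
    if t.half_range[0] <= length <= t.half_range[1]:
        if at5:
            return FragmentClass.five_prime_half
        if at3:
            return FragmentClass.three_prime_half
    if t.trf_range[0] <= length <= t.trf_range[1]:
        if at5:
            return FragmentClass.five_prime_tRF
        if at3:
            return FragmentClass.three_prime_tRF
    return FragmentClass.other_tRNA_fragment


def isoacceptor_counts(
    reads: Iterable[ReadRecord],
    annotations: AnnotationSet,
    thresholds: FragmentThresholds = FragmentThresholds(),
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample 5'-half counts aggregated by tRNA isoacceptor.

    Only reads whose best annotation is a tRNA and whose fragment class
    is ``five_prime_half`` are counted. Rows are "AminoAcid-ANTICODON"
    isoacceptor keys, columns samples. tRNA names that cannot be parsed
    into an isoacceptor are returned in a reject list rather than being
    silently dropped.
    """
    counts: dict[tuple[str, str], Counter] = defaultdict(Counter)
    rejects: list[str] = []
    samples: list[str] = []
    for read in reads:
        if read.sample not in samples:
            samples.append(read.sample)
        best, best_key = None, None
        for ann in annotations.overlapping(read):
            overlap = min(read.end, ann.end) - max(read.start, ann.start)
            key = (-overlap, CLASS_PRIORITY[ann.rna_class])
            if best_key is None or key < best_key:
                best_key, best = key, ann
        if best is None or best.rna_class != "tRNA":
            continue
        if classify_trna_fragment(read, best, thresholds) is not FragmentClass.five_prime_half:
            continue
        iso = parse_isoacceptor(best.name)
        if iso is None:
            rejects.append(best.name)
            continue
        counts[iso][read.sample] += 1
    index = [f"{aa}-{ac}" for aa, ac in sorted(counts)]
    mat = pd.DataFrame(0, index=index, columns=samples, dtype=int)
    for (aa, ac), per_sample in counts.items():
        for sample, k in per_sample.items():
            mat.loc[f"{aa}-{ac}", sample] = k
    return mat, rejects
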