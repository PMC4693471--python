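"""Readers and writers for the pipeline's plain-text formats.

Tables are TSV with a header row. Reads and annotations travel as BED6
(0-based half-open); the BED name field carries ``read_id|sample`` for
reads and ``name|class`` for annotations. Networks are exported as SIF
("mirna targets gene") and GraphML. Parse errors name the file and the
1-based line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd
import yaml

from .annotation import AnnotationRecord, AnnotationSet, ReadRecord

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_bed_reads",
    "write_bed_reads",
    "read_bed_annotations",
    "write_bed_annotations",
    "read_universe_tsv",
    "read_family_map_tsv",
    "read_signatures_tsv",
    "write_sif",
    "write_graphml",
    "load_config",
    "write_run_log",
]


class ParseError(ValueError):
    pass


def read_counts_tsv(path) -> pd.DataFrame:
    """Feature x sample integer count matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ParseError(f"{path}: empty count matrix")
    if not all(pd.api.types.is_numeric_dtype(t) for t in df.dtypes):
        raise ParseError(f"{path}: non-numeric count columns")
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative counts")
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature")


def read_design_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "genotype", "age"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: design table missing columns {sorted(missing)}")
    return df


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def _parse_bed6_line(path, lineno: int, line: str):
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise ParseError(
            f"{path}, line {lineno}: expected 6 BED fields, got {len(fields)}"
        )
    chrom, start, end, name, _score, strand = fields[:6]
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise ParseError(
            f"{path}, line {lineno}: non-integer coordinates ({start!r}, {end!r})"
        ) from exc
    if end_i <= start_i:
        raise ParseError(f"{path}, line {lineno}: end must exceed start")
    if strand not in "+-":
        raise ParseError(f"{path}, line {lineno}: strand must be + or -")
    return chrom, start_i, end_i, name, strand


def read_bed_reads(path) -> list[ReadRecord]:
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, strand = _parse_bed6_line(path, lineno, line)
            read_id, _, sample = name.partition("|")
            reads.append(
                ReadRecord(chrom, start, end, strand, read_id, sample or "S1")
            )
    return reads


def write_bed_reads(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}|{r.sample}\t0\t{r.strand}\n"
            )


def read_bed_annotations(path) -> AnnotationSet:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, strand = _parse_bed6_line(path, lineno, line)
            base, sep, cls = name.rpartition("|")
            if not sep:
                raise ParseError(
                    f"{path}, line {lineno}: annotation name must be 'name|class'"
                )
            try:
                records.append(AnnotationRecord(chrom, start, end, strand, base, cls))
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    return AnnotationSet(records)


def write_bed_annotations(annotations: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for a in annotations.records:
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{a.name}|{a.rna_class}\t0\t{a.strand}\n"
            )


_UNIVERSE_MIRNA_COLS = ("mirna", "mirna_family", "mir family", "mir_family", "family")
_UNIVERSE_GENE_COLS = ("gene", "gene symbol", "gene_symbol", "symbol")


def read_universe_tsv(path) -> pd.DataFrame:
    """Interaction-universe TSV; flexible column naming, extras ignored.

    Recognizes a miRNA/family token column and a gene-symbol column
    (case-insensitive); returns a two-column (mirna, gene) DataFrame.
    """
    df = pd.read_csv(path, sep="\t")
    lower = {c.lower().strip(): c for c in df.columns}
    mir_col = next((lower[c] for c in _UNIVERSE_MIRNA_COLS if c in lower), None)
    gene_col = next((lower[c] for c in _UNIVERSE_GENE_COLS if c in lower), None)
    if mir_col is None or gene_col is None:
        raise ParseError(
            f"{path}: need a miRNA column ({_UNIVERSE_MIRNA_COLS}) and a gene "
            f"column ({_UNIVERSE_GENE_COLS}); found {list(df.columns)}"
        )
    return df.rename(columns={mir_col: "mirna", gene_col: "gene"})[["mirna", "gene"]]


def read_family_map_tsv(path) -> dict[str, str]:
    """Two-column (mirna, family) TSV -> dict."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: family map needs two columns (mirna, family)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_signatures_tsv(path) -> dict[str, set[str]]:
    """Two-column (tissue, mirna) TSV -> per-tissue miRNA sets."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: signatures need two columns (tissue, mirna)")
    out: dict[str, set[str]] = {}
    for tissue, sub in df.groupby(df.columns[0]):
        out[str(tissue)] = set(sub.iloc[:, 1].astype(str))
    return out


def write_sif(graph: nx.DiGraph, path, relation: str = "targets") -> None:
    with open(path, "w") as fh:
        for u, v in graph.edges:
            fh.write(f"{u}\t{relation}\t{v}\n")


def write_graphml(graph: nx.DiGraph, path) -> None:
    nx.write_graphml(graph, path)


def load_config(path) -> dict:
    """YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


def write_run_log(outdir, subcommand: str, params: Mapping, seed: Optional[int]) -> None:
    """Record the config snapshot and seed of a run, for reproducibility."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"subcommand": subcommand, "seed": seed, "params": dict(params)}
    with open(outdir / f"{subcommand}_run.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
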