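"""Readers and writers for the tabular formats the pipeline touches.

Conventions
-----------
* eccDNA circles: BED3/BED4 (tab-separated, 0-based half-open).
* Enhancers: 6-column TSV ``chrom start end enh_id gene_id score`` with one
  row per (enhancer, candidate target).
* Transcripts: GTF/GFF3 (via :mod:`gffutils`, coordinates converted to
  0-based half-open on read) or a 6/7-column TSV
  ``chrom start end strand transcript_id gene_id [biotype]``.
* PPI: 3-column TSV ``gene_a gene_b confidence`` (STRING-like, undirected).
* DEG tables: 3-column TSV ``gene_id log2fc q_value`` or a bare gene list.
* Expression: genes x samples TSV with a header row of sample ids.

Malformed rows are rejected with the offending line number; nothing is
silently repaired. Writers emit rows in a documented deterministic order so
repeated runs are byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

from .types import (
    EccDNARecord,
    EdgCall,
    EdgCatalog,
    EnhancerRecord,
    GenomicInterval,
    TranscriptRecord,
    ValidationError,
)


class ParseError(ValueError):
    """Raised for malformed input files, naming the line where possible."""


# ---------------------------------------------------------------------------
# eccDNA (BED)
# ---------------------------------------------------------------------------

def read_bed(path, dataset: str = "default") -> list[EccDNARecord]:
    """Read eccDNA intervals from a BED3+ file.

    Rows keep file order. A missing 4th (name) column synthesizes ids
    ``ecc_<index>`` from 0. Coordinates are taken verbatim (BED is already
    0-based half-open).
    """
    records: list[EccDNARecord] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        idx = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}/{fields[2]!r}"
                ) from None
            ecc_id = fields[3] if len(fields) > 3 and fields[3] else f"ecc_{idx}"
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if ecc_id in seen_ids:
                raise ParseError(f"{path}:{lineno}: duplicate eccDNA id {ecc_id!r}")
            seen_ids.add(ecc_id)
            records.append(EccDNARecord(interval, ecc_id, dataset))
            idx += 1
    return records


def write_bed(records: Iterable[EccDNARecord], path) -> None:
    """Write eccDNA records as BED4, preserving input order."""
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.ecc_id}\n")


# ---------------------------------------------------------------------------
# Enhancers
# ---------------------------------------------------------------------------

_ENH_COLS = ["chrom", "start", "end", "enh_id", "gene_id", "score"]


def read_enhancers(path) -> list[EnhancerRecord]:
    """Read an enhancer/target table into one record per enhancer.

    Rows sharing an ``enh_id`` are grouped; their coordinates must agree.
    Targets are ordered by S_GE descending, ties by gene_id ascending, so
    the top-1 target of each enhancer is well defined.
    """
    df = _read_tsv(path, _ENH_COLS)
    if df.empty:
        return []
    for col, caster in (("start", int), ("end", int), ("score", float)):
        try:
            df[col] = df[col].map(caster)
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ParseError(
                f"{path}: non-numeric {col} at data row {bad + 1}"
            ) from None
    if df["score"].map(lambda s: not math.isfinite(s) or s < 0).any():
        raise ParseError(f"{path}: S_GE scores must be finite and >= 0")

    records = []
    for enh_id, grp in df.groupby("enh_id", sort=False):
        coords = grp[["chrom", "start", "end"]].drop_duplicates()
        if len(coords) != 1:
            raise ParseError(
                f"{path}: enhancer {enh_id!r} has inconsistent coordinates across rows"
            )
        chrom, start, end = coords.iloc[0]
        targets = sorted(
            zip(grp["gene_id"], grp["score"]), key=lambda t: (-t[1], t[0])
        )
        try:
            interval = GenomicInterval(chrom, start, end)
            records.append(EnhancerRecord(interval, enh_id, tuple(targets)))
        except ValidationError as exc:
            raise ParseError(f"{path}: enhancer {enh_id!r}: {exc}") from None
    return records


def write_enhancers(records: Iterable[EnhancerRecord], path) -> None:
    """Write enhancers as the 6-column TSV, one row per target.

    Rows are ordered by (chrom, start, end, enh_id) and, within an enhancer,
    by the stored target order (score desc, gene asc).
    """
    rows = []
    for rec in sorted(
        records, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.enh_id)
    ):
        iv = rec.interval
        for gene, score in rec.targets:
            rows.append((iv.chrom, iv.start, iv.end, rec.enh_id, gene, score))
    pd.DataFrame(rows, columns=_ENH_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------

_TX_COLS = ["chrom", "start", "end", "strand", "transcript_id", "gene_id"]


def read_transcripts(path) -> list[TranscriptRecord]:
    """Read transcript annotation from GTF/GFF3 or the 6/7-column TSV.

    Format is chosen by extension: ``.gtf``, ``.gff``, ``.gff3`` go through
    gffutils (1-based closed coordinates converted to 0-based half-open);
    anything else is parsed as TSV already in BED-style coordinates.
    """
    suffix = Path(path).suffix.lower()
    if suffix in (".gtf", ".gff", ".gff3"):
        return _read_transcripts_gxf(path)
    return _read_transcripts_tsv(path)


def _read_transcripts_gxf(path) -> list[TranscriptRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records = []
    for feat in db.all_features():
        if feat.featuretype not in ("transcript", "mRNA"):
            continue
        gene_id = _first_attr(feat, "gene_id", "Parent", "gene")
        tx_id = _first_attr(feat, "transcript_id", "ID") or f"tx_{len(records)}"
        biotype = (
            _first_attr(feat, "transcript_biotype", "gene_biotype", "biotype")
            or "unknown"
        )
        strand = feat.strand if feat.strand in ("+", "-") else "."
        interval = GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
        records.append(TranscriptRecord(interval, tx_id, gene_id or "", biotype))
    for rec in records:
        if not rec.gene_id:
            raise ParseError(f"{path}: transcript {rec.transcript_id} lacks a gene id")
    return records


def _first_attr(feat, *keys) -> Optional[str]:
    for key in keys:
        if key in feat.attributes and feat.attributes[key]:
            return feat.attributes[key][0]
    return None


def _read_transcripts_tsv(path) -> list[TranscriptRecord]:
    df = _read_tsv(path, _TX_COLS, optional=["biotype"])
    records = []
    for row in df.itertuples(index=False):
        try:
            interval = GenomicInterval(
                row.chrom, int(row.start), int(row.end), row.strand
            )
            biotype = getattr(row, "biotype", "unknown")
            records.append(
                TranscriptRecord(interval, row.transcript_id, row.gene_id, biotype)
            )
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"{path}: transcript {row.transcript_id!r}: {exc}") from None
    return records


def write_transcripts(records: Iterable[TranscriptRecord], path) -> None:
    """Write transcripts as the 7-column TSV ordered by genomic position."""
    rows = [
        (
            r.interval.chrom,
            r.interval.start,
            r.interval.end,
            r.interval.strand,
            r.transcript_id,
            r.gene_id,
            r.biotype,
        )
        for r in sorted(
            records,
            key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.transcript_id),
        )
    ]
    pd.DataFrame(rows, columns=_TX_COLS + ["biotype"]).to_csv(path, sep="\t", index=False)


def biotype_map(transcripts: Iterable[TranscriptRecord]) -> dict:
    """Gene -> biotype mapping; a gene with any protein_coding transcript is coding."""
    out: dict = {}
    for tx in transcripts:
        if out.get(tx.gene_id) != "protein_coding":
            out[tx.gene_id] = tx.biotype
    return out


# ---------------------------------------------------------------------------
# PPI
# ---------------------------------------------------------------------------

def read_ppi(path, min_confidence: float = 700.0) -> pd.DataFrame:
    """Read a weighted undirected edge list, clean it, return a DataFrame.

    Edges below ``min_confidence`` (on the file's native scale; default 700
    on STRING's 0-1000 scale) and self-loops are dropped. Reciprocal and
    duplicate rows collapse to one undirected edge keeping the maximum
    confidence. Output rows are sorted by (gene_a, gene_b) with
    gene_a < gene_b lexicographically.
    """
    df = _read_tsv(path, ["gene_a", "gene_b", "confidence"])
    if df.empty:
        return pd.DataFrame(columns=["gene_a", "gene_b", "confidence"])
    for col in ("gene_a", "gene_b"):
        if (df[col].isna() | (df[col].astype(str).str.strip() == "")).any():
            raise ParseError(f"{path}: empty node name in edge list")
    try:
        df["confidence"] = df["confidence"].astype(float)
    except (ValueError, TypeError):
        raise ParseError(f"{path}: non-numeric confidence value") from None
    df = df[df["confidence"] >= min_confidence]
    df = df[df["gene_a"] != df["gene_b"]]
    lo = df[["gene_a", "gene_b"]].min(axis=1)
    hi = df[["gene_a", "gene_b"]].max(axis=1)
    df = pd.DataFrame({"gene_a": lo, "gene_b": hi, "confidence": df["confidence"]})
    df = (
        df.groupby(["gene_a", "gene_b"], as_index=False)["confidence"]
        .max()
        .sort_values(["gene_a", "gene_b"])
        .reset_index(drop=True)
    )
    return df


def write_ppi(edges: pd.DataFrame, path) -> None:
    edges.sort_values(["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def ppi_graph(edges: pd.DataFrame) -> nx.Graph:
    """Build an undirected :class:`networkx.Graph` from a cleaned edge list."""
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, confidence=row.confidence)
    return g


# ---------------------------------------------------------------------------
# DEG tables and gene lists
# ---------------------------------------------------------------------------

def read_deg_table(path) -> pd.DataFrame:
    """Read a ``gene_id  log2fc  q_value`` table (unfiltered)."""
    df = _read_tsv(path, ["gene_id", "log2fc", "q_value"])
    if df.empty:
        return pd.DataFrame(columns=["gene_id", "log2fc", "q_value"])
    try:
        df["log2fc"] = df["log2fc"].astype(float)
        df["q_value"] = df["q_value"].astype(float)
    except (ValueError, TypeError):
        raise ParseError(f"{path}: non-numeric log2fc/q_value") from None
    if ((df["q_value"] < 0) | (df["q_value"] > 1)).any():
        raise ParseError(f"{path}: q_value outside [0, 1]")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{path}: duplicate gene {dup!r} in DEG table")
    return df


def read_gene_list(path) -> set:
    """Read a one-gene-per-line text file into a set (blank lines skipped)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(genes):
            fh.write(f"{gene}\n")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column = gene ids, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise ParseError(f"{path}: non-numeric expression column(s) {list(bad)}")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# EDG catalogs and centrality tables
# ---------------------------------------------------------------------------

_CATALOG_COLS = [
    "gene_id",
    "classes",
    "dataset",
    "n_supporting_ecc",
    "supporting_ecc",
    "supporting_elements",
    "biotype",
]


def write_edg_catalog(catalog: EdgCatalog, path) -> None:
    """Write one row per EDG call, sorted by gene_id."""
    rows = []
    for gene in sorted(catalog.calls):
        call = catalog.calls[gene]
        rows.append(
            (
                gene,
                ",".join(sorted(call.classes)),
                call.dataset,
                len(call.supporting_ecc_ids),
                ";".join(sorted(call.supporting_ecc_ids)),
                ";".join(sorted(call.supporting_element_ids)),
                call.biotype,
            )
        )
    pd.DataFrame(rows, columns=_CATALOG_COLS).to_csv(path, sep="\t", index=False)


def read_edg_catalog(path) -> EdgCatalog:
    df = _read_tsv(path, _CATALOG_COLS)
    dataset = df["dataset"].iloc[0] if len(df) else "default"
    calls = {}
    for row in df.itertuples(index=False):
        calls[row.gene_id] = EdgCall(
            gene_id=row.gene_id,
            classes=frozenset(str(row.classes).split(",")),
            supporting_ecc_ids=frozenset(_split(row.supporting_ecc)),
            supporting_element_ids=frozenset(_split(row.supporting_elements)),
            dataset=row.dataset,
            biotype=row.biotype,
        )
    return EdgCatalog(dataset=dataset, calls=calls)


def write_centrality_table(records, path) -> None:
    """Write ranked centrality records (already in rank order)."""
    rows = [
        (r.rank, r.gene_id, r.K, r.N, r.Q, r.alpha_used, r.c_wl, r.egis)
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["rank", "gene_id", "K", "N", "Q", "alpha", "c_wl", "egis"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _split(value) -> list:
    text = "" if value is None or (isinstance(value, float) and math.isnan(value)) else str(value)
    return [v for v in text.split(";") if v]


def _read_tsv(path, columns: list, optional: list | None = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df
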