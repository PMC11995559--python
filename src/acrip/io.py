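"""Readers and writers for BED, GTF-lite, TSV matrices, YAML config and JSON.

Interval arithmetic everywhere in the package is 0-based half-open; the GTF
reader/writer is the single place where conversion to the 1-based inclusive
GTF convention happens (losslessly).  Writers emit sorted, fixed-precision
output so reruns diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .genome import (
    CDS,
    FIVE_UTR,
    THREE_UTR,
    GenomicInterval,
    Transcript,
    TranscriptAnnotation,
)
from .matrix import OmicsMatrix

_GTF_REGION = {"five_prime_utr": FIVE_UTR, "CDS": CDS, "three_prime_utr": THREE_UTR}
_REGION_GTF = {v: k for k, v in _GTF_REGION.items()}
FLOAT_FORMAT = "%.6f"


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[GenomicInterval, list[str]]]:
    """Read a BED4+ file.

    Returns a list of ``(interval, extra_columns)`` pairs; coordinates are
    kept 0-based half-open as in the file.  Malformed lines raise
    :class:`FormatError` naming the line.
    """
    out: list[tuple[GenomicInterval, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start >= end")
            out.append((GenomicInterval(chrom, start, end), fields[3:]))
    return out


def write_bed(records: list[tuple[GenomicInterval, list[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, extra in records:
            fields = [iv.chrom, str(iv.start), str(iv.end), *extra]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GTF-lite
# ---------------------------------------------------------------------------

def _parse_attrs(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf_lite(path: str | Path) -> TranscriptAnnotation:
    """Read the GTF-lite dialect written by the simulator.

    GTF 1-based inclusive coordinates are converted to internal 0-based
    half-open; the round trip through :func:`write_gtf_lite` is lossless.
    """
    ann = TranscriptAnnotation()
    biotypes: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GTF columns")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, raw = fields
            start, end = int(start_s) - 1, int(end_s)  # to 0-based half-open
            attrs = _parse_attrs(raw)
            if feature == "gene":
                biotypes[attrs["gene_id"]] = attrs.get("gene_biotype", "protein_coding")
                continue
            if feature == "transcript":
                tid = attrs["transcript_id"]
                ann.add(Transcript(tid, attrs["gene_id"], chrom, strand))
                continue
            if feature != "exon" and feature not in _GTF_REGION:
                raise FormatError(f"{path}: line {lineno}: unknown feature {feature!r}")
            tid = attrs.get("transcript_id")
            if tid not in ann.transcripts:
                raise FormatError(f"{path}: line {lineno}: unknown transcript {tid!r}")
            tx = ann.transcripts[tid]
            iv = GenomicInterval(chrom, start, end, strand)
            if feature == "exon":
                tx.exons.append(iv)
            else:
                tx.segments.append((_GTF_REGION[feature], iv))
    for tx in ann.transcripts.values():
        tx.exons.sort(key=lambda e: e.start)
        tx.segments.sort(key=lambda rs: rs[1].start)
        tx.biotype = biotypes.get(tx.gene_id, "protein_coding")
    ann.validate()
    return ann


def write_gtf_lite(ann: TranscriptAnnotation, path: str | Path) -> None:
    lines: list[str] = []

    def row(chrom: str, feature: str, iv: GenomicInterval, strand: str, attrs: str) -> str:
        # internal 0-based half-open -> GTF 1-based inclusive
        return "\t".join(
            [chrom, "acrip", feature, str(iv.start + 1), str(iv.end), ".", strand, ".", attrs]
        )

    seen_genes: set[str] = set()
    for tid in sorted(ann.transcripts):
        tx = ann.transcripts[tid]
        gattrs = f'gene_id "{tx.gene_id}"; gene_biotype "{tx.biotype}";'
        if tx.gene_id not in seen_genes:
            seen_genes.add(tx.gene_id)
            lines.append(row(tx.chrom, "gene", tx.span, tx.strand, gattrs))
        tattrs = f'gene_id "{tx.gene_id}"; transcript_id "{tid}";'
        lines.append(row(tx.chrom, "transcript", tx.span, tx.strand, tattrs))
        for exon in tx.exons:
            lines.append(row(tx.chrom, "exon", exon, tx.strand, tattrs))
        for region, seg in tx.segments:
            lines.append(row(tx.chrom, _REGION_GTF[region], seg, tx.strand, tattrs))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, kind: str = "count", assay: str = "") -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise FormatError(
                f"{path}: non-numeric value at feature {df.index[bad.argmax()]!r}, "
                f"sample {col!r}"
            )
        df[col] = coerced
    return OmicsMatrix(df, kind=kind, assay=assay)


def write_matrix(m: OmicsMatrix, path: str | Path) -> None:
    """Write a matrix as TSV, sorted, floats to 6 decimals (NaN -> empty cell)."""
    out = m.values.sort_index(axis=0).sort_index(axis=1)
    if m.kind == "count":
        out = out.astype(np.int64)
        out.to_csv(path, sep="\t", index_label="feature")
    else:
        out.to_csv(path, sep="\t", index_label="feature", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# YAML / JSON
# ---------------------------------------------------------------------------

def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_yaml(data: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def write_json(data, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
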