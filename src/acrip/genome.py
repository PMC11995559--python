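"""Genomic intervals and a minimal transcript annotation model.

All coordinates inside the package are 0-based half-open; only GTF I/O
(see :mod:`acrip.io`) converts to/from the 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError

FIVE_UTR = "5'UTR"
CDS = "CDS"
THREE_UTR = "3'UTR"
REGION_ORDER = (FIVE_UTR, CDS, THREE_UTR)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ConfigError("chrom must be non-empty")
        if self.start >= self.end:
            raise ConfigError(f"start must be < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ConfigError(f"strand must be one of + - . , got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand ignored)."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_from_key(key: str, strand: str = ".") -> GenomicInterval:
    chrom, span = key.rsplit(":", 1)
    start, end = span.split("-")
    return GenomicInterval(chrom, int(start), int(end), strand)


def union_length(intervals: list[GenomicInterval]) -> int:
    """Total number of bases covered by a set of intervals (per chromosome)."""
    total = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs = sorted(ivs, key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                total += cur_end - cur_start
                cur_start, cur_end = iv.start, iv.end
        total += cur_end - cur_start
    return total


@dataclass
class Transcript:
    """A transcript with exon structure and 5'UTR/CDS/3'UTR segmentation.

    ``segments`` is an ordered list of ``(region, interval)`` pairs where
    region is one of 5'UTR, CDS, 3'UTR.  Exons must be sorted and
    non-overlapping; every segment must lie within an exon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    segments: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    biotype: str = "protein_coding"

    def validate(self) -> None:
        if not self.exons:
            raise ConfigError(f"transcript {self.transcript_id} has no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ConfigError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
        for region, seg in self.segments:
            if region not in REGION_ORDER:
                raise ConfigError(f"unknown region class {region!r}")
            if not any(e.start <= seg.start and seg.end <= e.end for e in self.exons):
                raise ConfigError(
                    f"transcript {self.transcript_id}: {region} segment "
                    f"{seg.key()} lies outside exons"
                )

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    def region_at(self, position: int) -> str | None:
        """Region class containing a genomic position, or None."""
        for region, seg in self.segments:
            if seg.start <= position < seg.end:
                return region
        return None


@dataclass
class TranscriptAnnotation:
    """Collection of gene models keyed by transcript id."""

    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def validate(self) -> None:
        for tx in self.transcripts.values():
            tx.validate()

    def add(self, tx: Transcript) -> None:
        self.transcripts[tx.transcript_id] = tx

    @property
    def genes(self) -> list[str]:
        return sorted({tx.gene_id for tx in self.transcripts.values()})

    def transcripts_of_gene(self, gene_id: str) -> list[Transcript]:
        return sorted(
            (tx for tx in self.transcripts.values() if tx.gene_id == gene_id),
            key=lambda t: t.transcript_id,
        )

    def gene_of_transcript(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].gene_id

    def protein_coding(self) -> list[Transcript]:
        return sorted(
            (tx for tx in self.transcripts.values() if tx.biotype == "protein_coding"),
            key=lambda t: t.transcript_id,
        )

    def gene_length(self, gene_id: str) -> int:
        """Gene length for TPM: union exon length of the longest transcript.

        The longest transcript is the one with the greatest exonic length;
        ties broken by lexicographically smallest transcript id.
        """
        txs = self.transcripts_of_gene(gene_id)
        if not txs:
            raise ConfigError(f"unknown gene {gene_id}")
        best = min(txs, key=lambda t: (-t.exonic_length, t.transcript_id))
        return union_length(best.exons)

    def gene_lengths(self) -> dict[str, int]:
        return {g: self.gene_length(g) for g in self.genes}
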