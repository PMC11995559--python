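"""Reliability filters for acRIP peaks.

The chain applied to per-sample peaks is: fold-enrichment computation
against matched IgG and input coverage; significance + FE thresholds
(adjusted p < 0.05, FE > 1); restriction to protein-coding exons with
region-class assignment; removal of peaks overlapping any IgG peak of the
same sample; replicate consensus (>= 2 of 3); and validation against the
set of mRNAs detected by RNA-seq.  Each filter is a pure predicate on
fixed peak attributes, so the final set does not depend on filter order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .genome import CDS, FIVE_UTR, THREE_UTR, GenomicInterval, TranscriptAnnotation, union_length
from .matrix import OmicsMatrix
from .peaks import SamplePeak

_REGION_PRIORITY = {FIVE_UTR: 0, CDS: 1, THREE_UTR: 2}


def fold_enrichment(acrip: float, igg: float, input_: float, *, input_floor: float = 0.5) -> float:
    """FE = (acRIP - IgG) / Input on depth-normalized coverages.

    The input denominator is floored at ``input_floor`` so that peaks over
    coverage holes do not blow up; the result may be <= 0 (such peaks are
    removed by the FE > 1 filter).
    """
    if input_floor <= 0:
        raise ConfigError("input_floor must be > 0")
    return (acrip - igg) / max(input_, input_floor)


def compute_fe(peak: SamplePeak, igg_cov: float, input_cov: float,
               *, input_floor: float = 0.5) -> float:
    """FE of one peak given matched IgG and input mean coverages."""
    return fold_enrichment(peak.mean_ip, igg_cov, input_cov, input_floor=input_floor)


def _mean_cov(cpm, index, interval: GenomicInterval, starts: np.ndarray,
              chroms: np.ndarray) -> float:
    sel = (chroms == interval.chrom) & (starts >= interval.start) & (starts < interval.end)
    if not sel.any():
        return 0.0
    return float(cpm[sel].mean())


def attach_coverage(
    peaks: list[SamplePeak],
    acrip: OmicsMatrix,
    igg: OmicsMatrix,
    input_: OmicsMatrix,
    sample: str,
    *,
    input_floor: float = 0.5,
) -> list[SamplePeak]:
    """Fill depth-normalized mean coverage of the three assays and the FE."""
    mats = {"ip": acrip, "igg": igg, "input": input_}
    cpms = {k: m.cpm()[sample].to_numpy() for k, m in mats.items()}
    keys = list(acrip.values.index)
    starts = np.array([int(k.rsplit(":", 1)[1].split("-")[0]) for k in keys])
    chroms = np.array([k.rsplit(":", 1)[0] for k in keys])
    for pk in peaks:
        pk.mean_ip = _mean_cov(cpms["ip"], keys, pk.interval, starts, chroms)
        pk.mean_igg = _mean_cov(cpms["igg"], keys, pk.interval, starts, chroms)
        pk.mean_input = _mean_cov(cpms["input"], keys, pk.interval, starts, chroms)
        pk.fe = fold_enrichment(pk.mean_ip, pk.mean_igg, pk.mean_input,
                                input_floor=input_floor)
    return peaks


def filter_significant(
    peaks: list[SamplePeak], *, q_max: float = 0.05, fe_min: float = 1.0
) -> list[SamplePeak]:
    """Retain peaks with adjusted p below q_max and FE above fe_min."""
    return [p for p in peaks if p.peak_q < q_max and p.fe > fe_min]


def filter_exonic(
    peaks: list[SamplePeak],
    ann: TranscriptAnnotation,
    *,
    min_overlap_frac: float = 0.5,
) -> list[SamplePeak]:
    """Restrict to peaks on protein-coding exons; assign host and region.

    A peak is retained iff at least ``min_overlap_frac`` of its length
    overlaps the exon union of protein-coding transcripts.  The host
    transcript is the one with maximal exonic overlap (ties: smallest id);
    the region class (5'UTR/CDS/3'UTR) is the host segment containing the
    summit midpoint, falling back to the segment with greatest overlap
    with the summit window, then with the peak.
    """
    coding = ann.protein_coding()
    kept: list[SamplePeak] = []
    for pk in peaks:
        best_tx, best_ov = None, 0
        for tx in coding:
            if tx.chrom != pk.interval.chrom:
                continue
            ov = sum(pk.interval.overlap_length(e) for e in tx.exons)
            if ov > best_ov:
                best_tx, best_ov = tx, ov
        if best_tx is None:
            continue
        exonic = union_length(
            [
                GenomicInterval(
                    pk.interval.chrom,
                    max(pk.interval.start, e.start),
                    min(pk.interval.end, e.end),
                )
                for tx in coding
                for e in tx.exons
                if pk.interval.overlap_length(e) > 0
            ]
        ) if best_ov else 0
        if exonic / len(pk.interval) < min_overlap_frac:
            continue
        pk.host_transcript = best_tx.transcript_id
        pk.host_gene = best_tx.gene_id
        mid = (pk.summit.start + pk.summit.end) // 2
        region = best_tx.region_at(mid)
        if region is None:
            candidates = [
                (seg.overlap_length(pk.summit), -_REGION_PRIORITY[r], r)
                for r, seg in best_tx.segments
            ] + [
                (seg.overlap_length(pk.interval), -_REGION_PRIORITY[r], r)
                for r, seg in best_tx.segments
            ]
            candidates.sort(reverse=True)
            region = candidates[0][2] if candidates and candidates[0][0] > 0 else CDS
        pk.region = region
        kept.append(pk)
    return kept


def calibrate_igg(
    ac_peaks: list[SamplePeak], igg_peaks: list[SamplePeak]
) -> list[SamplePeak]:
    """Drop acRIP peaks overlapping (>= 1 bp) any IgG peak of the same sample."""
    return [
        pk
        for pk in ac_peaks
        if not any(pk.interval.overlaps(ig.interval) for ig in igg_peaks)
    ]


@dataclass
class ConsensusPeak:
    """Group-level peak supported by >= consensus_min replicates."""

    interval: GenomicInterval
    group: str
    support: int
    samples: tuple[str, ...]
    fe: float                    # mean of contributing sample-peak FEs
    host_transcript: str | None = None
    host_gene: str | None = None
    region: str | None = None
    members: list[SamplePeak] = field(default_factory=list, repr=False)


def consensus(
    sample_peaks: list[SamplePeak],
    *,
    group: str,
    consensus_min: int = 2,
) -> list[ConsensusPeak]:
    """Single-linkage clustering of same-group sample peaks by >= 1 bp overlap.

    A cluster is kept iff it contains peaks from at least ``consensus_min``
    distinct replicates; its interval is the union span of the members, and
    the group FE is the arithmetic mean of the members' FEs.  Host
    transcript and region class are taken by majority among members (ties:
    lexicographically smallest transcript; 5'UTR < CDS < 3'UTR order).
    """
    peaks = sorted(sample_peaks, key=lambda p: (p.interval.chrom, p.interval.start))
    out: list[ConsensusPeak] = []
    cluster: list[SamplePeak] = []
    cur_end = -1

    def flush(cluster: list[SamplePeak]) -> None:
        reps = {p.sample for p in cluster}
        if len(reps) < consensus_min:
            return
        chrom = cluster[0].interval.chrom
        start = min(p.interval.start for p in cluster)
        end = max(p.interval.end for p in cluster)
        hosts = sorted(
            {p.host_transcript for p in cluster if p.host_transcript},
            key=lambda t: (-sum(1 for p in cluster if p.host_transcript == t), t),
        )
        host = hosts[0] if hosts else None
        gene = next((p.host_gene for p in cluster if p.host_transcript == host), None)
        regions = sorted(
            {p.region for p in cluster if p.region},
            key=lambda r: (-sum(1 for p in cluster if p.region == r), _REGION_PRIORITY[r]),
        )
        out.append(
            ConsensusPeak(
                interval=GenomicInterval(chrom, start, end),
                group=group,
                support=len(reps),
                samples=tuple(sorted(reps)),
                fe=float(np.mean([p.fe for p in cluster])),
                host_transcript=host,
                host_gene=gene,
                region=regions[0] if regions else None,
                members=list(cluster),
            )
        )

    for pk in peaks:
        if cluster and (
            pk.interval.chrom != cluster[-1].interval.chrom or pk.interval.start >= cur_end
        ):
            flush(cluster)
            cluster, cur_end = [], -1
        cluster.append(pk)
        cur_end = max(cur_end, pk.interval.end)
    if cluster:
        flush(cluster)
    return out


def validate_by_rnaseq(
    cons_peaks: list[ConsensusPeak], detected_mrnas: set[str]
) -> list[ConsensusPeak]:
    """Keep consensus peaks whose host gene is detected by RNA-seq."""
    return [p for p in cons_peaks if p.host_gene in detected_mrnas]
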