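"""Synthetic acRIP/IgG/input coverage, RNA-seq and proteomics with ground truth.

The generator emulates the study design the pipeline assumes: two groups
(wild type and disease model), three biological replicates each, three
assays per replicate (acRIP, IgG, input), negative-binomial window
coverage with planted enriched regions, log-normal protein intensities
with planted log2 fold changes, and group-exclusive detection patterns.

Randomness is threaded through per-gene substreams derived from the
top-level seed (``default_rng((seed, stage, gene_index))``) in a fixed,
documented order.  All outputs are integer counts or intensities rounded
to six decimals; a fixed seed therefore yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genome import CDS, FIVE_UTR, THREE_UTR, GenomicInterval, Transcript, TranscriptAnnotation
from .matrix import OmicsMatrix

ASSAYS = ("acRIP", "IgG", "input")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Rates are fractions in [0, 1]; ``nb_dispersion`` is the negative-binomial
    dispersion phi with variance mu + phi * mu^2.
    """

    n_genes: int = 200
    exons_per_gene: int = 3
    exon_windows: int = 4       # windows per exon
    intron_windows: int = 1
    intergenic_windows: int = 2
    window_size: int = 50       # bases per window
    n_replicates: int = 3
    groups: tuple[str, ...] = ("WT", "FAD")
    timepoints: tuple[str, ...] = ()
    chrom: str = "chrS"

    background_mean: float = 20.0
    nb_dispersion: float = 0.05
    peak_fraction: float = 0.3
    peak_windows: int = 2
    enrichment_effect: float = 8.0
    igg_peak_rate: float = 0.01
    igg_enrichment: float = 5.0

    rna_mean: float = 200.0
    rna_undetected_fraction: float = 0.02
    protein_base: float = 20.0
    protein_sigma: float = 0.3
    protein_effects: tuple[float, ...] = (2.0, -2.0)
    protein_de_fraction: float = 0.1
    exclusive_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "exons_per_gene", "exon_windows", "window_size",
                     "n_replicates", "peak_windows"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        for name in ("peak_fraction", "igg_peak_rate", "exclusive_fraction",
                     "protein_de_fraction", "rna_undetected_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if len(self.groups) != 2:
            raise ConfigError("groups must name exactly two group labels")
        if self.exons_per_gene * self.exon_windows < 3:
            raise ConfigError("exon_windows: need at least 3 exonic windows per gene")
        if self.peak_windows > self.exon_windows:
            raise ConfigError("peak_windows must not exceed exon_windows")


@dataclass
class GroundTruth:
    """Planted truth sidecar for parameter-recovery tests."""

    true_peaks: list[dict] = field(default_factory=list)
    true_protein_lfc: dict[str, float] = field(default_factory=dict)
    true_detection: dict[str, dict[str, dict[str, bool]]] = field(default_factory=dict)
    true_de_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    igg_windows: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)

    def peak_genes(self, group: str) -> set[str]:
        return {p["gene"] for p in self.true_peaks if p["group"] == group}


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(cfg: SimConfig) -> TranscriptAnnotation:
    """Non-overlapping toy gene models on one chromosome.

    Every gene has one transcript on the + strand; the first exonic window
    is 5'UTR, the last is 3'UTR, everything between is CDS.  All exon and
    gene boundaries fall on window boundaries so that window-level coverage
    maps unambiguously onto gene structure.
    """
    ann = TranscriptAnnotation()
    w = cfg.window_size
    cursor = 0  # in windows
    for i in range(cfg.n_genes):
        gid, tid = f"g{i + 1:05d}", f"t{i + 1:05d}"
        exons: list[GenomicInterval] = []
        pos = cursor
        for _ in range(cfg.exons_per_gene):
            exons.append(GenomicInterval(cfg.chrom, pos * w, (pos + cfg.exon_windows) * w, "+"))
            pos += cfg.exon_windows + cfg.intron_windows
        pos -= cfg.intron_windows  # no intron after last exon
        cursor = pos + cfg.intergenic_windows

        # segment the exonic windows: first -> 5'UTR, last -> 3'UTR, rest CDS
        segments: list[tuple[str, GenomicInterval]] = []
        exonic_windows: list[tuple[int, int]] = []
        for e in exons:
            for ws in range(e.start // w, e.end // w):
                exonic_windows.append((ws * w, (ws + 1) * w))
        for j, (s, e) in enumerate(exonic_windows):
            region = FIVE_UTR if j == 0 else THREE_UTR if j == len(exonic_windows) - 1 else CDS
            segments.append((region, GenomicInterval(cfg.chrom, s, e, "+")))
        segments = _merge_segments(segments)
        tx = Transcript(tid, gid, cfg.chrom, "+", exons, segments)
        tx.validate()
        ann.add(tx)
    return ann


def _merge_segments(
    segments: list[tuple[str, GenomicInterval]]
) -> list[tuple[str, GenomicInterval]]:
    """Coalesce per-window segments of the same region within one exon run."""
    merged: list[tuple[str, GenomicInterval]] = []
    for region, iv in segments:
        if merged and merged[-1][0] == region and merged[-1][1].end == iv.start:
            prev = merged[-1][1]
            merged[-1] = (region, GenomicInterval(prev.chrom, prev.start, iv.end, prev.strand))
        else:
            merged.append((region, iv))
    return merged


def window_grid(cfg: SimConfig, ann: TranscriptAnnotation) -> list[GenomicInterval]:
    """Contiguous fixed-width windows tiling the simulated chromosome."""
    w = cfg.window_size
    end = max(tx.span.end for tx in ann.transcripts.values()) + cfg.intergenic_windows * w
    return [GenomicInterval(cfg.chrom, s, s + w) for s in range(0, end, w)]


# ---------------------------------------------------------------------------
# acRIP / IgG / input coverage
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    n = 1.0 / phi
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _plan_peaks(cfg: SimConfig, ann: TranscriptAnnotation) -> GroundTruth:
    """Choose peak-bearing genes, their group pattern and CDS peak locations."""
    rng = np.random.default_rng((cfg.seed, 1))
    ga, gb = cfg.groups
    genes = ann.genes
    n_peak = int(round(cfg.peak_fraction * cfg.n_genes))
    peak_idx = np.sort(rng.choice(cfg.n_genes, size=n_peak, replace=False))
    order = rng.permutation(n_peak)
    n_excl = int(round(cfg.exclusive_fraction * n_peak))

    truth = GroundTruth()
    truth.true_detection["ac4c"] = {g: {ga: False, gb: False} for g in genes}
    truth.true_de_labels["ac4c"] = {g: "ns" for g in genes}
    for rank, j in enumerate(order):
        gi = int(peak_idx[j])
        gid = genes[gi]
        tx = ann.transcripts_of_gene(gid)[0]
        cds = [seg for region, seg in tx.segments if region == CDS]
        w = cfg.window_size
        candidates: list[tuple[int, int]] = []
        for seg in cds:
            for s in range(seg.start, seg.end - cfg.peak_windows * w + 1, w):
                candidates.append((s, s + cfg.peak_windows * w))
        start, end = candidates[int(rng.integers(len(candidates)))]
        if rank < n_excl:
            groups = (ga,) if rank % 2 == 0 else (gb,)
        else:
            groups = (ga, gb)
        for grp in groups:
            truth.true_peaks.append(
                {"gene": gid, "transcript": tx.transcript_id, "chrom": tx.chrom,
                 "start": start, "end": end, "group": grp,
                 "enrichment": cfg.enrichment_effect}
            )
            truth.true_detection["ac4c"][gid][grp] = True
        if groups == (ga,):
            truth.true_de_labels["ac4c"][gid] = "down" if ga == cfg.groups[0] else "up"
        elif groups == (gb,):
            truth.true_de_labels["ac4c"][gid] = "up" if gb == cfg.groups[1] else "down"
    return truth


def simulate_rip_coverage(
    cfg: SimConfig, ann: TranscriptAnnotation
) -> tuple[dict[str, OmicsMatrix], GroundTruth]:
    """Window counts for the three assays of every replicate of both groups.

    Input and IgG follow the negative-binomial background; acRIP windows
    inside a group's planted peaks have their mean multiplied by
    ``enrichment_effect``, and a planted set of runs of windows carries
    non-specific IgG enrichment shared by every sample.
    """
    truth = _plan_peaks(cfg, ann)
    windows = window_grid(cfg, ann)
    n_win = len(windows)
    win_start = np.array([iv.start for iv in windows])
    keys = [iv.key() for iv in windows]

    # IgG non-specific runs, shared across samples (sticky sequence, not noise)
    rng_igg = np.random.default_rng((cfg.seed, 5))
    igg_run_windows = max(2, cfg.peak_windows)
    n_runs = int(round(cfg.igg_peak_rate * n_win / igg_run_windows))
    igg_mask = np.zeros(n_win, dtype=bool)
    if n_runs:
        starts = rng_igg.choice(n_win - igg_run_windows, size=n_runs, replace=False)
        for s in starts:
            igg_mask[s:s + igg_run_windows] = True
    truth.igg_windows = [keys[i] for i in np.flatnonzero(igg_mask)]

    peak_mask = {g: np.zeros(n_win, dtype=bool) for g in cfg.groups}
    for p in truth.true_peaks:
        sel = (win_start >= p["start"]) & (win_start < p["end"])
        peak_mask[p["group"]] |= sel

    samples = [f"{g}_{r}" for g in cfg.groups for r in range(1, cfg.n_replicates + 1)]
    counts = {a: np.zeros((n_win, len(samples)), dtype=np.int64) for a in ASSAYS}

    # draw gene block by gene block with per-gene substreams (documented order:
    # per gene: assay x group x replicate); trailing windows use stream index n_genes
    genes = ann.genes
    blocks: list[np.ndarray] = []
    block_edges = []
    for gid in genes:
        tx = ann.transcripts_of_gene(gid)[0]
        block_edges.append(tx.span.end)
    prev = 0
    for edge_i, edge in enumerate(block_edges):
        nxt = block_edges[edge_i]
        hi = nxt + cfg.intergenic_windows * cfg.window_size
        blocks.append(np.flatnonzero((win_start >= prev) & (win_start < hi)))
        prev = hi
    tail = np.flatnonzero(win_start >= prev)
    if tail.size:
        blocks.append(tail)

    for bi, block in enumerate(blocks):
        rng = np.random.default_rng((cfg.seed, 2, bi))
        for a in ASSAYS:
            for si, s in enumerate(samples):
                grp = s.rpartition("_")[0]
                mean = np.full(block.size, cfg.background_mean)
                if a == "acRIP":
                    mean[peak_mask[grp][block]] *= cfg.enrichment_effect
                elif a == "IgG":
                    mean[igg_mask[block]] *= cfg.igg_enrichment
                counts[a][block, si] = _nb_draw(rng, mean, cfg.nb_dispersion)

    matrices = {
        a: OmicsMatrix(pd.DataFrame(counts[a], index=keys, columns=samples),
                       kind="count", assay=a)
        for a in ASSAYS
    }
    return matrices, truth


# ---------------------------------------------------------------------------
# RNA-seq counts and protein intensities
# ---------------------------------------------------------------------------

def simulate_expression(
    cfg: SimConfig, ann: TranscriptAnnotation, truth: GroundTruth
) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Gene-level RNA counts and protein intensities with planted effects.

    RNA expression is shared between groups (the disease model shows minimal
    transcript-level change); a small fraction of non-peak genes is planted
    as undetectable.  Proteins (one per gene) are log-normal; a planted
    fraction carries a log2 fold change drawn from ``protein_effects`` and a
    disjoint planted fraction is detected exclusively in one group (missing
    values, not zeros, in the other).
    """
    genes = ann.genes
    ga, gb = cfg.groups
    samples = [f"{g}_{r}" for g in cfg.groups for r in range(1, cfg.n_replicates + 1)]
    peak_genes = {p["gene"] for p in truth.true_peaks}

    rng_assign = np.random.default_rng((cfg.seed, 3))
    non_peak = [g for g in genes if g not in peak_genes]
    n_undet = int(round(cfg.rna_undetected_fraction * cfg.n_genes))
    n_undet = min(n_undet, len(non_peak))
    undetected = set(
        rng_assign.choice(len(non_peak), size=n_undet, replace=False).tolist()
    )
    rna_undetected = {non_peak[i] for i in undetected}

    # protein effect assignment on genes without exclusivity overlap
    rng_prot = np.random.default_rng((cfg.seed, 4))
    n_de = int(round(cfg.protein_de_fraction * cfg.n_genes))
    n_excl = int(round(cfg.exclusive_fraction * cfg.n_genes * 0.5))
    perm = rng_prot.permutation(cfg.n_genes)
    de_idx = set(perm[:n_de].tolist())
    excl_idx = perm[n_de:n_de + 2 * n_excl].tolist()
    excl_group = {int(i): (ga if k % 2 == 0 else gb) for k, i in enumerate(excl_idx)}

    truth.true_detection.setdefault("rna", {})
    truth.true_detection.setdefault("protein", {})
    truth.true_de_labels.setdefault("rna", {})
    truth.true_de_labels.setdefault("protein", {})

    rna = np.zeros((len(genes), len(samples)), dtype=np.int64)
    prot = np.full((len(genes), len(samples)), np.nan)
    for gi, gid in enumerate(genes):
        rng = np.random.default_rng((cfg.seed, 6, gi))
        mean = cfg.rna_mean * float(rng.lognormal(0.0, 1.0))
        if gid in rna_undetected:
            mean = 0.2
        rna[gi] = _nb_draw(rng, np.full(len(samples), mean), cfg.nb_dispersion)
        truth.true_detection["rna"][gid] = {
            ga: gid not in rna_undetected, gb: gid not in rna_undetected
        }
        truth.true_de_labels["rna"][gid] = "ns"

        lfc = 0.0
        if gi in de_idx:
            lfc = float(cfg.protein_effects[gi % len(cfg.protein_effects)])
        base = cfg.protein_base + 2.0 * float(rng.standard_normal())
        only = excl_group.get(gi)
        det = {ga: only in (None, ga), gb: only in (None, gb)}
        for si, s in enumerate(samples):
            grp = s.rpartition("_")[0]
            if not det[grp]:
                continue
            mu = base + (lfc if grp == gb else 0.0)
            prot[gi, si] = round(2.0 ** (mu + cfg.protein_sigma * float(rng.standard_normal())), 6)
        truth.true_protein_lfc[gid] = lfc
        truth.true_detection["protein"][gid] = det
        if only == ga:
            label = "down"
        elif only == gb:
            label = "up"
        elif lfc >= 1:
            label = "up"
        elif lfc <= -1:
            label = "down"
        else:
            label = "ns"
        truth.true_de_labels["protein"][gid] = label

    counts = OmicsMatrix(pd.DataFrame(rna, index=genes, columns=samples), kind="count")
    intens = OmicsMatrix(pd.DataFrame(prot, index=genes, columns=samples), kind="intensity")
    return counts, intens


# ---------------------------------------------------------------------------
# Composition generators: plant an exact detection/effect composition
# ---------------------------------------------------------------------------

def simulate_protein_composition(
    n_overlay_up: int,
    n_overlay_down: int,
    n_overlay_ns: int,
    n_group_a_only: int,
    n_group_b_only: int,
    *,
    groups: tuple[str, str] = ("WT", "FAD"),
    n_replicates: int = 3,
    lfc: float = 2.0,
    sigma: float = 0.1,
    base: float = 20.0,
    seed: int = 0,
    prefix: str = "P",
) -> tuple[OmicsMatrix, pd.Series]:
    """Protein intensity table with a planted detection/effect composition.

    Plants ``n_overlay_up`` shared proteins raised by ``lfc`` in group B,
    ``n_overlay_down`` lowered by ``lfc``, ``n_overlay_ns`` unchanged, plus
    group-exclusive proteins (missing in the other group).  Returns the
    matrix and the planted label per protein (up/down/ns at the composition
    level, a-only/b-only for exclusives).
    """
    ga, gb = groups
    rng = np.random.default_rng((seed, 11))
    samples = [f"{g}_{r}" for g in groups for r in range(1, n_replicates + 1)]
    blocks = [
        ("overlay-up", n_overlay_up, lfc, None),
        ("overlay-down", n_overlay_down, -lfc, None),
        ("overlay-ns", n_overlay_ns, 0.0, None),
        ("b-only", n_group_b_only, 0.0, gb),
        ("a-only", n_group_a_only, 0.0, ga),
    ]
    rows, labels, ids = [], [], []
    i = 0
    for label, n, effect, only in blocks:
        for _ in range(n):
            i += 1
            pid = f"{prefix}{i:06d}"
            b = base + 2.0 * float(rng.standard_normal())
            row = []
            for s in samples:
                grp = s.rpartition("_")[0]
                if only is not None and grp != only:
                    row.append(np.nan)
                    continue
                mu = b + (effect if grp == gb else 0.0)
                row.append(round(2.0 ** (mu + sigma * float(rng.standard_normal())), 6))
            rows.append(row)
            ids.append(pid)
            labels.append(label)
    m = OmicsMatrix(pd.DataFrame(rows, index=ids, columns=samples), kind="intensity")
    return m, pd.Series(labels, index=ids, name="planted")


def simulate_ac4c_composition(
    n_overlay_up: int,
    n_overlay_down: int,
    n_overlay_ns: int,
    n_group_a_only: int,
    n_group_b_only: int,
    *,
    groups: tuple[str, str] = ("WT", "FAD"),
    n_replicates: int = 3,
    fe_low: float = 1.0,
    fe_high: float = 4.0,
    fe_exclusive: float = 3.0,
    sigma: float = 0.05,
    seed: int = 0,
    prefix: str = "g",
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-replicate mRNA fold-enrichment table with a planted composition.

    Overlay-up genes carry FE ``fe_low`` in group A and ``fe_high`` in group
    B (so the pseudocounted fold change (FE+1 ratio) clears 2), overlay-down
    the reverse, overlay-ns equal FE; exclusive genes have FE only in their
    group (NaN, i.e. not detected, elsewhere).  Noise is applied on the
    log2(FE+1) scale.  Returns the replicate FE table (genes x samples) and
    planted labels.
    """
    ga, gb = groups
    rng = np.random.default_rng((seed, 12))
    samples = [f"{g}_{r}" for g in groups for r in range(1, n_replicates + 1)]
    blocks = [
        ("overlay-up", n_overlay_up, fe_low, fe_high),
        ("overlay-down", n_overlay_down, fe_high, fe_low),
        ("overlay-ns", n_overlay_ns, fe_high, fe_high),
        ("b-only", n_group_b_only, None, fe_exclusive),
        ("a-only", n_group_a_only, fe_exclusive, None),
    ]
    rows, labels, ids = [], [], []
    i = 0
    for label, n, fe_a, fe_b in blocks:
        for _ in range(n):
            i += 1
            gid = f"{prefix}{i:06d}"
            row = []
            for s in samples:
                grp = s.rpartition("_")[0]
                fe = fe_a if grp == ga else fe_b
                if fe is None:
                    row.append(np.nan)
                    continue
                noisy = 2.0 ** (np.log2(fe + 1.0) + sigma * float(rng.standard_normal())) - 1.0
                row.append(round(max(noisy, 0.0), 6))
            rows.append(row)
            ids.append(gid)
            labels.append(label)
    df = pd.DataFrame(rows, index=ids, columns=samples)
    return df, pd.Series(labels, index=ids, name="planted")


def verdict_composition(
    n_up_shared: int,
    n_up_only_a: int,
    n_up_only_b: int,
    n_down_shared: int,
    n_down_only_a: int,
    n_down_only_b: int,
    prefix: str = "g",
) -> tuple[pd.Series, pd.Series]:
    """Two verdict series (e.g. two timepoints) with a planted Venn structure."""
    ids, va, vb = [], [], []
    spec = [
        ("up", "up", n_up_shared),
        ("up", "ns", n_up_only_a),
        ("ns", "up", n_up_only_b),
        ("down", "down", n_down_shared),
        ("down", "ns", n_down_only_a),
        ("ns", "down", n_down_only_b),
    ]
    i = 0
    for a, b, n in spec:
        for _ in range(n):
            i += 1
            ids.append(f"{prefix}{i:06d}")
            va.append(a)
            vb.append(b)
    return pd.Series(va, index=ids, name="t1"), pd.Series(vb, index=ids, name="t2")
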