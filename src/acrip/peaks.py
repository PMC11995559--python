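"""Window-level enrichment scan and per-sample peak assembly.

Enrichment of IP (acRIP or IgG) over input is tested per fixed-width window
with an upper-tail Poisson probability whose null mean is the input count
scaled by the library-size ratio (floored at ``lambda_floor`` to avoid
zero-mean nulls), followed by Benjamini-Hochberg adjustment across all
windows of the sample.  Adjacent significant windows are merged into peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .genome import GenomicInterval, interval_from_key
from .matrix import OmicsMatrix
from .differential import bh_adjust


@dataclass
class SamplePeak:
    """An enriched interval in one sample/assay: a run of significant windows."""

    interval: GenomicInterval
    sample: str
    assay: str
    summit: GenomicInterval          # window of minimal p (ties: leftmost)
    peak_p: float                    # minimal window p
    peak_q: float                    # minimal window q over the peak
    n_sig_windows: int
    mean_ip: float = float("nan")    # depth-normalized (CPM) means, attached later
    mean_input: float = float("nan")
    mean_igg: float = float("nan")
    fe: float = float("nan")
    host_transcript: str | None = None
    host_gene: str | None = None
    region: str | None = None

    @property
    def name(self) -> str:
        return f"{self.sample}:{self.assay}:{self.interval.key()}"


def test_windows(
    ip: OmicsMatrix,
    input_: OmicsMatrix,
    sample: str,
    *,
    lambda_floor: float = 0.5,
    chrom_blacklist: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-window upper-tail Poisson test of IP enrichment over input.

    Returns a DataFrame indexed by window key with columns chrom, start,
    end, ip_count, input_count, scaled_lambda, p_value, q_value.  Windows
    on blacklisted chromosomes (e.g. chrM) are excluded before testing.
    """
    if list(ip.values.index) != list(input_.values.index):
        raise ConfigError("ip and input matrices are on different window grids")
    if lambda_floor <= 0:
        raise ConfigError("lambda_floor must be > 0")
    ip_lib = float(ip.values[sample].sum())
    input_lib = float(input_.values[sample].sum())
    if input_lib <= 0:
        raise ConfigError(f"sample {sample!r} has zero input library size")

    ivs = [interval_from_key(k) for k in ip.values.index]
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in ivs],
            "start": [iv.start for iv in ivs],
            "end": [iv.end for iv in ivs],
            "ip_count": ip.values[sample].to_numpy(),
            "input_count": input_.values[sample].to_numpy(),
        },
        index=ip.values.index,
    )
    if chrom_blacklist:
        df = df[~df["chrom"].isin(chrom_blacklist)].copy()

    lam = np.maximum(df["input_count"].to_numpy(float) * (ip_lib / input_lib), lambda_floor)
    # P(X >= ip_count) under Poisson(lam); sf(k-1) is the upper tail at k
    p = stats.poisson.sf(df["ip_count"].to_numpy() - 1, lam)
    df["scaled_lambda"] = lam
    df["p_value"] = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    return df


def call_sample_peaks(
    tests: pd.DataFrame,
    *,
    q_max: float = 0.05,
    min_windows: int = 2,
    merge_gap: int = 1,
    sample: str = "",
    assay: str = "acRIP",
) -> list[SamplePeak]:
    """Merge significant windows (q < q_max) into peaks.

    Significant windows on the same chromosome separated by at most
    ``merge_gap`` non-significant windows are merged; the resulting peak
    spans the gap.  Peaks supported by fewer than ``min_windows``
    significant windows are dropped.  The summit is the significant window
    of minimal p (ties: leftmost).
    """
    sig = tests[tests["q_value"] < q_max].sort_values(["chrom", "start"])
    if sig.empty:
        return []
    width = int(sig["end"].iloc[0] - sig["start"].iloc[0])
    peaks: list[SamplePeak] = []
    cluster: list[pd.Series] = []

    def flush(cluster: list[pd.Series]) -> None:
        if len(cluster) < min_windows:
            return
        chrom = cluster[0]["chrom"]
        start, end = int(cluster[0]["start"]), int(cluster[-1]["end"])
        best = min(cluster, key=lambda r: (r["p_value"], r["start"]))
        peaks.append(
            SamplePeak(
                interval=GenomicInterval(chrom, start, end),
                sample=sample,
                assay=assay,
                summit=GenomicInterval(chrom, int(best["start"]), int(best["end"])),
                peak_p=float(best["p_value"]),
                peak_q=float(min(r["q_value"] for r in cluster)),
                n_sig_windows=len(cluster),
            )
        )

    for _, row in sig.iterrows():
        if cluster and (
            row["chrom"] != cluster[-1]["chrom"]
            or (row["start"] - cluster[-1]["end"]) > merge_gap * width
        ):
            flush(cluster)
            cluster = []
        cluster.append(row)
    flush(cluster)
    return peaks


def peaks_to_bed(peaks: list[SamplePeak]) -> list[tuple[GenomicInterval, list[str]]]:
    """BED4+ records: name, peak_p, peak_q, summit offset within the peak."""
    records = []
    for pk in sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start)):
        records.append(
            (
                pk.interval,
                [
                    pk.name,
                    f"{pk.peak_p:.6g}",
                    f"{pk.peak_q:.6g}",
                    str(pk.summit.start - pk.interval.start),
                ],
            )
        )
    return records
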