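"""Cross-omics layer: Venn classes, 3x3 verdict cross-classification,
distribution comparisons, PCA, FE-distribution fit and stage specificity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, FitError
from .matrix import OmicsMatrix

VERDICTS = ("up", "ns", "down")

# Cross-omics group numbering over (protein verdict, ac4C verdict).  The two
# anchors are fixed by convention — group 1 is protein-up & ac4C-up, group 7
# protein-down & ac4C-down — and the remaining cells are enumerated row-major
# over (up, ns, down) x (up, ns, down) with the third row reversed so both
# anchors hold.
CROSS_GROUP_INDEX: dict[tuple[str, str], int] = {
    ("up", "up"): 1, ("up", "ns"): 2, ("up", "down"): 3,
    ("ns", "up"): 4, ("ns", "ns"): 5, ("ns", "down"): 6,
    ("down", "down"): 7, ("down", "ns"): 8, ("down", "up"): 9,
}


# ---------------------------------------------------------------------------
# Venn classes
# ---------------------------------------------------------------------------

def venn_classify(
    detected_a: set[str], detected_b: set[str],
    *, labels: tuple[str, str, str] = ("AD absent", "Overlay", "AD unique"),
) -> tuple[pd.Series, tuple[int, int, int]]:
    """Partition features into (only A, both, only B) detection classes.

    Returns per-feature classes and the counts triple
    (|A only|, |both|, |B only|) in the label order given.
    """
    only_a = detected_a - detected_b
    both = detected_a & detected_b
    only_b = detected_b - detected_a
    classes = {}
    for f in only_a:
        classes[f] = labels[0]
    for f in both:
        classes[f] = labels[1]
    for f in only_b:
        classes[f] = labels[2]
    series = pd.Series(classes, name="venn_class").sort_index()
    return series, (len(only_a), len(both), len(only_b))


# ---------------------------------------------------------------------------
# Cross-omics classification
# ---------------------------------------------------------------------------

def cross_classify(
    protein_verdicts: pd.Series, ac4c_verdicts: pd.Series
) -> tuple[pd.DataFrame, dict[int, int]]:
    """3x3 cross-classification of per-gene protein and ac4C verdicts.

    Only genes present in both layers are classified.  Returns the per-gene
    table (protein_verdict, ac4c_verdict, group) and counts per group
    index; "differential at both levels" is the sum of the four corner
    groups (1, 3, 7, 9).
    """
    shared = protein_verdicts.index.intersection(ac4c_verdicts.index)
    rows = []
    for g in sorted(shared):
        pv, av = str(protein_verdicts[g]), str(ac4c_verdicts[g])
        if pv not in VERDICTS or av not in VERDICTS:
            raise ConfigError(f"unknown verdict {pv!r}/{av!r} for {g!r}")
        rows.append((g, pv, av, CROSS_GROUP_INDEX[(pv, av)]))
    df = pd.DataFrame(rows, columns=["gene", "protein_verdict", "ac4c_verdict", "group"])
    df = df.set_index("gene")
    counts = {i: int((df["group"] == i).sum()) for i in range(1, 10)}
    return df, counts


def both_de_count(counts: dict[int, int]) -> int:
    """Genes differential at both omics levels (neither verdict ns)."""
    return counts[1] + counts[3] + counts[7] + counts[9]


# ---------------------------------------------------------------------------
# Distribution comparisons
# ---------------------------------------------------------------------------

def ks_compare(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigError("KS test requires two non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def chi2_yates(table) -> tuple[float, float]:
    """Chi-square test of a 2x2 table with Yates continuity correction.

    chi2 = sum (max(|O - E| - 0.5, 0))^2 / E with 1 degree of freedom.
    """
    t = np.asarray(table, dtype=float)
    _check_2x2(t)
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    expected = np.outer(row, col) / n
    adj = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    chi2 = float((adj ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def phi_coefficient(table) -> float:
    """Phi association coefficient of a 2x2 table: (ad - bc)/sqrt(margins)."""
    t = np.asarray(table, dtype=float)
    _check_2x2(t)
    (a, b), (c, d) = t
    denom = np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    return float((a * d - b * c) / denom)


def _check_2x2(t: np.ndarray) -> None:
    if t.shape != (2, 2):
        raise ConfigError("expected a 2x2 table")
    if (t < 0).any():
        raise ConfigError("table entries must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ConfigError("2x2 table has a zero margin")


# ---------------------------------------------------------------------------
# PCA and correlation structure
# ---------------------------------------------------------------------------

def pca_top_mad(
    matrix: OmicsMatrix | pd.DataFrame,
    *,
    variance_floor: float | None = None,
    mad_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """PCA of samples after variance and MAD feature selection.

    Features with variance <= ``variance_floor`` (if given) are excluded,
    then only the top ``mad_fraction`` of features by median absolute
    deviation are kept (ties at the cutoff are kept).  Features with any
    missing value are excluded (PCA needs complete rows).  Features are
    centered and the sample scores computed by SVD.

    Returns (scores with explained-variance fractions as attrs, loadings,
    kept feature ids).
    """
    values = matrix.values if isinstance(matrix, OmicsMatrix) else pd.DataFrame(matrix)
    if values.shape[1] < 3:
        raise ConfigError("PCA requires at least 3 samples")
    complete = values.dropna(axis=0)
    if variance_floor is not None:
        complete = complete[complete.var(axis=1, ddof=1) > variance_floor]
    mad = (complete.sub(complete.median(axis=1), axis=0)).abs().median(axis=1)
    if len(mad) == 0:
        raise ConfigError("no features left after variance filtering")
    cutoff = mad.quantile(1.0 - mad_fraction, interpolation="higher")
    kept = complete[mad >= cutoff]
    x = kept.to_numpy(float) - kept.to_numpy(float).mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)  # samples x features
    k = min(x.shape)
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=kept.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    loadings = pd.DataFrame(
        vt[:k].T, index=kept.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    total = float((s ** 2).sum())
    scores.attrs["explained_variance_ratio"] = (
        (s[:k] ** 2 / total).tolist() if total > 0 else [0.0] * k
    )
    return scores, loadings, list(kept.index)


def spearman_matrix(matrix: OmicsMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise sample-sample Spearman correlations on shared non-missing features."""
    values = matrix.values if isinstance(matrix, OmicsMatrix) else pd.DataFrame(matrix)
    samples = list(values.columns)
    if len(samples) < 2:
        raise ConfigError("need at least 2 samples for a correlation matrix")
    out = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    for i, a in enumerate(samples):
        for j in range(i + 1, len(samples)):
            b = samples[j]
            pair = values[[a, b]].dropna()
            if len(pair) < 3:
                rho = np.nan
            else:
                rho = float(stats.spearmanr(pair[a], pair[b]).statistic)
            out.loc[a, b] = out.loc[b, a] = rho
    return out


# ---------------------------------------------------------------------------
# FE distribution fit
# ---------------------------------------------------------------------------

@dataclass
class DistributionFit:
    """Least-squares Gaussian fit to a histogram of log10 FE values."""

    bin_centers: np.ndarray
    counts: np.ndarray
    amplitude: float
    mean: float
    sd: float
    area: float          # amplitude * sd * sqrt(2*pi)
    residual: float      # root-mean-square residual of the fit


def fit_fe_distribution(fes, *, bin_width: float = 0.1) -> DistributionFit:
    """Histogram log10(FE) and fit a Gaussian a*exp(-(x-mu)^2 / 2 sigma^2)."""
    fes = np.asarray(fes, dtype=float)
    fes = fes[fes > 0]
    if fes.size < 3:
        raise FitError("need at least 3 positive FE values")
    x = np.log10(fes)
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    if np.count_nonzero(counts) < 3:
        raise FitError(
            f"degenerate histogram ({np.count_nonzero(counts)} occupied bins); "
            "cannot fit a Gaussian"
        )

    def gauss(x, a, mu, sd):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sd ** 2))

    w = counts / counts.sum()
    mu0 = float((centers * w).sum())
    sd0 = float(np.sqrt(max(((centers - mu0) ** 2 * w).sum(), bin_width ** 2)))
    try:
        popt, _ = optimize.curve_fit(
            gauss, centers, counts, p0=(counts.max(), mu0, sd0), maxfev=10000
        )
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    a, mu, sd = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    if sd <= 0 or not np.isfinite(sd):
        raise FitError("degenerate fit: sd undefined")
    resid = float(np.sqrt(np.mean((gauss(centers, *popt) - counts) ** 2)))
    return DistributionFit(centers, counts, a, mu, sd, a * sd * np.sqrt(2 * np.pi), resid)


# ---------------------------------------------------------------------------
# Stage specificity across timepoints
# ---------------------------------------------------------------------------

def stage_specificity(
    verdicts_t1: pd.Series, verdicts_t2: pd.Series
) -> tuple[dict[str, int], float]:
    """Fraction of first-timepoint calls not reproduced at the second.

    Per direction, the overlap counts genes with the same non-ns verdict at
    both timepoints; specificity = 1 - (overlap_up + overlap_down) /
    (t1_up + t1_down).
    """
    overlap = {"up": 0, "down": 0}
    t1_counts = {"up": 0, "down": 0}
    for direction in ("up", "down"):
        t1_set = set(verdicts_t1.index[verdicts_t1 == direction])
        t2_set = set(verdicts_t2.index[verdicts_t2 == direction])
        overlap[direction] = len(t1_set & t2_set)
        t1_counts[direction] = len(t1_set)
    total_t1 = t1_counts["up"] + t1_counts["down"]
    if total_t1 == 0:
        return overlap, 0.0
    spec = 1.0 - (overlap["up"] + overlap["down"]) / total_t1
    return overlap, spec
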