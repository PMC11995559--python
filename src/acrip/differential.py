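"""Differential calling: empirical-Bayes moderated t, exact count test,
Benjamini-Hochberg adjustment, and exclusive-detection rules.

The moderated t-statistic follows the empirical-Bayes variance-shrinkage
formulation of Smyth (2004): per-feature residual variances ``s_g^2`` with
``d_g`` residual degrees of freedom are assumed to follow a scaled
inverse-chi-square prior with hyperparameters ``(d0, s0^2)`` estimated by
moment matching on the log scale; the posterior variance
``s_post^2 = (d0 s0^2 + d s^2) / (d0 + d)`` replaces ``s^2`` in an ordinary
two-sample t with ``d0 + d`` total degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConfigError
from .matrix import OmicsMatrix


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, tie-stable)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ConfigError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Smyth-style variance shrinkage
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ConfigError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled inverse-chi-square variance prior.

    Moment matching of log(s^2) whose distribution under the prior is a
    location-shifted log-F: the excess variance of log(s^2) beyond the
    within-feature trigamma(df/2) term identifies d0, and the mean
    identifies s0^2.  d0 = inf (no excess variance) means complete
    shrinkage to a common value.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ConfigError("need at least two positive variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def squeeze_variances(s2: np.ndarray, df: float, d0: float, s02: float) -> np.ndarray:
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, float), s02)
    return (d0 * s02 + df * np.asarray(s2, float)) / (d0 + df)


@dataclass
class ModeratedTTestResults:
    """Results of a two-group empirical-Bayes moderated t-test."""

    table: pd.DataFrame      # feature-indexed: mean_a, mean_b, lfc, s2, s2_post, t, df_total, p, adj_p
    d0: float                # prior degrees of freedom
    s02: float               # prior variance
    df_residual: float
    groups: tuple[str, str]

    def summary(self) -> str:
        n = len(self.table)
        n_sig = int((self.table["adj_p"] < 0.05).sum())
        lines = [
            "Empirical-Bayes moderated t-test",
            f"  contrast: {self.groups[1]} - {self.groups[0]} (log2 scale)",
            f"  features tested: {n}",
            f"  residual df: {self.df_residual:g}   prior df d0: {self.d0:g}   "
            f"prior variance s0^2: {self.s02:.4g}",
            f"  adj. p < 0.05: {n_sig}",
        ]
        return "\n".join(lines)


class ModeratedTTest:
    """Two-group moderated t-test on a log2-scale features x samples matrix.

    Parameters
    ----------
    data:
        DataFrame of log2 values (features x samples) or an
        :class:`~acrip.matrix.OmicsMatrix` already log-transformed.
    groups:
        Ordered pair of group labels; the reported log fold change is
        group2 minus group1.  If omitted, taken from the sample ids.

    Features with missing values or fewer than two replicates in either
    group are excluded from the test (they belong to the exclusive-
    detection path, not the overlay test).
    """

    def __init__(self, data, groups: tuple[str, str] | None = None):
        if isinstance(data, OmicsMatrix):
            self._values = data.values
            inferred = tuple(data.groups)
        else:
            self._values = pd.DataFrame(data)
            seen: list[str] = []
            for s in self._values.columns:
                g = str(s).rpartition("_")[0]
                if g not in seen:
                    seen.append(g)
            inferred = tuple(seen)
        self.groups = tuple(groups) if groups else inferred
        if len(self.groups) != 2:
            raise ConfigError("moderated t-test requires exactly two groups")

    def fit(self) -> ModeratedTTestResults:
        ga, gb = self.groups
        cols_a = [s for s in self._values.columns if str(s).rpartition("_")[0] == ga]
        cols_b = [s for s in self._values.columns if str(s).rpartition("_")[0] == gb]
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise ConfigError("each group needs at least two replicates")
        a = self._values[cols_a].to_numpy(float)
        b = self._values[cols_b].to_numpy(float)
        complete = ~np.isnan(a).any(axis=1) & ~np.isnan(b).any(axis=1)
        a, b = a[complete], b[complete]
        index = self._values.index[complete]
        n1, n2 = a.shape[1], b.shape[1]
        df = float(n1 + n2 - 2)

        mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
        ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
        s2 = ss / df
        d0, s02 = fit_variance_prior(s2, df)
        s2_post = squeeze_variances(s2, df, d0, s02)
        lfc = mean_b - mean_a
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = lfc / se
        df_total = df + d0
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
        table = pd.DataFrame(
            {
                "mean_a": mean_a,
                "mean_b": mean_b,
                "lfc": lfc,
                "s2": s2,
                "s2_post": s2_post,
                "t": t,
                "df_total": df_total,
                "p": p,
                "adj_p": bh_adjust(p),
            },
            index=index,
        )
        return ModeratedTTestResults(table, d0, s02, df, (ga, gb))


def moderated_t(values, groups: tuple[str, str] | None = None) -> pd.DataFrame:
    """Functional wrapper: fit the moderated t-test and return its table."""
    return ModeratedTTest(values, groups).fit().table


# ---------------------------------------------------------------------------
# Exact two-group count test
# ---------------------------------------------------------------------------

def exact_count_test(c1: int, c2: int, lib1: float, lib2: float) -> float:
    """Two-sided exact test of a two-group count split.

    Conditional on the total n = c1 + c2, c1 is Binomial(n, pi0) under the
    null with pi0 = lib1 / (lib1 + lib2); the two-sided p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    Zero totals give p = 1.
    """
    if min(c1, c2) < 0:
        raise ConfigError("counts must be non-negative")
    if lib1 <= 0 or lib2 <= 0:
        raise ConfigError("library sizes must be positive")
    n = int(c1) + int(c2)
    if n == 0:
        return 1.0
    pi0 = lib1 / (lib1 + lib2)
    return float(stats.binomtest(int(c1), n, pi0, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Verdicts
# ---------------------------------------------------------------------------

LAYERS = ("protein", "ac4c", "rna")


@dataclass
class Thresholds:
    """Layer significance/fold-change thresholds."""

    alpha: float = 0.05
    fc_cut: float = 2.0
    rna_use_adjusted: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.fc_cut <= 1:
            raise ConfigError("fc_cut must be > 1")


def call_de(
    layer: str,
    overlay: pd.DataFrame | None,
    detected_a: set[str],
    detected_b: set[str],
    fc: pd.Series | None = None,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Assign up/down/ns verdicts for one omics layer.

    Overlay features (detected in both groups) are judged by the layer's
    significance rule together with fold change >= fc_cut (up) or
    <= 1/fc_cut (down).  Exclusive features follow the layer's
    exclusive-detection rule: proteins are called unconditionally
    (detected only in group B -> up, only in group A -> down); exclusive
    ac4C mRNAs must still clear the fold-change cut (their pseudocounted
    fold change is computable from the detected group alone); RNA has no
    exclusive rule.  ``fc`` supplies fold changes on the natural scale; for
    protein/rna overlay features it defaults to 2**lfc from the overlay
    table.

    Returns a DataFrame with columns feature, layer, verdict, basis.
    """
    if layer not in LAYERS:
        raise ConfigError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    th = thresholds or Thresholds()
    overlay = overlay if overlay is not None else pd.DataFrame(columns=["lfc", "p", "adj_p"])
    fc = fc if fc is not None else pd.Series(dtype=float)

    rows: list[tuple[str, str, str, str]] = []
    both = detected_a & detected_b
    only_a = detected_a - detected_b
    only_b = detected_b - detected_a

    pcol = "p" if (layer == "rna" and not th.rna_use_adjusted) else "adj_p"
    for feat in sorted(both):
        if feat not in overlay.index:
            rows.append((feat, layer, "ns", "overlay-test"))
            continue
        rec = overlay.loc[feat]
        f = float(fc[feat]) if feat in fc.index else float(2.0 ** rec["lfc"])
        sig = float(rec[pcol]) < th.alpha
        if sig and f >= th.fc_cut:
            v = "up"
        elif sig and f <= 1.0 / th.fc_cut:
            v = "down"
        else:
            v = "ns"
        rows.append((feat, layer, v, "overlay-test"))

    for feat in sorted(only_b):
        if layer == "protein":
            rows.append((feat, layer, "up", "exclusive-rule"))
        elif layer == "ac4c":
            f = float(fc.get(feat, np.nan))
            v = "up" if f >= th.fc_cut else "down" if f <= 1.0 / th.fc_cut else "ns"
            rows.append((feat, layer, v, "exclusive-rule"))
        else:
            rows.append((feat, layer, "ns", "exclusive-rule"))
    for feat in sorted(only_a):
        if layer == "protein":
            rows.append((feat, layer, "down", "exclusive-rule"))
        elif layer == "ac4c":
            f = float(fc.get(feat, np.nan))
            v = "up" if f >= th.fc_cut else "down" if f <= 1.0 / th.fc_cut else "ns"
            rows.append((feat, layer, v, "exclusive-rule"))
        else:
            rows.append((feat, layer, "ns", "exclusive-rule"))

    df = pd.DataFrame(rows, columns=["feature", "layer", "verdict", "basis"])
    return df.set_index("feature").sort_index()


def rna_differential(
    counts: OmicsMatrix, groups: tuple[str, str] | None = None
) -> pd.DataFrame:
    """Per-gene exact count test between two groups with library-size scaling.

    Group counts are pooled over replicates; fold change is the ratio of
    library-size-normalized pooled counts with a half-count pseudocount.
    """
    gs = tuple(groups) if groups else tuple(counts.groups)
    if len(gs) != 2:
        raise ConfigError("rna_differential requires exactly two groups")
    ga, gb = gs
    cols_a, cols_b = counts.samples_of_group(ga), counts.samples_of_group(gb)
    c_a = counts.values[cols_a].sum(axis=1).astype(int)
    c_b = counts.values[cols_b].sum(axis=1).astype(int)
    lib_a = float(c_a.sum())
    lib_b = float(c_b.sum())
    p = np.array([exact_count_test(int(a), int(b), lib_a, lib_b) for a, b in zip(c_a, c_b)])
    fc = ((c_b + 0.5) / lib_b) / ((c_a + 0.5) / lib_a)
    return pd.DataFrame(
        {
            "count_a": c_a,
            "count_b": c_b,
            "fc": fc,
            "lfc": np.log2(fc),
            "p": p,
            "adj_p": bh_adjust(p),
        },
        index=counts.values.index,
    )
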