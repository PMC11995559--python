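import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from acrip.differential import (
    ModeratedTTest,
    Thresholds,
    bh_adjust,
    call_de,
    exact_count_test,
    fit_variance_prior,
    moderated_t,
    rna_differential,
    squeeze_variances,
    trigamma_inverse,
)
from acrip.errors import ConfigError
from acrip.matrix import OmicsMatrix


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

class TestBH:
    def test_hand_oracle(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
            [0.04, 0.04, 0.04, 0.04], rtol=1e-12)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.3])), [0.3])

    def test_capped_at_one_and_monotone(self):
        p = np.array([0.9, 0.95, 0.5, 1.0])
        adj = bh_adjust(p)
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_ties_get_equal_adjustment(self):
        adj = bh_adjust(np.array([0.02, 0.02, 0.8]))
        assert adj[0] == adj[1]

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.1], [np.nan]])
    def test_invalid_pvalues_rejected(self, bad):
        with pytest.raises(ConfigError):
            bh_adjust(np.array(bad))

    def test_empty_input_passthrough(self):
        assert bh_adjust(np.array([])).size == 0

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(1e-12, 1, size=rng.integers(1, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-10)


# ---------------------------------------------------------------------------
# Variance prior / moderated t
# ---------------------------------------------------------------------------

class TestTrigammaInverse:
    @pytest.mark.parametrize("x", [0.01, 0.5, 1.0, 5.0, 123.0])
    def test_inverts_trigamma(self, x):
        y = float(special.polygamma(1, x))
        assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)

    def test_requires_positive(self):
        with pytest.raises(ConfigError):
            trigamma_inverse(0.0)


def _brute_force_moderated(a: np.ndarray, b: np.ndarray):
    """Independent scalar implementation of the Smyth closed forms."""
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2
    s2, lfc = [], []
    for i in range(a.shape[0]):
        xa, xb = a[i], b[i]
        ss = ((xa - xa.mean()) ** 2).sum() + ((xb - xb.mean()) ** 2).sum()
        s2.append(ss / df)
        lfc.append(xb.mean() - xa.mean())
    s2 = np.array(s2)
    # hyperparameters: log-scale moment matching (Smyth 2004 eq. 4-7)
    z = np.log(s2)
    e = z - special.digamma(df / 2) + math.log(df / 2)
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2))
    if evar > 0:
        # invert trigamma by bisection (independent of the package's Newton)
        lo, hi = 1e-8, 1e8
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if float(special.polygamma(1, mid)) > evar:
                lo = mid
            else:
                hi = mid
        d0 = 2 * lo
        s02 = math.exp(e.mean() + float(special.digamma(d0 / 2)) - math.log(d0 / 2))
    else:
        d0, s02 = math.inf, math.exp(e.mean())
    out = []
    for i in range(a.shape[0]):
        sp = s02 if math.isinf(d0) else (d0 * s02 + df * s2[i]) / (d0 + df)
        t = lfc[i] / math.sqrt(sp * (1 / n1 + 1 / n2))
        if math.isinf(d0):
            p = 2 * stats.norm.sf(abs(t))
        else:
            p = 2 * stats.t.sf(abs(t), df + d0)
        out.append((lfc[i], sp, t, p))
    return d0, s02, out


class TestModeratedT:
    def test_matches_independent_implementation_100_matrices(self):
        rng = np.random.default_rng(42)
        for k in range(100):
            nfeat = int(rng.integers(10, 40))
            a = rng.normal(0, rng.uniform(0.5, 2), size=(nfeat, 4))
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), size=(nfeat, 4))
            df = pd.DataFrame(
                np.hstack([a, b]),
                columns=[f"WT_{i+1}" for i in range(4)] + [f"FAD_{i+1}" for i in range(4)],
                index=[f"g{i}" for i in range(nfeat)])
            res = ModeratedTTest(df).fit()
            d0, s02, rows = _brute_force_moderated(a, b)
            if math.isinf(d0):
                assert math.isinf(res.d0)
            else:
                assert res.d0 == pytest.approx(d0, rel=1e-6)
            assert res.s02 == pytest.approx(s02, rel=1e-10)
            for i, (lfc, sp, t, p) in enumerate(rows):
                row = res.table.iloc[i]
                assert row["lfc"] == pytest.approx(lfc, abs=1e-10)
                assert row["s2_post"] == pytest.approx(sp, rel=1e-10)
                assert row["t"] == pytest.approx(t, rel=1e-10)
                # a 1e-10 relative error in t amplifies through the tail
                # function by a factor ~|t|, so p is compared at 1e-6
                assert row["p"] == pytest.approx(p, rel=1e-6, abs=1e-12)

    def test_d0_zero_limit_is_pooled_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(30, 3))
        b = rng.normal(size=(30, 3))
        s2 = (((a - a.mean(1, keepdims=True)) ** 2).sum(1)
              + ((b - b.mean(1, keepdims=True)) ** 2).sum(1)) / 4
        # with d0 -> 0 the squeezed variance is the sample variance, and the
        # moderated t equals the classical pooled two-sample t
        sp = squeeze_variances(s2, df=4.0, d0=0.0, s02=123.0)
        np.testing.assert_allclose(sp, s2, rtol=1e-12)
        t_mod = (b.mean(1) - a.mean(1)) / np.sqrt(sp * (1 / 3 + 1 / 3))
        t_ref = stats.ttest_ind(b, a, axis=1, equal_var=True).statistic
        np.testing.assert_allclose(t_mod, t_ref, rtol=1e-10)

    def test_equal_variances_complete_shrinkage(self):
        # all features share s^2 = c exactly: zero excess variance of log s^2,
        # so d0 = inf and every posterior variance collapses to the common
        # prior value s0^2 = c * exp(log(df/2) - digamma(df/2)), the
        # bias-corrected back-transform of mean(log s^2) (Smyth 2004 eq. 5).
        c, df = 0.7, 4.0
        d0, s02 = fit_variance_prior(np.full(10, c), df=df)
        assert math.isinf(d0)
        expected = c * math.exp(math.log(df / 2) - float(special.digamma(df / 2)))
        assert s02 == pytest.approx(expected, rel=1e-12)
        squeezed = squeeze_variances(np.full(10, c), df, d0, s02)
        np.testing.assert_allclose(squeezed, s02, rtol=1e-12)

    def test_null_calibration_2000_features(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(2000, 6))
        df = pd.DataFrame(x, columns=["WT_1", "WT_2", "WT_3",
                                      "FAD_1", "FAD_2", "FAD_3"])
        table = moderated_t(df)
        frac = float((table["p"] < 0.05).mean())
        assert 0.035 <= frac <= 0.065

    def test_missing_and_underreplicated_features_excluded(self):
        df = pd.DataFrame(
            {"WT_1": [1.0, 0.5, 1.0, np.nan], "WT_2": [2.0, 0.7, 1.5, 2.0],
             "FAD_1": [3.0, 0.9, np.nan, 3.0], "FAD_2": [4.0, 1.1, 2.0, 4.0],
             "WT_3": [1.5, 0.6, 1.2, 1.0], "FAD_3": [3.5, 1.0, 2.5, 2.0]},
            index=["ok1", "ok2", "miss_b", "miss_a"])
        table = moderated_t(df)
        assert list(table.index) == ["ok1", "ok2"]

    def test_single_replicate_group_rejected(self):
        df = pd.DataFrame({"WT_1": [1.0, 2.0], "FAD_1": [1.0, 2.0],
                           "FAD_2": [1.0, 2.0]})
        with pytest.raises(ConfigError, match="two replicates"):
            moderated_t(df)

    def test_explicit_group_order_flips_sign(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(20, 6)),
                          columns=["WT_1", "WT_2", "WT_3",
                                   "FAD_1", "FAD_2", "FAD_3"])
        fwd = moderated_t(df, groups=("WT", "FAD"))
        rev = moderated_t(df, groups=("FAD", "WT"))
        np.testing.assert_allclose(fwd["lfc"], -rev["lfc"], rtol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-12)

    def test_summary_mentions_key_quantities(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(50, 6)),
                          columns=["WT_1", "WT_2", "WT_3",
                                   "FAD_1", "FAD_2", "FAD_3"])
        res = ModeratedTTest(df).fit()
        s = res.summary()
        assert "moderated t" in s
        assert "features tested: 50" in s
        assert "FAD - WT" in s

    def test_matches_limma_ebayes(self, tmp_path):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, size=(80, 6))
        x[:20, 3:] += rng.normal(1.0, 0.2, size=(20, 3))
        df = pd.DataFrame(x, columns=["WT_1", "WT_2", "WT_3",
                                      "FAD_1", "FAD_2", "FAD_3"],
                          index=[f"g{i}" for i in range(80)])
        data_path = tmp_path / "x.tsv"
        df.to_csv(data_path, sep="\t")
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            x <- as.matrix(read.delim(args[1], row.names=1))
            design <- cbind(Intercept=1, FAD=rep(c(0,1), each=3))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(lfc=fit$coefficients[, "FAD"],
                              t=fit$t[, "FAD"], p=fit$p.value[, "FAD"],
                              d0=fit$df.prior, s02=fit$s2.prior)
            write.table(format(out, digits=12), args[2], sep="\\t", quote=FALSE)
        """)
        (tmp_path / "limma.R").write_text(script)
        out_path = tmp_path / "limma_out.tsv"
        subprocess.run(["Rscript", str(tmp_path / "limma.R"), str(data_path),
                        str(out_path)], check=True, capture_output=True)
        ref = pd.read_csv(out_path, sep="\t")
        res = ModeratedTTest(df).fit()
        assert res.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-6)
        assert res.s02 == pytest.approx(float(ref["s02"].iloc[0]), rel=1e-6)
        np.testing.assert_allclose(res.table["lfc"], ref["lfc"], rtol=1e-8)
        np.testing.assert_allclose(res.table["t"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(res.table["p"], ref["p"], rtol=1e-5)


# ---------------------------------------------------------------------------
# Exact count test
# ---------------------------------------------------------------------------

class TestExactCountTest:
    def test_extreme_split_equal_libraries(self):
        assert exact_count_test(10, 0, 1e6, 1e6) == pytest.approx(2 * 0.5 ** 10,
                                                                  rel=1e-12)

    def test_balanced_split_p_one(self):
        assert exact_count_test(5, 5, 1e6, 1e6) == pytest.approx(1.0)

    def test_zero_total_p_one(self):
        assert exact_count_test(0, 0, 1e6, 1e6) == 1.0

    def test_library_ratio_shifts_null(self):
        # pi0 = 3/4: observing 75 of 100 in the larger library is null-like
        assert exact_count_test(75, 25, 3e6, 1e6) > 0.5
        assert exact_count_test(25, 75, 3e6, 1e6) < 1e-10

    def test_matches_minlik_enumeration(self):
        for n, pi0 in [(7, 0.5), (12, 0.3), (25, 0.7)]:
            pmf = stats.binom.pmf(np.arange(n + 1), n, pi0)
            for c1 in range(n + 1):
                # scipy's two-sided minlik rule uses a 1e-7 relative tolerance
                oracle = float(pmf[pmf <= pmf[c1] * (1 + 1e-7)].sum())
                lib1 = pi0
                lib2 = 1 - pi0
                assert exact_count_test(c1, n - c1, lib1, lib2) == pytest.approx(
                    min(oracle, 1.0), rel=1e-9)

    def test_type_i_error_at_most_nominal_totals_up_to_30(self):
        for n in range(1, 31):
            pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
            rej = sum(pmf[c] for c in range(n + 1)
                      if exact_count_test(c, n - c, 1.0, 1.0) < 0.05)
            assert rej <= 0.05 + 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigError):
            exact_count_test(-1, 2, 1.0, 1.0)
        with pytest.raises(ConfigError):
            exact_count_test(1, 2, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Verdicts
# ---------------------------------------------------------------------------

def _overlay(rows):
    return pd.DataFrame(rows, columns=["lfc", "p", "adj_p"],
                        index=[f"f{i}" for i in range(len(rows))])


class TestCallDE:
    def test_overlay_requires_significance_and_fold_change(self):
        ov = _overlay([(2.0, 1e-4, 1e-3),    # up
                       (-2.0, 1e-4, 1e-3),   # down
                       (2.0, 0.5, 0.9),      # big fc, not significant
                       (0.5, 1e-4, 1e-3)])   # significant, small fc
        det = set(ov.index)
        out = call_de("protein", ov, det, det)
        assert out.loc["f0", "verdict"] == "up"
        assert out.loc["f1", "verdict"] == "down"
        assert out.loc["f2", "verdict"] == "ns"
        assert out.loc["f3", "verdict"] == "ns"
        assert (out["basis"] == "overlay-test").all()

    def test_protein_exclusive_rule_unconditional(self):
        out = call_de("protein", None, {"a_only"}, {"b_only"})
        assert out.loc["b_only", "verdict"] == "up"
        assert out.loc["a_only", "verdict"] == "down"
        assert (out["basis"] == "exclusive-rule").all()

    def test_ac4c_exclusive_needs_fold_change(self):
        # AD-absent gene with fe_wt=3 -> fc=0.25 <= 0.5 -> down
        fc = pd.Series({"absent_strong": 0.25, "absent_weak": 0.8,
                        "unique_strong": 4.0})
        out = call_de("ac4c", None,
                      {"absent_strong", "absent_weak"}, {"unique_strong"}, fc=fc)
        assert out.loc["absent_strong", "verdict"] == "down"
        assert out.loc["absent_weak", "verdict"] == "ns"
        assert out.loc["unique_strong", "verdict"] == "up"

    def test_rna_has_no_exclusive_rule(self):
        out = call_de("rna", None, {"a_only"}, {"b_only"})
        assert (out["verdict"] == "ns").all()

    def test_rna_raw_p_option(self):
        ov = _overlay([(2.0, 0.01, 0.2)])
        det = set(ov.index)
        adj = call_de("rna", ov, det, det,
                      thresholds=Thresholds(rna_use_adjusted=True))
        raw = call_de("rna", ov, det, det,
                      thresholds=Thresholds(rna_use_adjusted=False))
        assert adj.loc["f0", "verdict"] == "ns"
        assert raw.loc["f0", "verdict"] == "up"

    def test_overlay_feature_missing_from_table_is_ns(self):
        out = call_de("protein", _overlay([]), {"x"}, {"x"})
        assert out.loc["x", "verdict"] == "ns"

    def test_unknown_layer_rejected(self):
        with pytest.raises(ConfigError, match="unknown layer"):
            call_de("metabolite", None, set(), set())

    def test_threshold_validation(self):
        with pytest.raises(ConfigError):
            Thresholds(alpha=0.0)
        with pytest.raises(ConfigError):
            Thresholds(fc_cut=1.0)


class TestRnaDifferential:
    def test_pooled_counts_and_pseudocount_fc(self):
        # balancing gene keeps the two pooled libraries equal (300 reads each)
        df = pd.DataFrame({"WT_1": [10, 100, 40], "WT_2": [10, 100, 40],
                           "FAD_1": [40, 100, 10], "FAD_2": [40, 100, 10]},
                          index=["g_up", "g_flat", "g_bal"])
        m = OmicsMatrix(df, kind="count")
        out = rna_differential(m, ("WT", "FAD"))
        assert out.loc["g_up", "count_a"] == 20
        assert out.loc["g_up", "count_b"] == 80
        lib_a, lib_b = 300.0, 300.0
        expect_fc = ((80 + 0.5) / lib_b) / ((20 + 0.5) / lib_a)
        assert out.loc["g_up", "fc"] == pytest.approx(expect_fc, rel=1e-12)
        assert out.loc["g_up", "p"] == pytest.approx(
            exact_count_test(20, 80, lib_a, lib_b), rel=1e-12)
        assert out.loc["g_flat", "p"] == pytest.approx(1.0)
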