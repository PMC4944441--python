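"""Weighted independence-GEE: estimating equations, sandwich
covariance, Wald tests, the marker model suite and the genus screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dysbiome.containers import CohortMetadata, TaxonTable, ValidationError
from dysbiome.diversity import sample_metrics
from dysbiome.gee import (
    GEEModelSpec,
    bonferroni_threshold,
    fit_gee,
    genus_screen,
    model_suite,
    observation_weights,
    wald_test,
)
from dysbiome.synth import CohortSimConfig, simulate_cohort


def brute_force_gee(X, y, cl, w):
    """Independent oracle: per-cluster sandwich assembled with explicit
    matrix products."""
    clusters = np.unique(cl)
    p = X.shape[1]
    B = np.zeros((p, p))
    Xwy = np.zeros(p)
    for c in clusters:
        m = cl == c
        Xi, Wi, yi = X[m], np.diag(w[m]), y[m]
        B += Xi.T @ Wi @ Xi
        Xwy += Xi.T @ Wi @ yi
    beta = np.linalg.solve(B, Xwy)
    M = np.zeros((p, p))
    for c in clusters:
        m = cl == c
        Xi, Wi = X[m], np.diag(w[m])
        gi = Xi.T @ Wi @ (y[m] - Xi @ beta)
        M += np.outer(gi, gi)
    Binv = np.linalg.inv(B)
    return beta, Binv @ M @ Binv


class TestObservationWeights:
    def test_clusters_aab(self):
        np.testing.assert_allclose(
            observation_weights(np.array(["A", "A", "B"])), [0.5, 0.5, 1.0])

    def test_singletons_all_one(self):
        np.testing.assert_allclose(
            observation_weights(np.arange(7)), np.ones(7))

    def test_weights_sum_to_cluster_count(self):
        rng = np.random.default_rng(0)
        cl = rng.integers(0, 9, 40)
        assert observation_weights(cl).sum() == pytest.approx(
            np.unique(cl).size)


class TestFitGEE:
    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 50:
            n = int(rng.integers(6, 31))
            p = int(rng.integers(2, 5))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            y = rng.normal(size=n)
            cl = rng.integers(0, int(rng.integers(2, 11)), n)
            if np.unique(cl).size < 2:
                continue
            w = observation_weights(cl)
            fit = fit_gee(X, y, cl, w)
            beta0, cov0 = brute_force_gee(X, y, cl, w)
            np.testing.assert_allclose(fit.beta, beta0, rtol=1e-10)
            np.testing.assert_allclose(fit.robust_cov, cov0, rtol=1e-10,
                                       atol=1e-14)
            checked += 1

    def test_singleton_clusters_reduce_to_ols_hc0(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [1.0, 2.0, -1.0] + rng.normal(size=n)
        fit = fit_gee(X, y, np.arange(n), np.ones(n))
        ols = sm.OLS(y, X).fit(cov_type="HC0")
        np.testing.assert_allclose(fit.beta, ols.params, rtol=1e-10)
        np.testing.assert_allclose(fit.robust_cov, ols.cov_HC0, rtol=1e-10)

    def test_matches_statsmodels_cluster_gee(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = rng.normal(size=n)
        cl = rng.integers(0, 9, n)
        fit = fit_gee(X, y, cl, np.ones(n))
        ref = sm.GEE(y, X, groups=cl).fit()
        np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-8)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-8)

    def test_exact_linear_response(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(12), rng.normal(size=12)])
        beta_true = np.array([3.0, -2.0])
        y = X @ beta_true
        fit = fit_gee(X, y, np.repeat(np.arange(4), 3))
        np.testing.assert_allclose(fit.beta, beta_true, atol=1e-10)
        np.testing.assert_allclose(fit.se, 0.0, atol=1e-10)

    def test_weight_scaling_invariance(self):
        rng = np.random.default_rng(8)
        n = 24
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        cl = np.repeat(np.arange(6), 4)
        w = observation_weights(cl)
        a = fit_gee(X, y, cl, w)
        b = fit_gee(X, y, cl, w * 13.7)
        np.testing.assert_allclose(a.beta, b.beta, rtol=1e-10)
        np.testing.assert_allclose(a.robust_cov, b.robust_cov, rtol=1e-10)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(9)
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        cl = rng.integers(0, 6, n)
        perm = rng.permutation(n)
        a = fit_gee(X, y, cl)
        b = fit_gee(X[perm], y[perm], cl[perm])
        np.testing.assert_allclose(a.beta, b.beta, rtol=1e-10)
        np.testing.assert_allclose(a.robust_cov, b.robust_cov, rtol=1e-10)

    def test_rank_deficiency_names_columns(self):
        n = 12
        x = np.linspace(0, 1, n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValidationError, match="aliased"):
            fit_gee(X, np.ones(n), np.repeat([0, 1, 2], 4),
                    names=["intercept", "a", "b"])

    def test_single_cluster_rejected(self):
        X = np.ones((5, 1))
        with pytest.raises(ValidationError, match="single cluster"):
            fit_gee(X, np.ones(5), np.zeros(5))


class TestWald:
    def test_beta_two_se_one(self):
        from dysbiome.gee import GEEFit
        f = GEEFit(beta=np.array([2.0]), robust_cov=np.array([[1.0]]),
                   names=["x"], n_obs=4, n_clusters=2)
        chi2, p = wald_test(f, 0)
        assert chi2 == pytest.approx(4.0)
        assert p == pytest.approx(stats.chi2.sf(4.0, 1), abs=1e-12)
        assert p == pytest.approx(0.0455, abs=5e-4)

    def test_zero_beta(self):
        from dysbiome.gee import GEEFit
        f = GEEFit(beta=np.array([0.0]), robust_cov=np.array([[4.0]]),
                   names=["x"], n_obs=4, n_clusters=2)
        chi2, p = wald_test(f, 0)
        assert chi2 == 0.0 and p == 1.0

    def test_chi2_critical_value(self):
        from dysbiome.gee import GEEFit
        se = 1.0
        beta = np.sqrt(3.8415)
        f = GEEFit(beta=np.array([beta]), robust_cov=np.array([[se]]),
                   names=["x"], n_obs=4, n_clusters=2)
        _, p = wald_test(f, 0)
        assert p == pytest.approx(0.0500, abs=5e-4)


class TestModelSuite:
    def test_recovers_built_in_calprotectin_offset_313(self):
        # cohort built with a total CD-control baseline offset of 313:
        # direct extra offset + 260 * MD offset, no time decay
        truth = 313.0
        extra = truth - 260.0 * 0.86
        cover = 0
        for seed in range(100):
            # 3x cohort scale: enough clusters for near-nominal
            # sandwich CI coverage
            cfg = CohortSimConfig(seed=seed, cal_extra_cd=extra,
                                  decay_fraction=0.0,
                                  responder_effect_scale=0.0).scaled(3)
            table, meta, _, _ = simulate_cohort(cfg)
            metrics = sample_metrics(table)
            out = model_suite(metrics, meta, specs=(
                GEEModelSpec("cal_base", "calprotectin",
                             ("diagnosis", "time")),))
            row = out[out["term"] == "CD"].iloc[0]
            half = 1.959963984540054 * row["se"]
            cover += (row["beta"] - half) <= truth <= (row["beta"] + half)
        assert cover >= 90

    def test_empty_group_skipped_with_surviving_terms(self, small_cohort):
        table, meta, _, _ = small_cohort
        metrics = sample_metrics(table)
        keep = meta.data["group"] != "UC"
        sub = CohortMetadata(meta.data[keep].copy())
        msub = metrics[metrics["sample_id"].isin(sub.sample_ids)]
        out = model_suite(msub, sub, specs=(
            GEEModelSpec("md_avg", "md_index", ("diagnosis",)),))
        assert "UC" not in set(out["term"])
        assert "CD" in set(out["term"])

    def test_weighting_matters_with_unequal_clusters(self, small_cohort):
        table, meta, _, _ = small_cohort
        metrics = sample_metrics(table)
        weighted = model_suite(metrics, meta, specs=(
            GEEModelSpec("m", "md_index", ("diagnosis",)),))
        unweighted = model_suite(metrics, meta, specs=(
            GEEModelSpec("m", "md_index", ("diagnosis",),
                         weighting="unweighted"),))
        b1 = weighted[weighted["term"] == "CD"]["beta"].iloc[0]
        b2 = unweighted[unweighted["term"] == "CD"]["beta"].iloc[0]
        assert b1 != pytest.approx(b2, abs=1e-12)


def _screen_cohort(seed, n_subj=24, offset=0.0):
    """Tiny two-genus cohort for screen calibration: genus 0 null,
    genus 1 optionally shifted in cases."""
    rng = np.random.default_rng(seed)
    rows, meta = [], []
    for s in range(n_subj):
        group = "CD" if s < n_subj // 2 else "control_familial"
        responder = ("not_applicable" if group != "CD"
                     else ("responder" if s % 2 else "non_responder"))
        n_visits = int(rng.integers(1, 7))
        subj_re = rng.normal(0, 0.01, 2)
        for v in range(n_visits):
            base = np.array([0.05, 0.05]) + subj_re
            if group == "CD":
                base[1] += offset
            freq = np.clip(base + rng.normal(0, 0.01, 2), 1e-4, 1)
            rows.append(np.r_[freq, 1 - freq.sum()])
            meta.append({
                "sample_id": f"s{s}v{v}", "subject_id": f"p{s}",
                "group": group,
                "responder": responder,
                "time_days": float(v * 30),
                "calprotectin": np.nan, "activity_index": np.nan,
                "pretreatment_flag": bool(group == "CD" and v == 0),
            })
    lineages = ["k__B;p__P;c__C;o__O;f__F;g__A",
                "k__B;p__P;c__C;o__O;f__F;g__B",
                "k__B;p__P;c__C;o__O;f__F;g__C"]
    table = TaxonTable(
        pd.DataFrame(rows, index=[m["sample_id"] for m in meta],
                     columns=lineages), "frequencies")
    return table, CohortMetadata(pd.DataFrame(meta))


class TestGenusScreen:
    def test_bonferroni_threshold_for_134_genera(self):
        assert bonferroni_threshold(0.05, 134) == pytest.approx(
            3.731e-4, rel=1e-3)

    def test_screen_reports_thresholds_and_flags(self):
        table, meta = _screen_cohort(0, offset=0.08)
        out = genus_screen(table, meta, "case_vs_control")
        assert out.attrs["n_tested"] == 3
        assert out.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 3)
        hit = out[out["taxon"].str.endswith("g__B")].iloc[0]
        assert hit["bonferroni_significant"]
        assert hit["direction"] == "up"

    def test_null_genus_p_values_uniform(self):
        # null-calibration harness: nominal p of a no-effect genus is
        # uniform across 200 simulation replicates (KS at 0.01)
        pvals = []
        for seed in range(200):
            table, meta = _screen_cohort(seed, offset=0.0)
            out = genus_screen(table, meta, "case_vs_control")
            pvals.append(out["p"].iloc[0])
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_large_offset_power(self):
        # power harness: a strongly shifted genus reaches Bonferroni
        # significance in >= 95% of replicates
        hits = 0
        for seed in range(40):
            table, meta = _screen_cohort(seed, offset=0.08)
            out = genus_screen(table, meta, "case_vs_control")
            hits += bool(out[out["taxon"].str.endswith("g__B")]
                         ["bonferroni_significant"].iloc[0])
        assert hits >= 38

    def test_responder_contrast_uses_cases_only(self):
        table, meta = _screen_cohort(3)
        out = genus_screen(table, meta, "nonresponder_vs_responder")
        n_cases = int(meta.is_case().sum())
        assert len(out) == 3
        assert np.isfinite(out["p"]).all()
        # sanity: the contrast was fit on case samples only, so a
        # screen on the full table gives different betas
        other = genus_screen(table, meta, "case_vs_control")
        assert not np.allclose(out["beta"], other["beta"])
        assert n_cases < len(meta.data)
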