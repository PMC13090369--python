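"""Downstream inferential battery."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cascade_dpm import (ancova_group_effect, fit_marginal_swe, holm_adjust,
                         lme_time_by_stage, parallel_mediation,
                         semipartial_corr, slope_change_corr,
                         wild_bootstrap_fwe)


def brute_force_holm(p):
    """Step-down enumeration oracle for the Holm adjustment."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = (m - rank) * p[idx]
        running = max(running, val)
        adj[idx] = min(running, 1.0)
    return adj


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03])[0] == pytest.approx(0.03)

    def test_closed_form_m2(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_matches_brute_force_m5(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(0, 1, 5)
            np.testing.assert_allclose(holm_adjust(p), brute_force_holm(p),
                                       atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestSemipartial:
    def test_reduces_to_pearson_without_controls(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(100)
        b = 0.5 * a + rng.standard_normal(100)
        res = semipartial_corr(a, b)
        assert res.r == pytest.approx(stats.pearsonr(a, b).statistic,
                                      abs=1e-10)

    def test_orthogonal_construction_gives_zero(self):
        """Activity equal to a control variable is orthogonal to the
        control-residualized biomarker by OLS geometry."""
        rng = np.random.default_rng(2)
        ctrl = rng.standard_normal(120)
        b = 0.8 * ctrl + rng.standard_normal(120)
        a = ctrl  # lies in the span removed from the biomarker
        res = semipartial_corr(a, b, control_set=ctrl.reshape(-1, 1))
        assert abs(res.r) < 1e-8

    def test_matches_two_step_ols_oracle(self):
        rng = np.random.default_rng(5)
        n = 150
        demog = rng.standard_normal((n, 3))
        ctrl = rng.standard_normal((n, 2))
        b = ctrl @ [0.5, -0.3] + demog @ [0.2, 0.1, 0] \
            + rng.standard_normal(n)
        a = demog @ [0.3, 0, 0.2] + 0.4 * b + rng.standard_normal(n)
        res = semipartial_corr(a, b, ctrl, demog)
        # explicit two-step residualize-then-correlate oracle
        Xb = np.column_stack([np.ones(n), ctrl, demog])
        Xa = np.column_stack([np.ones(n), demog])
        rb = b - Xb @ np.linalg.lstsq(Xb, b, rcond=None)[0]
        ra = a - Xa @ np.linalg.lstsq(Xa, a, rcond=None)[0]
        assert res.r == pytest.approx(np.corrcoef(ra, rb)[0, 1], abs=1e-12)

    def test_invariant_to_affine_control_transform(self):
        rng = np.random.default_rng(6)
        n = 100
        ctrl = rng.standard_normal((n, 2))
        a = rng.standard_normal(n)
        b = ctrl[:, 0] + rng.standard_normal(n)
        r1 = semipartial_corr(a, b, ctrl)
        r2 = semipartial_corr(a, b, 3.0 * ctrl + 5.0)
        assert r1.r == pytest.approx(r2.r, abs=1e-10)


class TestAncova:
    def make_data(self, shift=0.0, n=60, seed=0):
        rng = np.random.default_rng(seed)
        g = np.repeat(["a", "b", "c"], n // 3)
        age = rng.normal(70, 5, n)
        y = 0.05 * age + rng.standard_normal(n)
        y[g == "c"] += shift
        return y, g, age.reshape(-1, 1)

    def test_null_rejection_near_alpha(self):
        rej = 0
        n_sim = 400
        for s in range(n_sim):
            y, g, cov = self.make_data(0.0, seed=s)
            rej += ancova_group_effect(y, g, cov).p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rej / n_sim - 0.05) < 3 * se

    def test_power_for_three_sd_shift(self):
        hits = 0
        for s in range(40):
            y, g, cov = self.make_data(3.0, seed=1000 + s)
            hits += ancova_group_effect(y, g, cov).p_value < 0.05
        assert hits / 40 > 0.95

    def test_reduces_to_anova_without_covariates(self):
        y, g, _ = self.make_data(1.0, seed=3)
        res = ancova_group_effect(y, g)
        f_ref, p_ref = stats.f_oneway(y[g == "a"], y[g == "b"], y[g == "c"])
        assert res.f_stat == pytest.approx(f_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_posthoc_holm_monotone(self):
        y, g, cov = self.make_data(2.0, seed=4)
        res = ancova_group_effect(y, g, cov)
        assert (res.posthoc["p_holm"] >= res.posthoc["p_raw"] - 1e-12).all()

    def test_small_group_rejected(self):
        y = np.arange(10.0)
        g = ["a"] * 8 + ["b"] * 2
        with pytest.raises(ValueError, match="< 3"):
            ancova_group_effect(y, g)


class TestMediation:
    def test_linear_identity(self):
        rng = np.random.default_rng(0)
        n = 150
        x = rng.standard_normal(n)
        m1 = 0.5 * x + rng.standard_normal(n)
        m2 = -0.3 * x + rng.standard_normal(n)
        y = 0.2 * x + 0.4 * m1 + 0.1 * m2 + rng.standard_normal(n)
        res = parallel_mediation(x, y, [m1, m2])
        assert res.total == pytest.approx(
            res.direct + res.indirect["ab"].sum(), abs=1e-10)

    def test_null_mediator_rejection_near_alpha(self):
        rej = 0
        n_sim = 400
        for s in range(n_sim):
            rng = np.random.default_rng(s)
            x = rng.standard_normal(200)
            m = rng.standard_normal(200)  # independent of x
            y = 0.3 * x + 1.0 * m + rng.standard_normal(200)
            res = parallel_mediation(x, y, [m])
            rej += res.indirect["p"].iloc[0] < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rej / n_sim - 0.05) < 3 * se

    def test_full_mediation_detected(self):
        detected = 0
        direct_small = 0
        for s in range(40):
            rng = np.random.default_rng(500 + s)
            n = 300
            x = rng.standard_normal(n)
            m = 0.6 * x + rng.standard_normal(n)
            y = 0.5 * m + rng.standard_normal(n)  # c' = 0, full mediation
            res = parallel_mediation(x, y, [m])
            detected += res.indirect["p"].iloc[0] < 0.05
            direct_small += res.direct_p > 0.05
        assert detected / 40 > 0.8
        assert direct_small / 40 > 0.8  # direct path ~ 0

    def test_demographic_preresidualization(self):
        rng = np.random.default_rng(7)
        n = 200
        age = rng.normal(70, 5, n)
        x = 0.1 * age + rng.standard_normal(n)
        m = 0.5 * x + rng.standard_normal(n)
        y = 0.3 * x + 0.4 * m + 0.05 * age + rng.standard_normal(n)
        res = parallel_mediation(x, y, [m], demographics=age.reshape(-1, 1))
        assert res.total == pytest.approx(
            res.direct + res.indirect["ab"].sum(), abs=1e-10)

    def test_collinear_mediators_warn(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(100)
        m1 = 0.5 * x + rng.standard_normal(100)
        m2 = m1 * (1 + 1e-12)
        res = parallel_mediation(x, rng.standard_normal(100), [m1, m2])
        assert res.warnings and "collinear" in res.warnings[0]


def make_long_data(seed, n_subj=60, n_visits=3, n_regions=2, beta_stage=0.0,
                   beta_inter=0.0, ri_sd=0.5, slope_sd=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        stage = rng.normal(0, 3)
        age = rng.normal(70, 5)
        sex = rng.integers(0, 2)
        edu = rng.normal(14, 3)
        u = rng.normal(0, ri_sd, n_regions)
        sl = rng.normal(0, slope_sd, n_regions)
        for v in range(n_visits):
            t = float(v)
            mu = beta_stage * stage + beta_inter * t * stage
            act = mu + u + sl * t + rng.normal(0, 1.0, n_regions)
            rows.append([f"s{s:03d}", t, stage, age, sex, edu, *act])
    cols = ["subject_id", "time_years_from_baseline", "stage_adjusted",
            "age_at_baseline", "sex", "education"] \
        + [f"r{k}" for k in range(n_regions)]
    return pd.DataFrame(rows, columns=cols)


class TestMarginalSwE:
    def test_time_centred_within_subject(self):
        df = make_long_data(0)
        m = fit_marginal_swe(df, ["r0", "r1"])
        tc = m.X[:, m.columns.index("time")]
        per_subject = pd.Series(tc).groupby(df["subject_id"].values).mean()
        np.testing.assert_allclose(per_subject, 0.0, atol=1e-12)

    def test_sandwich_matches_classical_under_iid_errors(self):
        """With independent homoskedastic errors (no subject effects) the
        cluster sandwich SEs agree with classical OLS SEs within 10%."""
        df = make_long_data(1, n_subj=500, n_visits=2, ri_sd=0.0)
        m = fit_marginal_swe(df, ["r0"])
        X, y = m.X, m.Y[:, 0]
        resid = y - X @ m.beta[:, 0]
        dof = len(y) - X.shape[1]
        classical = resid @ resid / dof * np.linalg.inv(X.T @ X)
        ratio = np.sqrt(np.diag(m.cov[0]) / np.diag(classical))
        assert np.all((ratio > 0.9) & (ratio < 1.1))

    def test_duplicating_cluster_rows_keeps_coefficients(self):
        df = make_long_data(2)
        dup = pd.concat([df, df], ignore_index=True)
        m1 = fit_marginal_swe(df, ["r0", "r1"])
        m2 = fit_marginal_swe(dup, ["r0", "r1"])
        np.testing.assert_allclose(m1.beta, m2.beta, atol=1e-10)

    def test_sandwich_psd(self):
        df = make_long_data(3)
        m = fit_marginal_swe(df, ["r0", "r1"])
        for V in m.cov:
            np.testing.assert_allclose(V, V.T, atol=1e-12)
            assert np.linalg.eigvalsh(V).min() > -1e-12

    def test_singular_design_lists_aliased_column(self):
        df = make_long_data(4)
        df["education"] = 14.0  # constant -> aliased with intercept
        with pytest.raises(ValueError, match="aliased"):
            fit_marginal_swe(df, ["r0"])


class TestWildBootstrap:
    def test_single_region_fwe_equals_own_p(self):
        df = make_long_data(5)
        m = fit_marginal_swe(df, ["r0"])
        res = wild_bootstrap_fwe(m, "stage", n_boot=199, seed=1)
        assert res["p_fwe"].iloc[0] == res["p_boot"].iloc[0]

    def test_fwe_adjusted_never_below_unadjusted(self):
        df = make_long_data(6, n_regions=2)
        m = fit_marginal_swe(df, ["r0", "r1"])
        res = wild_bootstrap_fwe(m, "stage", n_boot=199, seed=2)
        assert (res["p_fwe"] >= res["p_boot"] - 1e-12).all()

    def test_strong_effect_detected(self):
        hits = 0
        for s in range(20):
            df = make_long_data(100 + s, n_subj=200, beta_stage=0.35,
                                n_regions=2)
            m = fit_marginal_swe(df, ["r0", "r1"])
            res = wild_bootstrap_fwe(m, "stage", n_boot=199, seed=s)
            hits += (res["p_fwe"] < 0.05).iloc[0]
        assert hits / 20 > 0.9

    def test_seed_required_and_small_nboot_warns(self):
        df = make_long_data(7)
        m = fit_marginal_swe(df, ["r0"])
        with pytest.raises(ValueError, match="seed"):
            wild_bootstrap_fwe(m, "stage", n_boot=199)
        with pytest.warns(UserWarning, match="n_boot"):
            wild_bootstrap_fwe(m, "stage", n_boot=50, seed=3)

    def test_deterministic_given_seed(self):
        df = make_long_data(8)
        m = fit_marginal_swe(df, ["r0", "r1"])
        a = wild_bootstrap_fwe(m, "stage", n_boot=199, seed=9)
        b = wild_bootstrap_fwe(m, "stage", n_boot=199, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestLME:
    def test_zero_slope_variance_triggers_fallback(self):
        df = make_long_data(9, n_subj=80, n_visits=4, slope_sd=0.0)
        res = lme_time_by_stage(df, ["r0", "r1"])
        assert not res["used_random_slope"].any()
        assert res["fallback_logged"].all()

    def test_interaction_recovery(self):
        ests = []
        for s in range(25):
            df = make_long_data(200 + s, n_subj=160, n_visits=4,
                                beta_inter=0.05)
            res = lme_time_by_stage(df, ["r0"])
            ests.append(res["interaction_coef"].iloc[0])
        assert np.mean(ests) == pytest.approx(0.05, rel=0.15)

    def test_holm_applied_across_outcomes(self):
        df = make_long_data(10, n_subj=60, n_visits=3)
        res = lme_time_by_stage(df, ["r0", "r1"])
        assert (res["interaction_p_holm"]
                >= res["interaction_p"] - 1e-12).all()

    def test_too_few_longitudinal_subjects_rejected(self):
        df = make_long_data(11, n_subj=20)
        with pytest.raises(ValueError, match="30"):
            lme_time_by_stage(df, ["r0"])


class TestSlopeCorr:
    def test_proportional_slopes_r_one(self):
        s = pd.Series(np.arange(12.0), index=[f"s{i}" for i in range(12)])
        res = slope_change_corr(s, 2.0 * s)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_pearson(self):
        rng = np.random.default_rng(12)
        idx = [f"s{i}" for i in range(12)]
        a = pd.Series(rng.standard_normal(12), index=idx)
        b = pd.Series(rng.standard_normal(12), index=idx)
        res = slope_change_corr(a, b)
        am, bm = a - a.mean(), b - b.mean()
        r_hand = (am * bm).sum() / np.sqrt((am ** 2).sum() * (bm ** 2).sum())
        assert res.r == pytest.approx(r_hand, abs=1e-12)

    def test_null_rejection_near_alpha(self):
        rej = 0
        n_sim = 500
        for s in range(n_sim):
            rng = np.random.default_rng(s)
            idx = [f"s{i}" for i in range(30)]
            a = pd.Series(rng.standard_normal(30), index=idx)
            b = pd.Series(rng.standard_normal(30), index=idx)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rej += slope_change_corr(a, b).p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rej / n_sim - 0.05) < 3 * se

    def test_low_n_flagged(self):
        idx = [f"s{i}" for i in range(5)]
        a = pd.Series(np.arange(5.0), index=idx)
        with pytest.warns(UserWarning):
            res = slope_change_corr(a, a * 1.5 + 0.2)
        assert res.low_n_warning
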