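"""Disease progression model: orientation, fitting, prediction, sampling."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from cascade_dpm import (DiseaseProgressionModel, DPMFitConfig, DPMResults,
                         FitError, SchemaError, UnstageableError,
                         orient_biomarkers)
from .conftest import logistic

MONO_TOL = 1e-8


class TestOrientation:
    def test_pacc5_sign_flipped(self, default_config, small_cohort):
        cohort, _ = small_cohort
        oriented, record = orient_biomarkers(cohort, default_config.biomarkers)
        assert record.signs["pacc5"] == -1
        raw = cohort.observations.query("biomarker_name == 'pacc5'")["value"]
        z = oriented.observations.query("biomarker_name == 'pacc5'")["value"]
        # higher raw PACC5 (better cognition) -> lower oriented pathology
        assert np.corrcoef(raw, z)[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_round_trip_identity(self, default_config, small_cohort):
        cohort, _ = small_cohort
        oriented, record = orient_biomarkers(cohort, default_config.biomarkers)
        back = record.invert(oriented.observations)
        np.testing.assert_allclose(back["value"].to_numpy(),
                                   cohort.observations["value"].to_numpy(),
                                   atol=1e-10)

    def test_oriented_csf_markers_positively_correlated(self, default_config,
                                                        small_cohort):
        cohort, _ = small_cohort
        oriented, _ = orient_biomarkers(cohort, default_config.biomarkers)
        base = oriented.observations.query("visit_index == 0")
        wide = base.pivot(index="subject_id", columns="biomarker_name",
                          values="value")
        r = wide[["abeta42_40", "ptau181"]].corr().iloc[0, 1]
        assert r > 0.5

    def test_unknown_biomarker_raises_schema_error(self, default_config,
                                                   small_cohort):
        cohort, _ = small_cohort
        bad = cohort.observations.copy()
        bad.loc[bad.index[0], "biomarker_name"] = "mystery"
        from cascade_dpm import LongitudinalCohort
        bad_cohort = LongitudinalCohort(bad, cohort.covariates, cohort.labels)
        with pytest.raises(SchemaError, match="mystery"):
            orient_biomarkers(bad_cohort, default_config.biomarkers)


class TestFit:
    def test_time_shifts_recentred_to_zero(self, default_fit):
        assert default_fit.time_shifts.mean() == pytest.approx(0.0, abs=1e-9)

    def test_noise_sd_positive_everywhere(self, default_fit):
        assert (default_fit.noise_sd > 0).all()
        np.testing.assert_allclose(
            default_fit.total_sd ** 2,
            default_fit.noise_sd ** 2 + default_fit.random_intercept_sd ** 2,
            rtol=1e-10)

    def test_objective_nonincreasing(self, default_fit):
        diffs = np.diff(default_fit.convergence_log)
        assert (diffs <= 1e-6).all()

    def test_fitted_trajectories_monotone(self, default_fit):
        grid = default_fit.default_grid(step=0.05)
        for b, tr in default_fit.trajectories.items():
            assert np.diff(tr.predict(grid)).min() >= -MONO_TOL

    def test_shift_recovery_on_default_cohort(self, default_fit,
                                              small_cohort):
        """Spearman(true baseline stage, estimated shift) >= 0.8 (n=60)."""
        _, truth = small_cohort
        stages = truth.stage_series()
        shifts = default_fit.time_shifts.reindex(stages.index)
        assert spearmanr(stages, shifts).statistic >= 0.8

    def test_noiseless_shift_and_curve_recovery(self, noiseless_fit):
        """Noiseless logistic data: shifts and curves recovered exactly-ish."""
        fit, stages = noiseless_fit
        expected = stages - stages.mean()
        err = np.abs(fit.time_shifts.to_numpy() - expected)
        assert err.max() < fit.fit_config.shift_step  # within grid resolution
        lo, hi = fit.data_support
        g = np.linspace(lo, hi, 300)
        assert np.abs(fit.trajectories["m1"].predict(g)
                      - logistic(g)).max() < 0.05
        assert np.abs(fit.trajectories["m2"].predict(g)
                      - logistic(g, mid=3.0)).max() < 0.05

    def test_pairwise_shift_differences_match_stage_gaps(self, noiseless_fit):
        """Subjects generated 2 years apart end up ~2 latent years apart."""
        fit, stages = noiseless_fit
        d = fit.time_shifts.to_numpy()
        gaps = np.diff(stages)
        est_gaps = np.diff(d)
        np.testing.assert_allclose(est_gaps, gaps,
                                   atol=2 * fit.fit_config.shift_step)

    def test_degenerate_all_zero_shift_recovery(self):
        rows = []
        for i in range(12):
            for v in range(5):
                rows.append((f"s{i:02d}", float(v), "m1",
                             float(logistic(v, mid=2.0))))
        obs = pd.DataFrame(rows, columns=["subject_id",
                                          "time_years_from_baseline",
                                          "biomarker_name", "value"])
        fc = DPMFitConfig(basis_lo=-10, basis_hi=14, n_interior=10,
                          allow_single_biomarker=True)
        fit = DiseaseProgressionModel(obs, fit_config=fc).fit()
        assert np.abs(fit.time_shifts.to_numpy()).max() \
            < fc.shift_step

    def test_single_biomarker_rejected_by_default(self):
        rows = [(f"s{i}", 0.0, "m1", float(i)) for i in range(12)]
        obs = pd.DataFrame(rows, columns=["subject_id",
                                          "time_years_from_baseline",
                                          "biomarker_name", "value"])
        with pytest.raises(FitError, match="identifiab"):
            DiseaseProgressionModel(obs).fit()

    def test_translation_invariance_of_anchored_stages(self, default_config):
        """Shifting all observation times by +2 years leaves anchored
        downstream stages unchanged."""
        from cascade_dpm import (anchor_stages, generate_cohort, stage_cohort)
        cohort, _ = generate_cohort(default_config, 40, seed=11)
        shifted = cohort.observations.copy()
        shifted["time_years_from_baseline"] += 2.0
        from cascade_dpm import LongitudinalCohort
        cohort2 = LongitudinalCohort(shifted, cohort.covariates,
                                     cohort.labels)
        fits = []
        for c in (cohort, cohort2):
            m = DiseaseProgressionModel.from_cohort(
                c, default_config.biomarkers,
                biomarkers=default_config.dpm_biomarkers)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fits.append((c, m.fit(seed=0)))
        ref = cohort.labels["diagnostic_group"] == "CN"
        anchored = []
        for c, f in fits:
            st = stage_cohort(f, c)
            st = anchor_stages(st, ref.to_numpy())
            anchored.append(st.set_index("subject_id")["stage_anchored"])
        np.testing.assert_allclose(anchored[0], anchored[1],
                                   atol=3 * DPMFitConfig().shift_step)


class TestPredictAndSample:
    def test_flat_model_predicts_offset(self):
        from cascade_dpm import MonotoneBasis, TrajectoryModel
        basis = MonotoneBasis(-5, 5, n_interior=3)
        tr = TrajectoryModel("b", basis, offset=1.5,
                             theta=np.full(basis.n_basis, -40.0),
                             param_cov=np.zeros((basis.n_basis + 1,
                                                 basis.n_basis + 1)))
        np.testing.assert_allclose(tr.predict(np.linspace(-5, 5, 20)), 1.5,
                                   atol=1e-12)

    def test_mean_curve_matches_sampling_oracle(self, default_fit):
        """Quadrature posterior mean == mean of 10,000 posterior draws."""
        b = "hippocampal_volume"
        grid = np.linspace(-8, 8, 40)
        pred = default_fit.predict_trajectory(b, grid=grid)
        ss = default_fit.sample_trajectories(b, 10_000, seed=99, grid=grid)
        mc_mean = ss.samples.mean(axis=0)
        mc_err = ss.samples.std(axis=0) / np.sqrt(ss.samples.shape[0])
        assert np.all(np.abs(pred["mean"].to_numpy() - mc_mean)
                      < 5 * mc_err + 1e-6)

    def test_band_widens_away_from_data(self, default_fit):
        b = "pacc5"
        grid = default_fit.default_grid()
        pred = default_fit.predict_trajectory(b, grid=grid)
        width = pred["upper"] - pred["lower"]
        centre = np.argmin(np.abs(grid - np.median(
            default_fit.time_shifts.to_numpy())))
        assert width.iloc[-1] > width.iloc[centre]

    def test_sampled_curves_monotone_and_deterministic(self, default_fit):
        for b in default_fit.trajectories:
            s1 = default_fit.sample_trajectories(b, 50, seed=5)
            s2 = default_fit.sample_trajectories(b, 50, seed=5)
            np.testing.assert_array_equal(s1.samples, s2.samples)
            assert np.diff(s1.samples, axis=1).min() >= -MONO_TOL

    def test_sample_count_validated(self, default_fit):
        with pytest.raises(ValueError):
            default_fit.sample_trajectories("pacc5", 0, seed=1)

    def test_unknown_biomarker_key_error(self, default_fit):
        with pytest.raises(KeyError):
            default_fit.predict_trajectory("nope")


class TestSubjectNLL:
    def test_on_curve_nll_is_pure_normalization(self, default_fit):
        b = "ptau181"
        t = 3.0
        value = float(default_fit.trajectories[b].predict([t])[0])
        obs = pd.DataFrame({"biomarker_name": [b], "value": [value],
                            "time_years_from_baseline": [0.0]})
        s2 = float(default_fit.total_sd[b] ** 2)
        expected = 0.5 * np.log(2 * np.pi * s2)
        assert default_fit.subject_nll(obs, t) == pytest.approx(expected,
                                                                abs=1e-10)

    def test_likelihood_peaks_at_true_time(self, default_fit):
        t = 2.0
        obs = pd.DataFrame({
            "biomarker_name": list(default_fit.trajectories),
            "value": [float(default_fit.trajectories[b].predict([t])[0])
                      for b in default_fit.trajectories],
            "time_years_from_baseline": 0.0,
        })
        at_true = default_fit.subject_nll(obs, t)
        assert at_true < default_fit.subject_nll(obs, t - 5.0)
        assert at_true < default_fit.subject_nll(obs, t + 5.0)

    def test_matches_hand_coded_gaussian_oracle(self, default_fit):
        rows = [("ptau181", 0.4, 0.0), ("pacc5", -0.2, 1.0),
                ("hippocampal_volume", 1.1, 2.0)]
        obs = pd.DataFrame(rows, columns=["biomarker_name", "value",
                                          "time_years_from_baseline"])
        t = 1.5
        oracle = 0.0
        for b, y, dt in rows:
            s2 = float(default_fit.total_sd[b] ** 2)
            mu = float(default_fit.trajectories[b].predict([t + dt])[0])
            oracle += 0.5 * np.log(2 * np.pi * s2) + (y - mu) ** 2 / (2 * s2)
        assert default_fit.subject_nll(obs, t) == pytest.approx(oracle,
                                                                abs=1e-10)

    def test_unstageable_subject_raises(self, default_fit):
        obs = pd.DataFrame({"biomarker_name": ["fmri_activation"],
                            "value": [0.2],
                            "time_years_from_baseline": [0.0]})
        # fmri_activation is not a DPM biomarker in the default fit
        with pytest.raises(UnstageableError):
            default_fit.subject_nll(obs, 0.0)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, default_fit,
                                                   tmp_path):
        path = tmp_path / "fit.json"
        default_fit.save(path)
        back = DPMResults.load(path)
        grid = np.linspace(-10, 15, 60)
        for b in default_fit.trajectories:
            np.testing.assert_allclose(
                back.trajectories[b].predict(grid),
                default_fit.trajectories[b].predict(grid), atol=1e-12)
        pd.testing.assert_series_equal(back.time_shifts,
                                       default_fit.time_shifts)
        assert back.data_support == default_fit.data_support
        obs = pd.DataFrame({"biomarker_name": ["pacc5"], "value": [0.3],
                            "time_years_from_baseline": [0.0]})
        assert back.subject_nll(obs, 1.0) == pytest.approx(
            default_fit.subject_nll(obs, 1.0), abs=1e-12)
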