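"""Shared fixtures: default config, a small synthetic cohort and its DPM fit."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cascade_dpm import (DiseaseProgressionModel, DPMFitConfig,
                         generate_cohort, make_default_config)


@pytest.fixture(scope="session")
def default_config():
    return make_default_config()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """n=60 default cohort with ground truth (seed 1)."""
    return generate_cohort(default_config, 60, seed=1)


@pytest.fixture(scope="session")
def default_fit(default_config, small_cohort):
    """DPM fit of the n=60 seed-1 cohort (shared; treat as read-only)."""
    cohort, _ = small_cohort
    model = DiseaseProgressionModel.from_cohort(
        cohort, default_config.biomarkers,
        biomarkers=default_config.dpm_biomarkers)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return model.fit(seed=1)


def logistic(t, mid=0.0, slope=0.7, amp=2.5, base=-1.2):
    t = np.asarray(t, float)
    return base + amp / (1 + np.exp(-slope * (t - mid)))


@pytest.fixture(scope="session")
def noiseless_fit():
    """Two noiseless logistic biomarkers, 40 subjects, stages in [-8, 8]."""
    stages = np.linspace(-8, 8, 40)
    rows = []
    for i, s in enumerate(stages):
        for v in range(5):
            rows.append((f"s{i:02d}", float(v), "m1", float(logistic(s + v))))
            rows.append((f"s{i:02d}", float(v), "m2",
                         float(logistic(s + v, mid=3.0))))
    obs = pd.DataFrame(rows, columns=["subject_id",
                                      "time_years_from_baseline",
                                      "biomarker_name", "value"])
    fc = DPMFitConfig(basis_lo=-12, basis_hi=16, n_interior=12)
    fit = DiseaseProgressionModel(obs, fit_config=fc).fit()
    return fit, stages
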