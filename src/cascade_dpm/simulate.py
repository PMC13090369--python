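"""Synthetic longitudinal cohort generator with known ground truth.

Emulates the structure of a longitudinal memory-clinic cohort: staggered
annual follow-ups with modality-specific schedules and missingness,
sigmoidal biomarker abnormality trajectories on a ~20-year latent
disease-time axis, diagnostic groups with ordered latent-stage
distributions, subject random intercepts and observation noise, and an
age that increases with latent stage.  Everything downstream (model fit,
staging, cascade ordering, association statistics) is validated against the
returned :class:`GroundTruth`.

The baseline visit is always complete (cohort inclusion requires one full
measurement occasion); missingness applies to follow-up visits only and is
missing-completely-at-random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .task_metrics import classify_at

__all__ = [
    "LongitudinalCohort",
    "GroundTruth",
    "generate_cohort",
    "generate_recognition_trials",
]

OBS_COLUMNS = ["subject_id", "visit_index", "time_years_from_baseline",
               "biomarker_name", "value"]


@dataclass
class LongitudinalCohort:
    """Tidy longitudinal biomarker table plus covariates and labels.

    observations: (subject_id, visit_index, time_years_from_baseline,
    biomarker_name, value); covariates: (subject_id, age_at_baseline, sex,
    education, site); labels: (subject_id, diagnostic_group, at_group).
    """

    observations: pd.DataFrame
    covariates: pd.DataFrame
    labels: pd.DataFrame

    def validate(self) -> None:
        obs = self.observations
        if obs.duplicated(["subject_id", "visit_index", "biomarker_name"]).any():
            raise ValueError("duplicate (subject, visit, biomarker) rows")
        if (obs["time_years_from_baseline"] < 0).any():
            raise ValueError("negative observation times")
        missing = set(obs["subject_id"]) - set(self.covariates["subject_id"])
        if missing:
            raise ValueError(f"subjects without covariates: {sorted(missing)[:5]}")

    @property
    def biomarkers(self) -> list[str]:
        return sorted(self.observations["biomarker_name"].unique())

    def subject_ids(self) -> list:
        return sorted(self.covariates["subject_id"].unique())

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.observations.to_csv(out / "observations.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        self.labels.to_csv(out / "labels.csv", index=False)

    @classmethod
    def load(cls, in_dir: str | Path) -> "LongitudinalCohort":
        p = Path(in_dir)
        cohort = cls(
            observations=pd.read_csv(p / "observations.csv"),
            covariates=pd.read_csv(p / "covariates.csv"),
            labels=pd.read_csv(p / "labels.csv"),
        )
        cohort.validate()
        return cohort


@dataclass
class GroundTruth:
    """Generating quantities kept aside as a test oracle."""

    true_stage_baseline: dict  # subject_id -> years on the latent axis
    true_trajectory: dict  # biomarker -> BiomarkerSpec (curves callable)
    true_random_intercepts: dict  # (subject_id, biomarker) -> native units
    seed: int

    def stage_series(self) -> pd.Series:
        return pd.Series(self.true_stage_baseline).sort_index()

    def save(self, path: str | Path) -> None:
        payload = {
            "true_stage_baseline": {str(k): v for k, v in
                                    self.true_stage_baseline.items()},
            "true_random_intercepts": {f"{k[0]}|{k[1]}": v for k, v in
                                       self.true_random_intercepts.items()},
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def generate_cohort(
    config: SimulationConfig, n_subjects: int, seed: int
) -> tuple[LongitudinalCohort, GroundTruth]:
    """Draw a synthetic cohort from the generating model.

    Per subject: a diagnostic group (configured proportions), a baseline
    latent stage from that group's Gaussian, an age correlated with stage,
    then for every biomarker and scheduled visit the native-scale value
    ``spec.native_curve(stage + visit_years) + random intercept + noise``.
    Follow-up visits are dropped independently with the biomarker's
    ``missing_rate``; the baseline occasion is always complete, and the AT
    label stored in the cohort is derived from the observed baseline CSF
    values via :func:`cascade_dpm.task_metrics.classify_at`.

    Deterministic given ``seed``.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    try:
        config.validate()
    except ConfigError:
        raise
    rng = np.random.default_rng(seed)

    group_names = list(config.groups)
    props = np.array([config.groups[g].proportion for g in group_names])
    subj_ids = [f"S{i:04d}" for i in range(n_subjects)]
    groups = rng.choice(group_names, size=n_subjects, p=props / props.sum())
    stages = np.array([
        rng.normal(config.groups[g].stage_mean, config.groups[g].stage_sd)
        for g in groups
    ])
    ages = (config.age_intercept + config.age_stage_coef * stages
            + rng.normal(0.0, config.age_noise_sd, n_subjects))
    sexes = rng.integers(0, 2, n_subjects)
    education = np.clip(
        rng.normal(config.education_mean, config.education_sd, n_subjects), 8, 20
    ).round(1)
    sites = rng.integers(0, config.n_sites, n_subjects)

    rows: list[tuple] = []
    intercepts: dict = {}
    baseline_values: dict = {}
    for b in config.biomarkers:
        visits = config.schedules[b.family]
        b_int = rng.normal(0.0, b.random_intercept_sd, n_subjects)
        noise = rng.normal(0.0, b.noise_sd, (n_subjects, len(visits)))
        miss = rng.random((n_subjects, len(visits))) < b.missing_rate
        for i, sid in enumerate(subj_ids):
            intercepts[(sid, b.name)] = float(b_int[i])
            for k, v in enumerate(visits):
                value = float(b.native_curve(stages[i] + v) + b_int[i]
                              + noise[i, k])
                if v == 0:
                    baseline_values[(sid, b.name)] = value
                elif miss[i, k]:
                    continue
                rows.append((sid, v, float(v), b.name, value))

    observations = pd.DataFrame(rows, columns=OBS_COLUMNS)
    observations = observations.sort_values(
        ["subject_id", "visit_index", "biomarker_name"]
    ).reset_index(drop=True)
    covariates = pd.DataFrame({
        "subject_id": subj_ids,
        "age_at_baseline": np.round(ages, 2),
        "sex": sexes,
        "education": education,
        "site": [f"site{s}" for s in sites],
    })
    at = [
        classify_at(baseline_values.get((sid, "abeta42_40"), np.nan),
                    baseline_values.get((sid, "ptau181"), np.nan)).label
        for sid in subj_ids
    ]
    at = [lbl if lbl in {"A-T-", "A+T-", "A+T+"} else
          ("other" if lbl != "indeterminate" else "other") for lbl in at]
    labels = pd.DataFrame({
        "subject_id": subj_ids,
        "diagnostic_group": groups,
        "at_group": at,
    })
    cohort = LongitudinalCohort(observations, covariates, labels)
    cohort.validate()
    truth = GroundTruth(
        true_stage_baseline=dict(zip(subj_ids, stages.astype(float))),
        true_trajectory={b.name: b for b in config.biomarkers},
        true_random_intercepts=intercepts,
        seed=seed,
    )
    return cohort, truth


def generate_recognition_trials(
    n_novel: int, n_familiar: int, discriminability: float, seed: int
) -> pd.DataFrame:
    """Simulate old/new recognition confidence ratings.

    Latent memory strengths are Gaussian with unit SD; novel items are
    shifted by ``discriminability`` (a standardized effect).  Ratings 1..5
    (5 = sure novel) come from fixed equal-width cut-points centred between
    the two class means, so ``discriminability = 0`` yields identical rating
    distributions in expectation and very large values drive all novel
    trials to 5 and all familiar trials to 1.
    """
    if n_novel < 1 or n_familiar < 1:
        raise ValueError("trial counts must be >= 1")
    if discriminability < 0:
        raise ValueError("discriminability must be >= 0")
    rng = np.random.default_rng(seed)
    latent = np.concatenate([
        rng.normal(discriminability, 1.0, n_novel),
        rng.normal(0.0, 1.0, n_familiar),
    ])
    cuts = discriminability / 2.0 + np.array([-1.5, -0.5, 0.5, 1.5])
    ratings = 1 + (latent[:, None] > cuts[None, :]).sum(axis=1)
    return pd.DataFrame({
        "trial_id": np.arange(n_novel + n_familiar),
        "is_novel": np.r_[np.ones(n_novel, bool), np.zeros(n_familiar, bool)],
        "confidence_rating": ratings.astype(int),
    })
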