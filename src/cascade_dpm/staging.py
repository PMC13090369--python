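"""Probabilistic disease staging from a fitted progression model.

A subject's continuous disease stage is the minimizer of their Gaussian
negative log-likelihood profile over candidate latent times, given any subset
of their (oriented) longitudinal observations.  The arbitrary latent axis is
then anchored to a clinically meaningful zero — the median stage of a
reference subgroup (amyloid-positive, tau-negative cognitively normal
participants by convention) — and finally residualized for age, sex and
education, since demographics explain a sizeable share of stage variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dpm import DPMResults, UnstageableError

__all__ = [
    "StageEstimate",
    "estimate_stage",
    "stage_cohort",
    "anchor_stages",
    "residualize_stages",
    "stage_slopes",
]

logger = logging.getLogger(__name__)


@dataclass
class StageEstimate:
    """A subject's latent disease-stage estimate with its likelihood profile."""

    subject_id: object
    stage_raw: float  # argmin of the NLL profile (years, model axis)
    grid: np.ndarray
    nll_profile: np.ndarray
    n_observations_used: int
    stage_anchored: float | None = None
    stage_adjusted: float | None = None


def staging_grid(results: DPMResults, step: float = 0.05) -> np.ndarray:
    """Default staging grid: the shift-search range extended by 5 years."""
    lo = results.fit_config.shift_lo - 5.0
    hi = results.fit_config.shift_hi + 5.0
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def estimate_stage(results: DPMResults, subject_obs: pd.DataFrame,
                   grid=None, subject_id=None) -> StageEstimate:
    """Stage one subject by exhaustive NLL minimization on a grid.

    ``subject_obs`` carries the subject's oriented observations with their
    within-subject time offsets; multi-visit subjects contribute all visits.
    Ties are broken towards the smallest stage.  A subject without a usable
    observation raises :class:`UnstageableError` — there is no silent
    default stage.
    """
    grid = staging_grid(results) if grid is None else np.asarray(grid, float)
    profile = results.nll_profile(subject_obs, grid)
    k = int(np.argmin(profile))  # argmin returns the first (smallest) minimum
    n_used = int(subject_obs["biomarker_name"]
                 .isin(results.trajectories).sum())
    return StageEstimate(subject_id, float(grid[k]), grid, profile, n_used)


def stage_cohort(results: DPMResults, cohort, oriented: bool = False,
                 grid=None) -> pd.DataFrame:
    """Stage every subject of a cohort; returns a tidy stage table.

    ``cohort`` is a :class:`~cascade_dpm.simulate.LongitudinalCohort`; raw
    values are oriented through the fit's orientation record unless
    ``oriented=True``.  Unstageable subjects are skipped with a log notice.
    """
    obs = cohort.observations
    if not oriented:
        if results.orientation is None:
            raise ValueError("fit carries no orientation record; "
                             "pass oriented data")
        obs = results.orientation.apply(obs)
    rows = []
    for sid, sub in obs.groupby("subject_id"):
        try:
            est = estimate_stage(results, sub.reset_index(drop=True),
                                 grid=grid, subject_id=sid)
        except UnstageableError:
            logger.info("subject %s unstageable; skipped", sid)
            continue
        rows.append((sid, est.stage_raw, est.n_observations_used))
    return pd.DataFrame(rows, columns=["subject_id", "stage_raw",
                                       "n_observations_used"])


def anchor_stages(stages: pd.DataFrame, reference_mask) -> pd.DataFrame:
    """Translate stages so the reference subgroup's median raw stage is 0.

    Anchoring always rederives from ``stage_raw``, so it is idempotent and an
    order-preserving translation of the whole sample.
    """
    mask = np.asarray(reference_mask, bool)
    if mask.shape[0] != len(stages):
        raise ValueError("reference mask length does not match stage table")
    if not mask.any():
        raise ValueError(
            "reference subgroup is empty; choose a fallback reference group "
            "(e.g. all amyloid-positive controls, or the whole sample)"
        )
    out = stages.copy()
    out["stage_anchored"] = out["stage_raw"] - \
        float(out.loc[mask, "stage_raw"].median())
    return out


def residualize_stages(stages: pd.DataFrame, covariates: pd.DataFrame,
                       columns=("age_at_baseline", "sex", "education")
                       ) -> pd.DataFrame:
    """OLS-residualize anchored stages for demographics.

    Regresses ``stage_anchored`` on the requested covariate columns (with
    intercept) and stores the residual as ``stage_adjusted``; the fitted
    coefficients are attached as ``DataFrame.attrs['residualization']``.
    Constant or collinear covariates raise.
    """
    if "stage_anchored" not in stages:
        raise ValueError("anchor stages before residualizing")
    cov = covariates.set_index("subject_id").loc[stages["subject_id"]]
    X = np.column_stack([np.ones(len(stages))]
                        + [cov[c].to_numpy(float) for c in columns])
    for j, c in enumerate(columns, start=1):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {c!r} is constant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    y = stages["stage_anchored"].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    out = stages.copy()
    out["stage_adjusted"] = y - X @ beta
    out.attrs["residualization"] = dict(zip(("intercept",) + tuple(columns),
                                            beta.tolist()))
    return out


def stage_slopes(results: DPMResults, cohort, oriented: bool = False
                 ) -> pd.Series:
    """Per-subject rate of change of the disease stage (years per year).

    Each measurement occasion (distinct within-subject time) is staged
    independently using only that occasion's data, and an OLS line of stage
    on intra-individual time gives the subject's slope.  Subjects with fewer
    than two stageable occasions are skipped with a log notice.
    """
    obs = cohort.observations
    if not oriented:
        if results.orientation is None:
            raise ValueError("fit carries no orientation record; "
                             "pass oriented data")
        obs = results.orientation.apply(obs)
    slopes = {}
    for sid, sub in obs.groupby("subject_id"):
        occ_t, occ_s = [], []
        for t, occ in sub.groupby("time_years_from_baseline"):
            occ = occ.copy()
            occ["time_years_from_baseline"] = 0.0  # stage this occasion alone
            try:
                est = estimate_stage(results, occ.reset_index(drop=True),
                                     subject_id=sid)
            except UnstageableError:
                continue
            occ_t.append(float(t))
            occ_s.append(est.stage_raw)
        if len(occ_t) < 2:
            logger.info("subject %s has < 2 stageable occasions; skipped", sid)
            continue
        t = np.asarray(occ_t)
        s = np.asarray(occ_s)
        slopes[sid] = float(np.polyfit(t, s, 1)[0])
    return pd.Series(slopes, name="stage_slope")
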