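"""Multivariate monotone disease progression model (DPM).

Longitudinal biomarkers y_b of subject j observed at within-subject time tau
are modelled on a common latent disease-time axis through a per-subject
time-shift d_j:

    y_b(tau) = f_b(tau + d_j) + nu_jb + eps,   eps ~ N(0, sigma_b^2),

where every f_b is a smooth *monotonically increasing* trajectory from normal
to abnormal oriented biomarker levels, nu_jb is a subject random intercept,
and d_j places the subject on the latent axis.  Trajectories are represented
with a finite monotone basis — integrated B-splines with softplus-positive
weights and a Gaussian prior on the unconstrained weights — a finite-rank
surrogate for a monotone Gaussian process.  Inference is MAP with a Laplace
approximation for posterior trajectory sampling; time-shifts are updated by
exhaustive 1-D grid search on the subject negative log-likelihood, and the
two steps alternate until the shifts stop moving.

Identifiability: the latent axis origin is arbitrary, so internally the model
optimizes unconstrained shifts and reports them recentred to mean zero; the
recentring is a pure relabelling of the axis and leaves the penalized
objective untouched, which keeps the convergence log monotone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.special import expit, roots_hermite

from .config import BiomarkerSpec
from .simulate import LongitudinalCohort

__all__ = [
    "FitError",
    "SchemaError",
    "UnstageableError",
    "OrientationRecord",
    "orient_biomarkers",
    "MonotoneBasis",
    "TrajectoryModel",
    "TrajectorySampleSet",
    "DPMFitConfig",
    "DiseaseProgressionModel",
    "DPMResults",
    "fit_dpm",
]


class FitError(RuntimeError):
    """Model fitting failed (e.g. unidentifiable shift configuration)."""


class SchemaError(KeyError):
    """Input table does not match the expected biomarker schema."""


class UnstageableError(ValueError):
    """A subject has no usable observation on any fitted biomarker."""


def softplus(x):
    return np.logaddexp(0.0, x)


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

@dataclass
class OrientationRecord:
    """Invertible per-biomarker orientation transform.

    ``oriented = (raw_direction * value - center) / scale`` so that higher
    oriented values always mean more pathology (volumes, PACC5, Abeta42/40
    and fMRI activation are multiplied by -1) and each biomarker is z-scored
    against the reference rows used at construction.
    """

    signs: dict[str, int]
    centers: dict[str, float]
    scales: dict[str, float]

    def transform_values(self, biomarker: str, values):
        if biomarker not in self.signs:
            raise SchemaError(f"no orientation for biomarker {biomarker!r}")
        s = self.signs[biomarker]
        return (s * np.asarray(values, float) - self.centers[biomarker]) \
            / self.scales[biomarker]

    def inverse_values(self, biomarker: str, values):
        if biomarker not in self.signs:
            raise SchemaError(f"no orientation for biomarker {biomarker!r}")
        s = self.signs[biomarker]
        return s * (np.asarray(values, float) * self.scales[biomarker]
                    + self.centers[biomarker])

    def apply(self, observations: pd.DataFrame) -> pd.DataFrame:
        out = observations.copy()
        for b, sub in observations.groupby("biomarker_name"):
            out.loc[sub.index, "value"] = self.transform_values(b, sub["value"])
        return out

    def invert(self, observations: pd.DataFrame) -> pd.DataFrame:
        out = observations.copy()
        for b, sub in observations.groupby("biomarker_name"):
            out.loc[sub.index, "value"] = self.inverse_values(b, sub["value"])
        return out


def orient_biomarkers(
    cohort: LongitudinalCohort,
    specs: list[BiomarkerSpec],
    reference_subjects=None,
) -> tuple[LongitudinalCohort, OrientationRecord]:
    """Sign-flip and z-score every biomarker so higher = more pathology.

    ``reference_subjects`` optionally restricts the standardization rows to a
    subgroup (default: the whole sample).  The transform is recorded per
    biomarker and is exactly invertible.
    """
    spec_map = {s.name: s for s in specs}
    obs = cohort.observations
    unknown = set(obs["biomarker_name"]) - set(spec_map)
    if unknown:
        raise SchemaError(f"biomarkers without a spec: {sorted(unknown)}")
    ref = obs
    if reference_subjects is not None:
        ref = obs[obs["subject_id"].isin(set(reference_subjects))]
        if ref.empty:
            raise ValueError("reference subgroup has no observations")
    signs, centers, scales = {}, {}, {}
    for b, sub in ref.groupby("biomarker_name"):
        sign = 1 if spec_map[b].raw_direction > 0 else -1
        flipped = sign * sub["value"].to_numpy(float)
        signs[b] = sign
        centers[b] = float(flipped.mean())
        sd = float(flipped.std(ddof=1))
        scales[b] = sd if sd > 0 else 1.0
    record = OrientationRecord(signs, centers, scales)
    oriented = LongitudinalCohort(
        record.apply(obs), cohort.covariates.copy(), cohort.labels.copy()
    )
    return oriented, record


# ---------------------------------------------------------------------------
# Monotone basis
# ---------------------------------------------------------------------------

class MonotoneBasis:
    """Integrated B-spline basis on [lo, hi].

    Basis functions are antiderivatives of nonnegative B-splines, normalized
    to reach 1 at ``hi``; each is nondecreasing from 0, so any nonnegative
    combination plus an offset is a nondecreasing curve.  Evaluation outside
    [lo, hi] clamps to the boundary value (flat, hence still monotone).
    """

    def __init__(self, lo: float, hi: float, n_interior: int = 6,
                 degree: int = 2):
        self.lo, self.hi = float(lo), float(hi)
        self.n_interior = int(n_interior)
        self.degree = int(degree)
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        self.knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
        self.n_basis = len(self.knots) - degree - 1
        self._anti = []
        for k in range(self.n_basis):
            c = np.zeros(self.n_basis)
            c[k] = 1.0
            self._anti.append(BSpline(self.knots, c, degree).antiderivative())
        self._norms = np.array([float(a(self.hi) - a(self.lo))
                                for a in self._anti])

    def design(self, t) -> np.ndarray:
        """N x n_basis matrix of normalized integrated basis values."""
        tc = np.clip(np.asarray(t, float), self.lo, self.hi)
        cols = [(a(tc) - a(self.lo)) / n for a, n in zip(self._anti, self._norms)]
        return np.column_stack(cols)

    def to_dict(self) -> dict:
        return {"lo": self.lo, "hi": self.hi, "n_interior": self.n_interior,
                "degree": self.degree}


# ---------------------------------------------------------------------------
# Trajectory model
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryModel:
    """MAP posterior of one biomarker's monotone trajectory.

    Parameters are ``[offset, theta_1..theta_K]`` with curve
    ``f(t) = offset + sum_k softplus(theta_k) I_k(t + origin)`` where I_k is
    the integrated basis and ``origin`` maps the reported (recentred) axis to
    the internal fitting axis.  ``param_cov`` is the Laplace (Gauss-Newton)
    posterior covariance of the parameters at the MAP.
    """

    biomarker: str
    basis: MonotoneBasis
    offset: float
    theta: np.ndarray
    param_cov: np.ndarray
    origin: float = 0.0

    @property
    def coef_mean(self) -> np.ndarray:
        """Nonnegative basis weights at the MAP."""
        return softplus(self.theta)

    def predict(self, t) -> np.ndarray:
        D = self.basis.design(np.asarray(t, float) + self.origin)
        return self.offset + D @ self.coef_mean

    def _param_chol(self) -> np.ndarray:
        cov = self.param_cov + 1e-12 * np.eye(len(self.param_cov))
        return np.linalg.cholesky(cov)

    def sample_params(self, n: int, rng: np.random.Generator) -> np.ndarray:
        mean = np.r_[self.offset, self.theta]
        z = rng.standard_normal((n, len(mean)))
        return mean + z @ self._param_chol().T

    def curves_from_params(self, params: np.ndarray, t) -> np.ndarray:
        D = self.basis.design(np.asarray(t, float) + self.origin)
        return params[:, :1] + softplus(params[:, 1:]) @ D.T

    def posterior_mean_curve(self, t, n_quad: int = 61) -> np.ndarray:
        """Pointwise posterior-mean curve via Gauss-Hermite quadrature.

        The curve is linear in softplus(theta_k), whose posterior marginals
        under the Laplace approximation are Gaussian, so the pointwise mean
        needs only 1-D expectations E[softplus(theta_k)] — computed here to
        quadrature precision rather than by Monte Carlo.
        """
        nodes, wts = roots_hermite(n_quad)
        sd = np.sqrt(np.clip(np.diag(self.param_cov)[1:], 0, None))
        th = self.theta[:, None] + np.sqrt(2.0) * sd[:, None] * nodes[None, :]
        e_w = softplus(th) @ wts / np.sqrt(np.pi)
        D = self.basis.design(np.asarray(t, float) + self.origin)
        return self.offset + D @ e_w


@dataclass
class TrajectorySampleSet:
    """Posterior trajectory draws for one biomarker on a grid."""

    biomarker: str
    grid: np.ndarray
    samples: np.ndarray  # (n_samples, len(grid)); every row nondecreasing
    seed: int


# ---------------------------------------------------------------------------
# Fit configuration
# ---------------------------------------------------------------------------

@dataclass
class DPMFitConfig:
    """Tunable settings of the alternating MAP fit (units: years)."""

    basis_lo: float = -18.0
    basis_hi: float = 24.0
    n_interior: int = 6
    degree: int = 2
    shift_lo: float = -15.0
    shift_hi: float = 15.0
    shift_step: float = 0.05
    max_iter: int = 300
    shift_tol: float = 0.01
    theta_prior_sd: float = 3.0
    offset_prior_sd: float = 10.0
    init_spread_sd: float = 5.0
    allow_single_biomarker: bool = False

    def shift_grid(self) -> np.ndarray:
        n = int(round((self.shift_hi - self.shift_lo) / self.shift_step))
        return self.shift_lo + self.shift_step * np.arange(n + 1)


# ---------------------------------------------------------------------------
# Likelihood helpers (shared with staging)
# ---------------------------------------------------------------------------

def _nll_profiles(
    curve_lookup: dict[str, tuple[np.ndarray, np.ndarray]],
    variances: dict[str, float],
    obs: pd.DataFrame,
    subj_index: np.ndarray,
    n_subjects: int,
    grid: np.ndarray,
) -> np.ndarray:
    """Per-subject Gaussian NLL evaluated on a grid of candidate stages.

    ``curve_lookup[b] = (tgrid, values)`` is a dense tabulation of the fitted
    curve; observation i of subject j and biomarker b contributes
    ``0.5*log(2*pi*s_b^2) + (y_i - f_b(time_i + t))^2 / (2 s_b^2)`` at each
    candidate stage t.  Returns an (n_subjects, len(grid)) matrix.
    """
    out = np.zeros((n_subjects, len(grid)))
    for b, sub in obs.groupby("biomarker_name"):
        if b not in curve_lookup:
            continue
        tg, fv = curve_lookup[b]
        s2 = variances[b]
        times = sub["time_years_from_baseline"].to_numpy(float)
        y = sub["value"].to_numpy(float)
        pos = times[:, None] + grid[None, :]
        pred = np.interp(pos.ravel(), tg, fv).reshape(pos.shape)
        contrib = 0.5 * np.log(2 * np.pi * s2) \
            + (y[:, None] - pred) ** 2 / (2.0 * s2)
        np.add.at(out, subj_index[sub.index.to_numpy()], contrib)
    return out


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class DiseaseProgressionModel:
    """Monotone multivariate disease progression model.

    Built from an *oriented* long-format observation table (see
    :func:`orient_biomarkers`); ``fit`` runs the alternating MAP estimation
    and returns a :class:`DPMResults`.
    """

    def __init__(self, observations: pd.DataFrame,
                 orientation: OrientationRecord | None = None,
                 fit_config: DPMFitConfig | None = None):
        required = {"subject_id", "time_years_from_baseline",
                    "biomarker_name", "value"}
        missing = required - set(observations.columns)
        if missing:
            raise SchemaError(f"observations missing columns {sorted(missing)}")
        obs = observations.dropna(subset=["value"]).reset_index(drop=True)
        self.observations = obs
        self.orientation = orientation
        self.config = fit_config or DPMFitConfig()
        self.biomarkers = sorted(obs["biomarker_name"].unique())
        self.subjects = np.array(sorted(obs["subject_id"].unique()))
        self._subj_pos = {s: i for i, s in enumerate(self.subjects)}

    @classmethod
    def from_cohort(cls, cohort: LongitudinalCohort,
                    specs: list[BiomarkerSpec],
                    biomarkers: list[str] | None = None,
                    fit_config: DPMFitConfig | None = None,
                    reference_subjects=None) -> "DiseaseProgressionModel":
        """Orient a raw cohort and restrict to the modelling biomarkers."""
        oriented, record = orient_biomarkers(cohort, specs, reference_subjects)
        obs = oriented.observations
        if biomarkers is not None:
            obs = obs[obs["biomarker_name"].isin(set(biomarkers))]
        return cls(obs.reset_index(drop=True), orientation=record,
                   fit_config=fit_config)

    # -- pieces of the alternating algorithm --------------------------------

    def _basis(self) -> MonotoneBasis:
        c = self.config
        return MonotoneBasis(c.basis_lo, c.basis_hi, c.n_interior, c.degree)

    def _init_shifts(self) -> np.ndarray:
        """Severity-proxy initialization: per-subject mean oriented z.

        The mean oriented z-score across all of a subject's observations is a
        crude monotone function of disease stage; mapping it linearly to a
        spread of ``init_spread_sd`` years seeds the alternating optimization
        far from the all-zero degenerate point.
        """
        mz = self.observations.groupby("subject_id")["value"].mean()
        mz = mz.reindex(self.subjects).to_numpy(float)
        # subtracting the mean observation time makes the whole fit
        # equivariant under a constant shift of all observation times
        t_mean = float(self.observations["time_years_from_baseline"].mean())
        sd = mz.std()
        if sd <= 0:
            return np.zeros(len(mz)) - t_mean
        return (mz - mz.mean()) / sd * self.config.init_spread_sd - t_mean

    def _fit_curve(self, basis, t, y, s2, x0):
        c = self.config
        D = basis.design(t)
        pen0 = 1.0 / c.offset_prior_sd ** 2
        pen = 1.0 / c.theta_prior_sd ** 2

        def objective(p):
            beta0, th = p[0], p[1:]
            w = softplus(th)
            r = y - beta0 - D @ w
            obj = r @ r / (2 * s2) + pen0 * beta0 ** 2 / 2 + pen * th @ th / 2
            g = np.empty_like(p)
            g[0] = -r.sum() / s2 + pen0 * beta0
            g[1:] = -(D.T @ r) * expit(th) / s2 + pen * th
            return obj, g

        res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 200})
        # keep whichever of warm start / optimizer output is better, so the
        # outer objective can never increase at this step
        if objective(x0)[0] < objective(res.x)[0]:
            return np.asarray(x0, float)
        return res.x

    def _laplace_cov(self, basis, t, params, s2):
        c = self.config
        D = basis.design(t)
        J = np.column_stack([np.ones(len(t)), D * expit(params[1:])[None, :]])
        prior = np.r_[1.0 / c.offset_prior_sd ** 2,
                      np.full(basis.n_basis, 1.0 / c.theta_prior_sd ** 2)]
        H = J.T @ J / s2 + np.diag(prior)
        return np.linalg.inv(H)

    def _curve_lookup(self, basis, params):
        tg = np.arange(self.config.basis_lo, self.config.basis_hi + 1e-9, 0.05)
        lookup = {}
        for b, p in params.items():
            D = basis.design(tg)
            lookup[b] = (tg, p[0] + D @ softplus(p[1:]))
        return lookup

    def _update_shifts(self, lookup, variances, subj_index):
        """Exhaustive grid-search update of every subject's time-shift.

        The +/-15 year search window is centred on the mean observation
        time, which keeps the whole fit equivariant under a constant shift
        of all observation times.
        """
        t_mean = float(self.observations["time_years_from_baseline"].mean())
        grid = self.config.shift_grid() - t_mean
        prof = _nll_profiles(lookup, variances, self.observations,
                             subj_index, len(self.subjects), grid)
        best = np.argmin(prof, axis=1)  # first minimum = smallest shift on ties
        return grid[best], prof[np.arange(len(best)), best].sum()

    # -- main entry ----------------------------------------------------------

    def fit(self, seed: int = 0) -> "DPMResults":
        c = self.config
        if len(self.biomarkers) < 2 and not c.allow_single_biomarker:
            raise FitError(
                "time-shifts are not identifiable from a single biomarker "
                "without cross-marker overlap; need >= 2 biomarkers"
            )
        if len(self.subjects) < 2:
            raise FitError("need at least 2 subjects")
        basis = self._basis()
        obs = self.observations
        subj_index = obs["subject_id"].map(self._subj_pos).to_numpy()
        times = obs["time_years_from_baseline"].to_numpy(float)
        by_marker = {b: np.flatnonzero(obs["biomarker_name"].to_numpy() == b)
                     for b in self.biomarkers}

        delta = self._init_shifts()
        params = {b: np.r_[0.0, np.full(basis.n_basis, -1.0)]
                  for b in self.biomarkers}
        variances = {b: 1.0 for b in self.biomarkers}
        log: list[float] = []
        converged = False
        seen_states: set[bytes] = set()
        for _ in range(c.max_iter):
            # (i) curve + variance updates given shifts
            obj = 0.0
            for b in self.biomarkers:
                idx = by_marker[b]
                t = times[idx] + delta[subj_index[idx]]
                y = obs["value"].to_numpy(float)[idx]
                params[b] = self._fit_curve(basis, t, y, variances[b], params[b])
                D = basis.design(t)
                r = y - params[b][0] - D @ softplus(params[b][1:])
                variances[b] = max(float(r @ r / len(r)), 1e-8)
                obj += (len(r) / 2 * (1 + np.log(2 * np.pi * variances[b]))
                        + params[b][0] ** 2 / (2 * c.offset_prior_sd ** 2)
                        + params[b][1:] @ params[b][1:]
                        / (2 * c.theta_prior_sd ** 2))
            log.append(float(obj))
            # (ii) shift grid search given curves
            lookup = self._curve_lookup(basis, params)
            new_delta, _ = self._update_shifts(lookup, variances, subj_index)
            move = float(np.max(np.abs(new_delta - delta)))
            delta = new_delta
            if move < c.shift_tol:
                converged = True
                break
            # the grid search can cycle between equivalent assignments one
            # grid step apart; a revisited shift state cannot lead anywhere
            # new, so treat it as converged
            state = delta.tobytes()
            if state in seen_states:
                converged = True
                break
            seen_states.add(state)
        if not converged:
            warnings.warn("DPM alternating fit did not converge "
                          f"within {c.max_iter} iterations", RuntimeWarning)

        # final curve refit at converged shifts
        for b in self.biomarkers:
            idx = by_marker[b]
            t = times[idx] + delta[subj_index[idx]]
            y = obs["value"].to_numpy(float)[idx]
            params[b] = self._fit_curve(basis, t, y, variances[b], params[b])
            D = basis.design(t)
            r = y - params[b][0] - D @ softplus(params[b][1:])
            variances[b] = max(float(r @ r / len(r)), 1e-8)

        # recentring: reported axis has mean shift zero
        origin = float(delta.mean())
        shifts = pd.Series(delta - origin, index=self.subjects,
                           name="time_shift")

        # variance decomposition: within-subject scatter -> noise,
        # remainder of the total -> random intercept
        noise_sd, ri_sd, total_sd = {}, {}, {}
        for b in self.biomarkers:
            idx = by_marker[b]
            t = times[idx] + delta[subj_index[idx]]
            y = obs["value"].to_numpy(float)[idx]
            D = basis.design(t)
            r = y - params[b][0] - D @ softplus(params[b][1:])
            rs = pd.Series(r, index=subj_index[idx])
            grouped = rs.groupby(level=0)
            counts = grouped.count()
            multi = counts[counts >= 2].index
            if len(multi) > 0:
                within = float(np.sum([
                    ((rs.loc[[j]] - rs.loc[[j]].mean()) ** 2).sum()
                    for j in multi
                ]) / max((counts.loc[multi] - 1).sum(), 1))
            else:
                within = variances[b]
            within = min(max(within, 1e-8), variances[b])
            noise_sd[b] = np.sqrt(within)
            ri_sd[b] = np.sqrt(max(variances[b] - within, 0.0))
            total_sd[b] = np.sqrt(variances[b])

        trajectories = {}
        for b in self.biomarkers:
            idx = by_marker[b]
            t = times[idx] + delta[subj_index[idx]]
            cov = self._laplace_cov(basis, t, params[b], variances[b])
            trajectories[b] = TrajectoryModel(
                biomarker=b, basis=basis, offset=float(params[b][0]),
                theta=params[b][1:].copy(), param_cov=cov, origin=origin,
            )
        positions = times + delta[subj_index] - origin
        support = (float(positions.min()), float(positions.max()))
        return DPMResults(
            trajectories=trajectories,
            data_support=support,
            time_shifts=shifts,
            noise_sd=pd.Series(noise_sd),
            random_intercept_sd=pd.Series(ri_sd),
            total_sd=pd.Series(total_sd),
            orientation=self.orientation,
            convergence_log=log,
            converged=converged,
            seed=seed,
            fit_config=c,
        )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class DPMResults:
    """Fitted disease progression model.

    ``time_shifts`` are recentred to mean zero over the fitting sample;
    ``total_sd**2 = noise_sd**2 + random_intercept_sd**2`` is the variance
    used in the staging likelihood.  Curves are reported on the recentred
    latent axis.
    """

    trajectories: dict[str, TrajectoryModel]
    data_support: tuple[float, float]
    time_shifts: pd.Series
    noise_sd: pd.Series
    random_intercept_sd: pd.Series
    total_sd: pd.Series
    orientation: OrientationRecord | None
    convergence_log: list[float]
    converged: bool
    seed: int
    fit_config: DPMFitConfig

    # -- axis / grids --------------------------------------------------------
    def default_grid(self, step: float = 0.1) -> np.ndarray:
        lo = self.fit_config.shift_lo
        hi = self.fit_config.shift_hi + 5.0
        return np.arange(lo, hi + 1e-9, step)

    def support_grid(self, step: float = 0.05) -> np.ndarray:
        """Grid restricted to the latent-time range covered by fitting data.

        Outside this range the posterior is prior-dominated and derivative
        statistics are meaningless, so cascade analyses default to it.
        """
        lo, hi = self.data_support
        n = int(round((hi - lo) / step))
        return lo + step * np.arange(n + 1)

    def _variances(self) -> dict[str, float]:
        return {b: float(self.total_sd[b] ** 2) for b in self.trajectories}

    def _curve_lookup(self, step: float = 0.05):
        lookup = {}
        for b, tr in self.trajectories.items():
            tg = np.arange(tr.basis.lo - tr.origin, tr.basis.hi - tr.origin
                           + 1e-9, step)
            lookup[b] = (tg, tr.predict(tg))
        return lookup

    # -- prediction and sampling --------------------------------------------
    def predict_trajectory(self, biomarker: str, grid=None,
                           band_samples: int = 2000,
                           band_seed: int = 12345) -> pd.DataFrame:
        """Posterior mean curve with a pointwise 95% credible band.

        The mean is computed by quadrature (exact up to quadrature error);
        the band comes from Laplace-posterior curve draws.
        """
        tr = self.trajectories[biomarker]  # KeyError for unknown biomarker
        grid = self.default_grid() if grid is None else np.asarray(grid, float)
        mean = tr.posterior_mean_curve(grid)
        rng = np.random.default_rng(band_seed)
        curves = tr.curves_from_params(tr.sample_params(band_samples, rng), grid)
        lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
        return pd.DataFrame({"grid": grid, "mean": mean, "lower": lo,
                             "upper": hi, "sd": curves.std(axis=0)})

    def sample_trajectories(self, biomarker: str, n_samples: int,
                            seed: int, grid=None) -> TrajectorySampleSet:
        """Draw monotone trajectory samples from the Laplace posterior."""
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        tr = self.trajectories[biomarker]
        grid = self.default_grid() if grid is None else np.asarray(grid, float)
        rng = np.random.default_rng(seed)
        curves = tr.curves_from_params(tr.sample_params(n_samples, rng), grid)
        return TrajectorySampleSet(biomarker, grid, curves, seed)

    # -- likelihood ----------------------------------------------------------
    def subject_nll(self, subject_obs: pd.DataFrame, t: float) -> float:
        """Gaussian negative log-likelihood of one subject at latent time t.

        ``subject_obs`` holds oriented observations (columns biomarker_name,
        value, time_years_from_baseline); each contributes with variance
        noise^2 + random_intercept^2 of its biomarker.
        """
        obs = subject_obs[subject_obs["biomarker_name"].isin(self.trajectories)]
        obs = obs.dropna(subset=["value"])
        if obs.empty:
            raise UnstageableError(
                "subject has no usable observation on any fitted biomarker"
            )
        nll = 0.0
        for _, row in obs.iterrows():
            b = row["biomarker_name"]
            s2 = float(self.total_sd[b] ** 2)
            pred = float(self.trajectories[b].predict(
                [t + float(row["time_years_from_baseline"])])[0])
            nll += 0.5 * np.log(2 * np.pi * s2) \
                + (float(row["value"]) - pred) ** 2 / (2 * s2)
        return float(nll)

    def nll_profile(self, subject_obs: pd.DataFrame, grid) -> np.ndarray:
        """Vectorized :meth:`subject_nll` over a grid of candidate stages."""
        obs = subject_obs[subject_obs["biomarker_name"].isin(self.trajectories)]
        obs = obs.dropna(subset=["value"]).reset_index(drop=True)
        if obs.empty:
            raise UnstageableError(
                "subject has no usable observation on any fitted biomarker"
            )
        grid = np.asarray(grid, float)
        prof = _nll_profiles(self._curve_lookup(), self._variances(), obs,
                             np.zeros(len(obs), int), 1, grid)
        return prof[0]

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        lines = ["Disease progression model fit",
                 "=" * 34,
                 f"biomarkers: {len(self.trajectories)}   "
                 f"subjects: {len(self.time_shifts)}   "
                 f"converged: {self.converged} "
                 f"({len(self.convergence_log)} outer iterations)",
                 "",
                 f"{'biomarker':<22}{'noise_sd':>10}{'ri_sd':>10}"
                 f"{'total_sd':>10}"]
        for b in self.trajectories:
            lines.append(f"{b:<22}{self.noise_sd[b]:>10.3f}"
                         f"{self.random_intercept_sd[b]:>10.3f}"
                         f"{self.total_sd[b]:>10.3f}")
        sh = self.time_shifts
        lines += ["",
                  f"time-shifts (years): mean {sh.mean():+.3f}  "
                  f"sd {sh.std():.3f}  range [{sh.min():.2f}, {sh.max():.2f}]"]
        return "\n".join(lines)

    # -- serialization -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "fit_config": asdict(self.fit_config),
            "data_support": list(self.data_support),
            "time_shifts": {str(k): float(v)
                            for k, v in self.time_shifts.items()},
            "noise_sd": {k: float(v) for k, v in self.noise_sd.items()},
            "random_intercept_sd": {k: float(v) for k, v in
                                    self.random_intercept_sd.items()},
            "total_sd": {k: float(v) for k, v in self.total_sd.items()},
            "convergence_log": self.convergence_log,
            "converged": self.converged,
            "seed": self.seed,
            "orientation": None if self.orientation is None else
            asdict(self.orientation),
            "trajectories": {
                b: {
                    "basis": tr.basis.to_dict(),
                    "offset": tr.offset,
                    "theta": tr.theta.tolist(),
                    "param_cov": tr.param_cov.tolist(),
                    "origin": tr.origin,
                } for b, tr in self.trajectories.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "DPMResults":
        d = json.loads(Path(path).read_text())
        trajectories = {}
        for b, td in d["trajectories"].items():
            basis = MonotoneBasis(**td["basis"])
            trajectories[b] = TrajectoryModel(
                biomarker=b, basis=basis, offset=td["offset"],
                theta=np.array(td["theta"]),
                param_cov=np.array(td["param_cov"]),
                origin=td["origin"],
            )
        orient = d["orientation"]
        return cls(
            trajectories=trajectories,
            data_support=tuple(d["data_support"]),
            time_shifts=pd.Series(d["time_shifts"], name="time_shift"),
            noise_sd=pd.Series(d["noise_sd"]),
            random_intercept_sd=pd.Series(d["random_intercept_sd"]),
            total_sd=pd.Series(d["total_sd"]),
            orientation=None if orient is None else OrientationRecord(**orient),
            convergence_log=list(d["convergence_log"]),
            converged=bool(d["converged"]),
            seed=int(d["seed"]),
            fit_config=DPMFitConfig(**d["fit_config"]),
        )


def fit_dpm(cohort, fit_config: DPMFitConfig | None = None,
            seed: int = 0) -> DPMResults:
    """Fit the DPM to an oriented cohort (functional surface).

    ``cohort`` may be a :class:`LongitudinalCohort` or a long observation
    table with oriented values.
    """
    obs = cohort.observations if isinstance(cohort, LongitudinalCohort) \
        else cohort
    model = DiseaseProgressionModel(obs, fit_config=fit_config)
    return model.fit(seed=seed)
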