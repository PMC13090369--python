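"""Downstream inferential battery on per-subject scalars.

Implements the association analyses run on disease stages and mean
encoding-related fMRI activity: semi-partial correlations, ANCOVA with Holm
post-hocs, parallel mediation with delta-method (Sobel) inference,
region-level marginal models with subject-clustered sandwich covariance and
wild-bootstrap family-wise-error control, random-intercept mixed models with
a time x stage interaction, per-subject slope-slope correlations, and the
Bonferroni-Holm step-down adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "holm_adjust",
    "SemipartialResult",
    "semipartial_corr",
    "AncovaResult",
    "ancova_group_effect",
    "MediationResult",
    "parallel_mediation",
    "MarginalModelResult",
    "fit_marginal_swe",
    "wild_bootstrap_fwe",
    "LMEInteractionResult",
    "lme_time_by_stage",
    "slope_change_corr",
]

logger = logging.getLogger(__name__)


def _with_intercept(*cols):
    cols = [np.asarray(c, float) for c in cols]
    n = len(cols[0])
    mats = [np.ones((n, 1))]
    for c in cols:
        mats.append(c.reshape(n, -1))
    return np.hstack(mats)


def _residualize(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


# ---------------------------------------------------------------------------
# Holm
# ---------------------------------------------------------------------------

def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (monotonicity enforced)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p-values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# Semi-partial correlation
# ---------------------------------------------------------------------------

@dataclass
class SemipartialResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    df: int
    n: int


def semipartial_corr(activity, biomarker, control_set=None,
                     demographics=None) -> SemipartialResult:
    """Semi-partial Pearson correlation of activity with a biomarker.

    The biomarker is residualized on the control variables *and*
    demographics; activity is residualized on demographics only (controls
    removed from one side — the defining feature of a semi-partial
    correlation).  Inference is a t-test with df = n - 2 - #covariates and a
    Fisher-z 95% CI.
    """
    a = np.asarray(activity, float)
    b = np.asarray(biomarker, float)
    n = len(a)
    k_ctrl = 0
    Xb_cols, Xa_cols = [], []
    if control_set is not None and np.size(control_set) > 0:
        C = np.asarray(control_set, float).reshape(n, -1)
        Xb_cols.append(C)
        k_ctrl += C.shape[1]
    if demographics is not None and np.size(demographics) > 0:
        D = np.asarray(demographics, float).reshape(n, -1)
        Xb_cols.append(D)
        Xa_cols.append(D)
        k_ctrl += D.shape[1]
    if n < k_ctrl + 3:
        raise ValueError("need n >= number of controls + 3")
    Xb = _with_intercept(*Xb_cols) if Xb_cols else np.ones((n, 1))
    Xa = _with_intercept(*Xa_cols) if Xa_cols else np.ones((n, 1))
    for X in (Xb, Xa):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("control design is rank deficient")
    rb = _residualize(b, Xb)
    ra = _residualize(a, Xa)
    r = float(np.corrcoef(ra, rb)[0, 1])
    df = n - 2 - k_ctrl
    t = r * np.sqrt(df / max(1 - r ** 2, 1e-12))
    p = 2 * stats.t.sf(abs(t), df)
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    se = 1.0 / np.sqrt(max(n - 3 - k_ctrl, 1))
    lo, hi = np.tanh(z - 1.959964 * se), np.tanh(z + 1.959964 * se)
    return SemipartialResult(r, float(lo), float(hi), float(p), df, n)


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------

@dataclass
class AncovaResult:
    f_stat: float
    df1: int
    df2: int
    p_value: float
    partial_eta_sq: float
    posthoc: pd.DataFrame  # pairwise t, raw and Holm-adjusted p


def ancova_group_effect(outcome, group, covariates=None) -> AncovaResult:
    """One-way ANCOVA for a group factor given covariates.

    F compares the covariates-only model with the model adding group
    dummies; with an empty covariate set this reduces to a one-way ANOVA.
    Pairwise group differences are covariate-adjusted contrasts from the
    full model with pooled residual variance, Holm-corrected.
    """
    y = np.asarray(outcome, float)
    g = pd.Series(group).astype(str).reset_index(drop=True)
    levels = sorted(g.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = g.value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"groups with < 3 members: {small}")
    n = len(y)
    cov_block = []
    if covariates is not None and np.size(covariates) > 0:
        cov_block = [np.asarray(covariates, float).reshape(n, -1)]
    X0 = _with_intercept(*cov_block) if cov_block else np.ones((n, 1))
    dummies = pd.get_dummies(g, drop_first=True).to_numpy(float)
    X1 = np.hstack([X0, dummies])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("ANCOVA design is rank deficient")
    rss0 = float((_residualize(y, X0) ** 2).sum())
    res1 = _residualize(y, X1)
    rss1 = float((res1 ** 2).sum())
    df1 = len(levels) - 1
    df2 = n - X1.shape[1]
    f_stat = ((rss0 - rss1) / df1) / (rss1 / df2)
    p = float(stats.f.sf(f_stat, df1, df2))
    eta = (rss0 - rss1) / rss0 if rss0 > 0 else 0.0

    # pairwise post-hocs: adjusted means from the full model, pooled variance
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    sigma2 = rss1 / df2
    XtX_inv = np.linalg.pinv(X1.T @ X1)
    k0 = X0.shape[1]
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            c = np.zeros(X1.shape[1])
            if i > 0:
                c[k0 + i - 1] = 1.0
            if j > 0:
                c[k0 + j - 1] -= 1.0
            est = float(c @ beta)
            se = float(np.sqrt(sigma2 * c @ XtX_inv @ c))
            t = est / se
            rows.append((levels[i], levels[j], est, se, t,
                         2 * stats.t.sf(abs(t), df2)))
    posthoc = pd.DataFrame(rows, columns=["group_a", "group_b", "diff",
                                          "se", "t", "p_raw"])
    posthoc["p_holm"] = holm_adjust(posthoc["p_raw"].to_numpy())
    return AncovaResult(float(f_stat), df1, df2, p, float(eta), posthoc)


# ---------------------------------------------------------------------------
# Parallel mediation
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    """Parallel mediation x -> (m_1..m_K) -> y with delta-method inference.

    All inputs are residualized for the supplied demographics before any
    path model is fitted.  ``total`` satisfies the linear identity
    total = direct + sum(indirect) to numerical precision.
    """

    indirect: pd.DataFrame  # per mediator: a, b, ab, se, z, p
    direct: float
    direct_se: float
    direct_z: float
    direct_p: float
    total: float
    n: int
    condition_number: float
    warnings: list[str] = field(default_factory=list)


def parallel_mediation(x, y, mediators, demographics=None,
                       mediator_names=None) -> MediationResult:
    """Linear-system parallel mediation with Sobel-type z statistics.

    Mediator models ``m_k ~ x``, outcome model ``y ~ x + m_1 + ... + m_K``;
    ``indirect_k = a_k * b_k`` with delta-method standard error
    ``sqrt(a^2 se_b^2 + b^2 se_a^2)``.  Complete cases only.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    M = np.column_stack([np.asarray(m, float) for m in mediators])
    keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(M), axis=1)
    if demographics is not None and np.size(demographics) > 0:
        D = np.asarray(demographics, float).reshape(len(x), -1)
        keep &= np.all(np.isfinite(D), axis=1)
        D = D[keep]
    else:
        D = None
    x, y, M = x[keep], y[keep], M[keep]
    n = len(x)
    if D is not None:
        Z = _with_intercept(D)
        x = _residualize(x, Z)
        y = _residualize(y, Z)
        M = np.column_stack([_residualize(M[:, k], Z)
                             for k in range(M.shape[1])])
    names = mediator_names or [f"m{k + 1}" for k in range(M.shape[1])]

    warns: list[str] = []
    Xfull = _with_intercept(x, M)
    cond = float(np.linalg.cond(Xfull))
    if cond > 1e8:
        warns.append(f"collinear mediators (condition number {cond:.2e})")

    def ols(yv, X):
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        r = yv - X @ beta
        dof = len(yv) - X.shape[1]
        s2 = r @ r / dof
        cov = s2 * np.linalg.pinv(X.T @ X)
        return beta, np.sqrt(np.diag(cov))

    Xx = _with_intercept(x)
    rows = []
    b_full, se_full = ols(y, Xfull)
    for k, name in enumerate(names):
        a_hat, a_se = ols(M[:, k], Xx)
        a, sa = float(a_hat[1]), float(a_se[1])
        b, sb = float(b_full[2 + k]), float(se_full[2 + k])
        ab = a * b
        se = float(np.sqrt(a ** 2 * sb ** 2 + b ** 2 * sa ** 2))
        z = ab / se if se > 0 else 0.0
        rows.append((name, a, b, ab, se, z, 2 * stats.norm.sf(abs(z))))
    indirect = pd.DataFrame(rows, columns=["mediator", "a", "b", "ab",
                                           "se", "z", "p"])
    direct = float(b_full[1])
    d_se = float(se_full[1])
    d_z = direct / d_se if d_se > 0 else 0.0
    total_hat, _ = ols(y, Xx)
    total = float(total_hat[1])
    return MediationResult(indirect, direct, d_se, float(d_z),
                           float(2 * stats.norm.sf(abs(d_z))), total, n,
                           cond, warns)


# ---------------------------------------------------------------------------
# Marginal model with subject-clustered sandwich covariance
# ---------------------------------------------------------------------------

DESIGN_COLUMNS = ["intercept", "stage", "stage_sq", "time", "age", "sex",
                  "education", "time_x_age", "time_x_sex", "time_x_education"]


@dataclass
class MarginalModelResult:
    """OLS marginal mean model per region with cluster-robust covariance.

    The design holds an intercept, linear and quadratic disease stage,
    intra-individual time centred on each subject's mean timepoint, age, sex,
    education, and the time x covariate interactions.  ``cov`` is the
    subject-level sandwich estimator per region.
    """

    columns: list[str]
    regions: list[str]
    X: np.ndarray
    Y: np.ndarray  # (n_obs, n_regions)
    beta: np.ndarray  # (p, n_regions)
    cov: np.ndarray  # (n_regions, p, p)
    clusters: np.ndarray
    t_stats: pd.DataFrame
    p_values: pd.DataFrame
    n_clusters: int

    def contrast_vector(self, contrast) -> np.ndarray:
        if isinstance(contrast, str):
            c = np.zeros(len(self.columns))
            c[self.columns.index(contrast)] = 1.0
            return c
        return np.asarray(contrast, float)


def _cluster_sandwich(X, resid, clusters, XtX_inv):
    """Subject-clustered sandwich covariance for OLS coefficients."""
    order = np.argsort(clusters, kind="stable")
    Xs, rs, cs = X[order], resid[order], clusters[order]
    starts = np.r_[0, 1 + np.flatnonzero(cs[1:] != cs[:-1])]
    scores = np.add.reduceat(Xs * rs[:, None], starts, axis=0)
    meat = scores.T @ scores
    return XtX_inv @ meat @ XtX_inv


def fit_marginal_swe(data: pd.DataFrame, regions, stage_col="stage_adjusted",
                     time_col="time_years_from_baseline",
                     subject_col="subject_id") -> MarginalModelResult:
    """Fit the longitudinal marginal activity model with sandwich inference.

    ``data`` is long format: one row per subject-visit, with the region
    activity columns, the (cross-sectional) disease stage, demographics and
    the visit time.  Time is recoded within subject as the deviation from the
    subject's mean timepoint, so between- and within-subject effects
    separate.  Repeated rows of a subject are handled by the cluster-robust
    (sandwich) covariance; t statistics use n_clusters - 1 reference df.
    """
    df = data.copy()
    if len(df[subject_col].unique()) < 20:
        raise ValueError("need at least 20 subjects")
    tmean = df.groupby(subject_col)[time_col].transform("mean")
    tc = df[time_col] - tmean
    stage = df[stage_col].to_numpy(float)
    X = np.column_stack([
        np.ones(len(df)), stage, stage ** 2, tc,
        df["age_at_baseline"].to_numpy(float), df["sex"].to_numpy(float),
        df["education"].to_numpy(float),
        tc * df["age_at_baseline"].to_numpy(float),
        tc * df["sex"].to_numpy(float),
        tc * df["education"].to_numpy(float),
    ])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        aliased = [DESIGN_COLUMNS[j] for j in range(X.shape[1])
                   if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"singular design; aliased columns: {aliased}")
    regions = list(regions)
    Y = df[regions].to_numpy(float)
    clusters = df[subject_col].to_numpy()
    n_clusters = len(np.unique(clusters))
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    covs, trows, prows = [], [], []
    for r_i, r in enumerate(regions):
        resid = Y[:, r_i] - X @ beta[:, r_i]
        V = _cluster_sandwich(X, resid, clusters, XtX_inv)
        covs.append(V)
        se = np.sqrt(np.diag(V))
        t = beta[:, r_i] / se
        trows.append(t)
        prows.append(2 * stats.t.sf(np.abs(t), n_clusters - 1))
    t_stats = pd.DataFrame(np.array(trows), index=regions,
                           columns=DESIGN_COLUMNS)
    p_values = pd.DataFrame(np.array(prows), index=regions,
                            columns=DESIGN_COLUMNS)
    return MarginalModelResult(list(DESIGN_COLUMNS), regions, X, Y, beta,
                               np.array(covs), clusters, t_stats, p_values,
                               n_clusters)


def wild_bootstrap_fwe(model: MarginalModelResult, contrast,
                       n_boot: int = 1000, seed: int | None = None,
                       alternative: str = "two-sided") -> pd.DataFrame:
    """Wild-bootstrap FWE-corrected inference for one contrast across regions.

    Rademacher signs are drawn per subject (cluster) and applied to the
    residuals of the restricted (null-imposed) fit; each replicate is refit
    and the maximum statistic across regions forms the family-wise reference
    distribution.  One-sided alternatives use the signed statistic; the
    default is two-sided (max |t|).  Returns per-region observed t,
    unadjusted bootstrap p, and FWE-adjusted p (always >= the unadjusted p).
    """
    if seed is None:
        raise ValueError("seed is required for reproducible inference")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable FWE estimates",
                      UserWarning)
    c = model.contrast_vector(contrast)
    if np.count_nonzero(c) != 1:
        raise NotImplementedError("only single-coefficient contrasts")
    j = int(np.flatnonzero(c)[0])
    X = model.X
    keep = [k for k in range(X.shape[1]) if k != j]
    X0 = X[:, keep]
    X0tX0_inv = np.linalg.inv(X0.T @ X0)
    XtX_inv = np.linalg.inv(X.T @ X)
    pinvX = XtX_inv @ X.T
    rng = np.random.default_rng(seed)

    clusters = model.clusters
    order = np.argsort(clusters, kind="stable")
    inv_order = np.empty_like(order)
    inv_order[order] = np.arange(len(order))
    cs = clusters[order]
    starts = np.r_[0, 1 + np.flatnonzero(cs[1:] != cs[:-1])]
    cluster_id_sorted = np.repeat(np.arange(len(starts)),
                                  np.diff(np.r_[starts, len(cs)]))
    cluster_of_row = cluster_id_sorted[inv_order]
    n_clusters = len(starts)

    A = XtX_inv @ c  # maps scores to the contrast coefficient variance

    obs_t = np.empty(len(model.regions))
    boot_t = np.empty((len(model.regions), n_boot))
    for r_i in range(len(model.regions)):
        y = model.Y[:, r_i]
        # observed statistic (from the full fit)
        obs_t[r_i] = (c @ model.beta[:, r_i]) / np.sqrt(
            c @ model.cov[r_i] @ c)
        # restricted fit under H0: contrast coefficient = 0
        b0 = X0tX0_inv @ X0.T @ y
        fitted0 = X0 @ b0
        e0 = y - fitted0
        W = rng.choice([-1.0, 1.0], size=(n_clusters, n_boot))
        Ystar = fitted0[:, None] + e0[:, None] * W[cluster_of_row, :]
        Bstar = pinvX @ Ystar  # (p, n_boot)
        Rstar = Ystar - X @ Bstar
        # cluster-summed scores per replicate: (n_clusters, p, n_boot)
        SX = Rstar[order][:, None, :] * X[order][:, :, None]
        Sc = np.add.reduceat(SX, starts, axis=0)
        half = np.einsum("p,kpb->kb", A, Sc)
        var_c = np.einsum("kb,kb->b", half, half)
        boot_t[r_i] = (c @ Bstar) / np.sqrt(var_c)

    if alternative == "two-sided":
        stat_obs, stat_boot = np.abs(obs_t), np.abs(boot_t)
    elif alternative == "greater":
        stat_obs, stat_boot = obs_t, boot_t
    elif alternative == "less":
        stat_obs, stat_boot = -obs_t, -boot_t
    else:
        raise ValueError("alternative must be two-sided/greater/less")
    max_boot = stat_boot.max(axis=0)
    p_unadj = (1 + (stat_boot >= stat_obs[:, None]).sum(axis=1)) / (n_boot + 1)
    p_fwe = (1 + (max_boot[None, :] >= stat_obs[:, None]).sum(axis=1)) \
        / (n_boot + 1)
    return pd.DataFrame({
        "region": model.regions, "t": obs_t, "p_boot": p_unadj,
        "p_fwe": np.maximum(p_fwe, p_unadj), "n_boot": n_boot,
    })


# ---------------------------------------------------------------------------
# Random-intercept LME with time x stage interaction
# ---------------------------------------------------------------------------

@dataclass
class LMEInteractionResult:
    outcome: str
    interaction_coef: float
    interaction_se: float
    interaction_t: float
    interaction_p: float
    partial_eta_sq: float
    df_resid: float
    used_random_slope: bool
    fallback_logged: bool


def lme_time_by_stage(data: pd.DataFrame, outcomes,
                      stage_col="stage_adjusted",
                      time_col="time_years_from_baseline",
                      subject_col="subject_id",
                      try_random_slope: bool = True) -> pd.DataFrame:
    """Mixed models of longitudinal activity with a time x stage interaction.

    For each outcome column a linear mixed model with fixed effects
    time, stage, time x stage and time x demographics is fitted.  A random
    time slope is attempted first; when its variance estimate is essentially
    zero (singular fit) or the optimizer fails, the model falls back to a
    random intercept only, and the fallback is logged — longitudinal
    task-fMRI commonly produces exactly this degenerate slope variance.
    Holm adjustment is applied across the outcomes.
    """
    import statsmodels.api as sm

    df = data.copy()
    visits = df.groupby(subject_col)[time_col].nunique()
    if (visits >= 2).sum() < 30:
        raise ValueError("need >= 2 visits for at least 30 subjects")
    t = df[time_col].to_numpy(float)
    stage = df[stage_col].to_numpy(float)
    exog = pd.DataFrame({
        "intercept": 1.0, "time": t, "stage": stage,
        "time_x_stage": t * stage,
        "age": df["age_at_baseline"].to_numpy(float),
        "sex": df["sex"].to_numpy(float),
        "education": df["education"].to_numpy(float),
        "time_x_age": t * df["age_at_baseline"].to_numpy(float),
        "time_x_sex": t * df["sex"].to_numpy(float),
        "time_x_education": t * df["education"].to_numpy(float),
    })
    def _fit_mixed(md):
        last = None
        for method in (None, "lbfgs", "cg"):
            try:
                kw = {} if method is None else {"method": method}
                return md.fit(reml=True, **kw)
            except np.linalg.LinAlgError as e:  # optimizer-specific failure
                last = e
        raise last

    groups = df[subject_col]
    rows = []
    for out in outcomes:
        y = df[out].to_numpy(float)
        used_slope, fallback = False, False
        fit = None
        if try_random_slope:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                try:
                    md = sm.MixedLM(y, exog, groups=groups,
                                    exog_re=exog[["intercept", "time"]])
                    cand = _fit_mixed(md)
                    slope_var = float(cand.cov_re.iloc[1, 1])
                    total_re = float(np.trace(cand.cov_re)) + float(cand.scale)
                    boundary = any("boundary" in str(w.message)
                                   for w in caught)
                    if cand.converged and not boundary \
                            and slope_var > 1e-3 * total_re:
                        fit, used_slope = cand, True
                    else:
                        fallback = True
                except Exception:
                    fallback = True
        if fit is None:
            if fallback:
                logger.info("%s: random-slope fit singular or failed; "
                            "falling back to random intercept", out)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = sm.MixedLM(y, exog, groups=groups)
                fit = _fit_mixed(md)
            if not fit.converged:
                raise RuntimeError(
                    f"mixed model for {out!r} did not converge; "
                    f"gradient norm and scale: {fit.scale}"
                )
        coef = float(fit.params["time_x_stage"])
        se = float(fit.bse["time_x_stage"])
        tval = coef / se
        dfres = float(len(y) - exog.shape[1] - 1)
        p = float(2 * stats.t.sf(abs(tval), dfres))
        eta = tval ** 2 / (tval ** 2 + dfres)
        rows.append(LMEInteractionResult(out, coef, se, float(tval), p,
                                         float(eta), dfres, used_slope,
                                         fallback))
    res = pd.DataFrame([r.__dict__ for r in rows])
    res["interaction_p_holm"] = holm_adjust(res["interaction_p"].to_numpy())
    return res


# ---------------------------------------------------------------------------
# Slope-slope correlation
# ---------------------------------------------------------------------------

@dataclass
class SlopeCorrResult:
    r: float
    p_value: float
    n: int
    low_n_warning: bool


def slope_change_corr(stage_slopes: pd.Series,
                      activity_slopes: pd.Series) -> SlopeCorrResult:
    """Pearson correlation of per-subject stage and activity slopes."""
    joined = pd.concat([stage_slopes.rename("s"),
                        activity_slopes.rename("a")], axis=1).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need at least 3 paired slopes")
    low = n < 10
    if low:
        warnings.warn("fewer than 10 paired slopes; correlation unstable",
                      UserWarning)
    r, p = stats.pearsonr(joined["s"], joined["a"])
    return SlopeCorrResult(float(r), float(p), n, low)
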