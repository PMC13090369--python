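# Methods

This note documents the models, algorithms and design choices behind
`cascade-dpm`, in the order the pipeline runs them.

## Synthetic cohort generator

The generator (`cascade_dpm.simulate`) emulates the structure of a
longitudinal memory-clinic cohort so the whole analysis chain can be
validated against known ground truth.

**Generating model.**  Every biomarker *b* has a four-parameter logistic
abnormality trajectory on the latent disease-time axis (years),

    g_b(t) = amplitude_b / (1 + exp(-slope_b (t - midpoint_b))),

and the observed native-scale value of subject *j* at visit time τ is
`baseline_b + dir_b · g_b(s_j + τ) + u_jb + e`, with `s_j` the subject's
baseline latent stage, `u_jb ~ N(0, ri_sd_b²)` a subject random intercept
and `e ~ N(0, noise_sd_b²)` observation noise.  `dir_b` is the sign of
change with disease on the native scale: −1 for the Aβ42/40 ratio, volumes,
PACC5 and fMRI activation magnitude; +1 for pTau181, ADAS-COG-13 and loss
of deactivation.

**Default parameters.**  The eight biomarkers' midpoints are placed at the
cascade ordering CSF → volumes → fMRI deactivation → cognition (1.17 and
2.79 yr for the CSF markers, 4.09 and 5.38 yr for entorhinal and
hippocampal volume, 6.36 yr for deactivation, 8.95 and 10.57 yr for PACC5
and ADAS-COG-13); fMRI activation, which is analysed downstream rather than
modelled, sits at 7.5 yr.  Logistic slopes are 0.5–0.6 /yr so each
transition spans ~6–8 years and the full cascade ~20 years.  Noise and
random-intercept scales are ≈8% of each amplitude, making oriented z-scored
trajectories range roughly over one unit.  Diagnostic groups CN/SCD/MCI/DAT
draw baseline stages from Gaussians with means −2/3/7/11 yr (SDs 3, 3, 3,
2.5) and proportions 80:57:44:27, so group stage distributions overlap but
are strictly ordered.  Age is `70 + 0.5·stage + N(0, 4²)` to emulate the
positive age–stage association; education and sex are independent of stage.

**Schedules and missingness.**  Visits are annual; cognition and volumes
are scheduled at years 0–4, fMRI at years 0–3 (four time points), CSF at
years 0, 2, 4.  The baseline occasion is always complete — cohort inclusion
requires one full measurement occasion, and the stored AT label is derived
from the observed baseline CSF values through the package's own classifier,
so label and data can never disagree.  Follow-up visits are dropped
missing-completely-at-random per biomarker (30% CSF, 10% volumes, 15% fMRI,
5% cognition).  Informative dropout is deliberately out of scope; passing
tests therefore say nothing about robustness to stage-dependent attrition,
nor about site effects beyond a site label, measurement drift, or
non-sigmoidal trajectories.

**Recognition trials.**  Old/new confidence ratings come from two unit-SD
latent Gaussians separated by the requested discriminability, discretized
by fixed equal-width cut-points centred between the class means; rating 5
means "sure novel".  Zero discriminability yields identical rating
distributions in expectation, and the A′ of the output equals the
Mann–Whitney pair-count AUC by construction of the cumulative ROC.

## Disease progression model

**Monotone trajectory representation.**  Each biomarker's curve is

    f(t) = offset + Σ_k softplus(θ_k) · I_k(t),

where I_k are integrated quadratic B-splines on a fixed wide domain
(default [−18, 24] yr, 6 interior knots), normalized to rise from 0 to 1.
Because each I_k is nondecreasing and the weights are positive, *every*
curve in the parameterization — MAP estimate or posterior draw — is
nondecreasing by construction; the tests assert a 1e−8 tolerance that only
guards floating-point noise.  A Gaussian prior on the unconstrained
parameters (SD 3 on θ, 10 on the offset) regularizes data-sparse regions.
This finite-rank construction stands in for a monotone Gaussian process;
it trades posterior flexibility for speed and an exact monotonicity
guarantee, which suits a package validated by parameter recovery rather
than posterior calibration.

**Alternating MAP estimation.**  Given shifts, each biomarker's curve is
refit by L-BFGS on the penalized Gaussian likelihood (warm-started; the
update is rejected if the optimizer would increase the objective, so the
logged objective is monotonically nonincreasing), and the residual variance
is updated in closed form.  Given curves, every subject's shift is updated
by exhaustive grid search (step 0.05 yr over a ±15 yr window centred on the
mean observation time — centring makes the whole fit equivariant under a
constant shift of all observation times).  The loop stops when no shift
moves more than 0.01 yr, when the shift configuration revisits a previous
state (the grid search can cycle between equivalent assignments one step
apart), or at 300 iterations; the cap exists because single subjects on
flat likelihood regions can creep one grid step per iteration and
occasionally need a few hundred iterations.  Non-convergence raises a
warning and flags the fit rather than failing silently.

**Initialization and identifiability.**  Shifts start from a severity
proxy — each subject's mean oriented z-score, linearly scaled to a 5-yr
spread — which seeds the optimization away from the degenerate all-zero
configuration.  The latent origin is arbitrary: internally shifts are
unconstrained, and reporting recentres them to mean zero (a pure
relabelling that leaves the objective untouched).  A single biomarker
leaves relative shifts weakly identified, so single-biomarker fits are
refused unless explicitly enabled (`allow_single_biomarker`).

**Variance components.**  The likelihood used during fitting and staging
carries one total variance per biomarker (noise plus random intercept, the
marginal variance of a single observation).  After convergence the total is
decomposed: the within-subject mean squared residual estimates the noise
variance, the remainder the random-intercept variance.  A time-varying
random effect is not modelled.

**Posterior trajectory uncertainty.**  A Laplace (Gauss–Newton)
approximation at the MAP gives a Gaussian over (offset, θ); posterior
curves are draws mapped through the monotone parameterization.  The
pointwise posterior *mean* curve is computed by 1-D Gauss–Hermite
quadrature of E[softplus(θ_k)] (the curve is linear in those terms), which
is exact to quadrature precision — tests verify it against the mean of
10,000 Monte-Carlo draws.  Credible bands come from 2,000 internal draws
with a fixed seed.

## Staging

A subject's stage is the argmin of their Gaussian negative log-likelihood
profile over a candidate-stage grid (the shift window extended by ±5 yr,
step 0.05; ties break to the smallest stage; the coarse argmin is verified
against 10× finer exhaustive search).  Subjects without a usable
observation raise an explicit error — there is no silent default stage.
Anchoring subtracts the reference subgroup's median raw stage (reference:
amyloid-positive tau-negative CN participants, with logged fallbacks to all
A+ CN, then all CN); it always rederives from the raw stages, so it is
idempotent and order-preserving.  Residualization then regresses anchored
stages on age, sex and education by OLS and keeps the residuals.
Residualizing after anchoring (rather than before) only moves a constant
between the two steps, so correlations downstream are unaffected; site is
accepted as an optional covariate but off by default.  For rate-of-change
analyses each measurement occasion is staged *independently* using only
that occasion's data, and a per-subject OLS line of stage on
intra-individual time gives the stage slope.

## Cascade ordering and activity curves

**Fastest change.**  For each biomarker, 200 posterior curves are drawn,
differentiated by central differences on a 0.05-yr grid, and the argmax
recorded (earliest time on exact ties; flat curves are excluded and
logged).  The grid is restricted to the latent-time range covered by
fitting data: outside it the posterior is prior-dominated and derivative
statistics would reflect the basis, not the data.  The median and IQR of
the sampled argmax distribution summarize each biomarker; ordering the
medians orders the cascade.

**Activity smoothing splines.**  Mean activation/deactivation per subject
is regressed on the adjusted stage with a low-rank natural cubic smoothing
spline in the Reinsch/Green–Silverman parameterization: the parameters are
the spline's values at 3 interior quantile knots plus the two boundary
knots, the penalty is the integrated squared second derivative, and the
smoothing parameter minimizes GCV on a 61-point log grid.  Linear functions
lie in the penalty's null space, so exactly linear data are reproduced
exactly at any λ.  The first derivative is analytic (piecewise quadratic,
continuous); values outside the data range use the natural spline's linear
extrapolation and are flagged.

**Non-linearity test.**  The GCV smooth is compared with the OLS line
through an F statistic with fractional degrees of freedom from the smoother
trace (df1 = tr(S) − 2, df2 = n − tr(S)).  A smooth whose effective df does
not exceed the linear model's by more than 1 is reported as having no
testable non-linear component.  Because the smoothing parameter is selected
on the same data, this construction is mildly anti-conservative: under a
linear null the empirical rejection rate at nominal 5% is ≈9% in the
package's own simulations.  The implementation keeps the standard
construction (it is what the fractional-df F values in the field's reports
correspond to) and documents the inflation rather than hiding it; treat
borderline p-values accordingly.

## Association statistics

* **Semi-partial correlation** — the biomarker is residualized on controls
  plus demographics, activity on demographics only; Pearson r of the
  residuals, t-test with df = n − 2 − #covariates, Fisher-z CI.
* **ANCOVA** — nested-model F for the group factor given covariates
  (reducing exactly to one-way ANOVA with no covariates); partial η² =
  SS_effect/(SS_effect+SS_residual); pairwise covariate-adjusted contrasts
  with pooled residual variance, Holm-corrected.  Pooled (not
  group-specific) variances are the declared default.
* **Parallel mediation** — all variables are OLS-residualized for
  demographics first; mediator models m_k ~ x and outcome model
  y ~ x + m_1..m_K; indirect effects a_k·b_k with delta-method (Sobel)
  standard errors and normal-reference z.  The linear identity
  total = direct + Σ indirect holds to numerical precision and is asserted
  on every fit.  Delta-method inference is slightly conservative in small
  samples; the mediation entry point is written so a resampling check can
  be layered on top if needed.  The cognition endpoint defaults to PACC5.
* **Marginal (sandwich) model** — per region, OLS for the marginal mean
  with the design: intercept, stage, stage², within-subject-centred time,
  age, sex, education, and time × demographics interactions; inference by
  the subject-clustered sandwich covariance with t reference df =
  n_clusters − 1.
* **Wild bootstrap FWE** — Rademacher signs per subject applied to the
  residuals of the restricted (null-imposed) fit; each replicate is refit
  and the max statistic across regions forms the family-wise reference;
  p = (1 + #{max* ≥ obs}) / (B + 1).  One-sided variants use the signed
  statistic.  Restricted residuals and cluster-level weights are the
  standard defaults for this estimator family.
* **Mixed models** — random-intercept LME with fixed effects time, stage,
  time × stage and time × demographics.  A random time slope is attempted
  first and abandoned (with a logged fallback) when the fit is singular —
  boundary warning or slope variance below 1e−3 of the total — mirroring
  the degenerate slope variances typical of longitudinal task-fMRI.
  Interaction inference uses a t reference with residual-approximation df;
  partial η² = t²/(t²+df).  Holm adjustment is applied across outcomes.

## Pipeline

`run_full_pipeline` derives per-stage seeds from the master seed by fixed
offsets (simulate +0, fit +1000, staging +2000, trajectories +3000,
analysis +4000), fails fast naming the failing stage, and writes a manifest
with a canonical config hash.  All CSV/JSON outputs are byte-reproducible
given the same inputs; the report's early/late grouping splits at the
sample median adjusted stage.

## Problem sizes used in validation

The test suite validates recovery on cohorts of 60 subjects (10 seeds for
time-shift recovery, 20 for cascade ordering), FWE control on 500 null
datasets of 100 subjects × 5 regions with 199 bootstrap replicates,
mediation calibration on 1,000 null simulations of n = 200, and mixed-model
recovery on 200 simulations of 160 subjects × 4 visits.  These sizes were
chosen to match the synthetic study design while keeping each property
estimable with useful Monte-Carlo precision.

## Known limitations

* The Laplace approximation understates posterior asymmetry near the
  positivity boundary of the weights; credible bands are approximate.
* Grid-search staging has 0.05-yr resolution; uncertainty is reported as a
  likelihood profile, not a posterior.
* All participants are assumed to traverse the cascade at the same speed
  (one time-shift per subject, no progression-rate parameter, no subtype
  mixtures).
* MCAR missingness and annual visits in the generator are idealizations;
  see the generator section for what passing tests do and do not show.
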