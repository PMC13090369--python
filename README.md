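# cascade-dpm

Disease progression modelling and staging for longitudinal Alzheimer's
disease biomarker cohorts, with the downstream statistics linking
episodic-memory fMRI activity to disease stage.

## The problem

Alzheimer's disease unfolds over roughly two decades, but any single cohort
observes each participant for only a few years.  Placing everyone on a
common **latent disease-time axis** turns many short, staggered biomarker
series into one long picture of the pathological cascade: CSF amyloid and
pTau become abnormal first, then medial-temporal volumes, then
episodic-memory network function, and finally cognitive test scores.

`cascade-dpm` implements the full analysis chain for this problem:

1. **Progression model.**  Oriented (higher = more pathological, z-scored)
   biomarkers `y_b` of subject *j* at within-subject time τ follow

   `y_b(τ) = f_b(τ + d_j) + ν_jb + ε,  ε ~ N(0, σ_b²)`

   where each `f_b` is a smooth *monotonically increasing* trajectory shared
   by all subjects, `d_j` is the subject's time-shift onto the latent axis,
   `ν_jb` a random intercept.  Curves use an integrated-spline basis with
   softplus-positive weights (a finite-rank monotone surrogate for a
   monotone Gaussian process), fitted by MAP with a Laplace approximation;
   shifts by exhaustive 1-D grid search; the two alternate to convergence.
2. **Staging.**  A subject's disease stage is the minimizer of their
   Gaussian negative log-likelihood over candidate latent times, given any
   subset of their data; stages are anchored to the median of a reference
   subgroup (amyloid-positive cognitively normal controls) and residualized
   for age, sex and education.
3. **Cascade ordering.**  Trajectories are sampled from the model posterior,
   differentiated, and the argmax of the derivative — the *timepoint of
   fastest change* — ordered across biomarkers.
4. **Task metrics.**  The recognition-memory sensitivity index
   `A′ = ∫ H(FA) dFA` (0.5 = chance), the arcsine confidence modulator
   `arcsin((x−3)/2)·2/π`, and AT classification (A+: Aβ42/40 ≤ 0.08;
   T+: pTau181 ≥ 73.65).
5. **Association statistics.**  Semi-partial correlations, ANCOVA with Holm
   post-hocs, parallel mediation with Sobel z, subject-clustered
   sandwich-estimator marginal models with wild-bootstrap family-wise-error
   control, random-intercept mixed models with a time × stage interaction,
   and slope–slope correlations.
6. **Synthetic cohorts.**  A generator with known ground truth (latent
   stages, sigmoidal trajectories ordered as the cascade above, realistic
   missingness and visit schedules) so the whole chain is testable without
   access-restricted clinical data.

## Worked example

```python
import cascade_dpm as cd

config = cd.make_default_config()
cohort, truth = cd.generate_cohort(config, n_subjects=60, seed=1)

model = cd.DiseaseProgressionModel.from_cohort(
    cohort, config.biomarkers, biomarkers=config.dpm_biomarkers)
results = model.fit(seed=1)
print(results.summary())
```

```
Disease progression model fit
==================================
biomarkers: 7   subjects: 60   converged: True (217 outer iterations)

biomarker               noise_sd     ri_sd  total_sd
abeta42_40                 0.235     0.151     0.279
adas_cog13                 0.275     0.269     0.385
entorhinal_volume          0.233     0.188     0.299
fmri_deactivation          0.242     0.207     0.318
hippocampal_volume         0.197     0.142     0.243
pacc5                      0.275     0.218     0.351
ptau181                    0.230     0.161     0.281

time-shifts (years): mean +0.000  sd 5.809  range [-12.75, 10.95]
```

The per-biomarker scales are in oriented z-units; the time-shifts place
each subject on the latent axis (about two decades wide here).  Against the
generator's ground truth the shifts rank-correlate with the true baseline
stages at Spearman ρ = 0.992, and the sampled fastest-change times reproduce
the generating cascade order (CSF → volumes → fMRI deactivation →
cognition):

```python
fc = cd.fastest_change_timepoints(results, n_samples=200, seed=1)
for b, r in sorted(fc.items(), key=lambda kv: kv[1].median):
    print(f"{b:<22} median {r.median:6.2f} yr  IQR ({r.iqr[0]:.2f}, {r.iqr[1]:.2f})")
```

```
abeta42_40             median  -3.40 yr  IQR (-3.70, -3.30)
ptau181                median  -2.85 yr  IQR (-3.10, -2.70)
entorhinal_volume      median   1.85 yr  IQR (1.69, 2.05)
hippocampal_volume     median   2.25 yr  IQR (-12.75, 2.55)
fmri_deactivation      median   4.30 yr  IQR (3.80, 4.90)
pacc5                  median   7.90 yr  IQR (7.75, 8.20)
adas_cog13             median   8.45 yr  IQR (8.40, 8.60)
```

(The latent origin is arbitrary — shifts are recentred to mean zero — so
only differences and the ordering are meaningful.)

The full synthetic study, from simulation to report, is one call (or
`cascade-dpm run --seed 1 --n 200 --out run/` on the command line):

```python
manifest = cd.run_full_pipeline(n_subjects=200, seed=1, out_dir="run")
```

which writes the cohort, fitted model, stage table, fastest-change table,
activity-spline nonlinearity tests, the downstream statistics tables and a
markdown report with figures.

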