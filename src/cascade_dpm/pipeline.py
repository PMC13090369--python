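"""End-to-end orchestration of the synthetic cascade study.

simulate -> orient -> fit -> stage -> cascade & activity trajectories ->
downstream statistics -> report, with per-stage seeds derived from one master
seed, structured logging and a run manifest that makes a run reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig, make_default_config
from .simulate import generate_cohort
from .dpm import DiseaseProgressionModel, FitError
from .staging import (anchor_stages, residualize_stages, stage_cohort,
                      stage_slopes)
from .trajectories import (fastest_change_table, fastest_change_timepoints,
                           fit_activity_spline, nonlinearity_test,
                           spline_derivative)
from .assoc_stats import (fit_marginal_swe, holm_adjust, lme_time_by_stage,
                          semipartial_corr, slope_change_corr,
                          wild_bootstrap_fwe)

__all__ = ["RunManifest", "run_full_pipeline", "make_report", "PipelineError"]

logger = logging.getLogger(__name__)

STAGE_SEED_OFFSETS = {
    "simulate": 0, "fit": 1000, "stage": 2000, "trajectories": 3000,
    "analyze": 4000, "report": 5000,
}

ACTIVITY_REGIONS = ["fmri_activation", "fmri_deactivation"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    """Provenance of one pipeline run (hashes, seeds, outputs)."""

    config_hash: str
    master_seed: int
    stage_seeds: dict[str, int]
    software_version: str
    outputs: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1,
                                         sort_keys=True))


def _config_hash(config: SimulationConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _reference_mask(labels: pd.DataFrame) -> tuple[pd.Series, str]:
    """Anchoring reference: amyloid-positive tau-negative controls (CN A+T-),
    with logged fallbacks to all A+ controls, then all controls."""
    cn = labels["diagnostic_group"] == "CN"
    for name, mask in [
        ("CN A+T-", cn & (labels["at_group"] == "A+T-")),
        ("CN A+", cn & labels["at_group"].isin(["A+T-", "A+T+"])),
        ("CN", cn),
    ]:
        if mask.any():
            if name != "CN A+T-":
                logger.warning("anchoring reference fell back to %s", name)
            return mask, name
    raise PipelineError("staging: no control subjects to anchor on")


def run_full_pipeline(config: SimulationConfig | None = None,
                      n_subjects: int = 200, seed: int = 1,
                      out_dir: str | Path = "cascade_run",
                      n_boot: int = 1000,
                      n_fastest_samples: int = 200,
                      make_figures: bool = True) -> RunManifest:
    """Run every stage of the synthetic study and write the result bundle.

    Fails fast: the first stage error aborts the run with a
    :class:`PipelineError` naming the stage.  Given identical inputs the
    numerical outputs (all CSV/JSON artifacts) are identical.
    """
    config = config or make_default_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {k: seed + off for k, off in STAGE_SEED_OFFSETS.items()}
    manifest = RunManifest(_config_hash(config), seed, seeds, __version__)

    def stamp(stage):
        manifest.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    # -- simulate ------------------------------------------------------------
    try:
        config.validate()
        cohort, truth = generate_cohort(config, n_subjects, seeds["simulate"])
        cohort.save(out / "cohort")
        truth.save(out / "cohort" / "ground_truth.json")
        config.save(out / "config.yaml")
    except Exception as e:
        raise PipelineError(f"simulate: {e}") from e
    stamp("simulate")
    logger.info("simulate: %d subjects, %d observations", n_subjects,
                len(cohort.observations))

    # -- fit -----------------------------------------------------------------
    try:
        model = DiseaseProgressionModel.from_cohort(
            cohort, config.biomarkers, biomarkers=config.dpm_biomarkers)
        fit = model.fit(seed=seeds["fit"])
        fit.save(out / "dpm_fit.json")
    except FitError as e:
        raise PipelineError(f"fit: {e}") from e
    stamp("fit")
    logger.info("fit: converged=%s in %d iterations", fit.converged,
                len(fit.convergence_log))

    # -- stage ---------------------------------------------------------------
    try:
        stages = stage_cohort(fit, cohort)
        labels = cohort.labels.set_index("subject_id") \
            .loc[stages["subject_id"]].reset_index()
        ref_mask, ref_name = _reference_mask(labels)
        stages = anchor_stages(stages, ref_mask.to_numpy())
        stages = residualize_stages(stages, cohort.covariates)
        stages.to_csv(out / "stages.csv", index=False)
    except Exception as e:
        raise PipelineError(f"stage: {e}") from e
    stamp("stage")

    # -- trajectories --------------------------------------------------------
    try:
        fc = fastest_change_timepoints(fit, n_samples=n_fastest_samples,
                                       seed=seeds["trajectories"])
        fc_table = fastest_change_table(fc)
        fc_table.to_csv(out / "fastest_change.csv", index=False)
        # stage-resolved activity curves (baseline visit, oriented)
        activity = _baseline_activity_table(cohort, fit, stages)
        spline_rows = []
        for region in ACTIVITY_REGIONS:
            sub = activity.dropna(subset=[region])
            if len(sub) < 10:
                logger.warning("trajectories: too few %s values; skipped",
                               region)
                continue
            cov = sub[["age_at_baseline"]].to_numpy(float)
            nl = nonlinearity_test(sub["stage_adjusted"], sub[region],
                                   covariates=cov)
            spline_rows.append((region, nl.f_stat, nl.df1, nl.df2,
                                nl.p_value, nl.edf_smooth,
                                nl.has_nonlinear_component))
        nl_table = pd.DataFrame(spline_rows, columns=[
            "region", "f_nonlinear", "df1", "df2", "p_raw", "edf",
            "has_nonlinear_component"])
        if len(nl_table):
            nl_table["p_holm"] = holm_adjust(nl_table["p_raw"].to_numpy())
        nl_table.to_csv(out / "nonlinearity.csv", index=False)
    except Exception as e:
        raise PipelineError(f"trajectories: {e}") from e
    stamp("trajectories")

    # -- analyze -------------------------------------------------------------
    try:
        analysis = _downstream_stats(cohort, fit, stages, n_boot,
                                     seeds["analyze"])
        for name, table in analysis.items():
            table.to_csv(out / f"{name}.csv", index=False)
    except Exception as e:
        raise PipelineError(f"analyze: {e}") from e
    stamp("analyze")

    # -- report --------------------------------------------------------------
    bundle = {
        "out": out, "cohort": cohort, "fit": fit, "stages": stages,
        "fastest_change": fc_table, "nonlinearity": nl_table,
        "analysis": analysis, "reference": ref_name,
    }
    try:
        make_report(bundle, figures=make_figures)
    except Exception as e:
        raise PipelineError(f"report: {e}") from e
    stamp("report")

    manifest.outputs = {p.name: str(p) for p in sorted(out.glob("*"))}
    manifest.save(out / "manifest.json")
    return manifest


def _baseline_activity_table(cohort, fit, stages) -> pd.DataFrame:
    """One row per subject: baseline oriented activity + stage + demographics."""
    obs = fit.orientation.apply(cohort.observations)
    base = obs[obs["visit_index"] == 0]
    wide = base.pivot_table(index="subject_id", columns="biomarker_name",
                            values="value", aggfunc="first")
    covs = cohort.covariates.set_index("subject_id")
    table = wide.join(covs).join(
        stages.set_index("subject_id")[["stage_adjusted", "stage_anchored"]])
    return table.reset_index()


def _longitudinal_activity_table(cohort, fit, stages) -> pd.DataFrame:
    """Long table of oriented activity visits joined with stage/demographics."""
    obs = fit.orientation.apply(cohort.observations)
    act = obs[obs["biomarker_name"].isin(ACTIVITY_REGIONS)]
    wide = act.pivot_table(
        index=["subject_id", "visit_index", "time_years_from_baseline"],
        columns="biomarker_name", values="value", aggfunc="first"
    ).reset_index()
    covs = cohort.covariates.set_index("subject_id")
    st = stages.set_index("subject_id")[["stage_adjusted"]]
    return wide.join(covs, on="subject_id").join(st, on="subject_id")


def _downstream_stats(cohort, fit, stages, n_boot, seed) -> dict:
    out: dict[str, pd.DataFrame] = {}
    base = _baseline_activity_table(cohort, fit, stages)

    # semi-partial correlations: volumes vs activity controlling CSF+demog,
    # cognition vs activity controlling volumes+demog
    demog = base[["age_at_baseline", "sex", "education"]].to_numpy(float)
    rows = []
    pairs = [
        ("hippocampal_volume", ["abeta42_40", "ptau181"]),
        ("entorhinal_volume", ["abeta42_40", "ptau181"]),
        ("pacc5", ["hippocampal_volume", "entorhinal_volume"]),
        ("adas_cog13", ["hippocampal_volume", "entorhinal_volume"]),
    ]
    for region in ACTIVITY_REGIONS:
        for marker, controls in pairs:
            cols = [marker, region] + controls
            sub = base.dropna(subset=cols)
            d = sub[["age_at_baseline", "sex", "education"]].to_numpy(float)
            r = semipartial_corr(sub[region].to_numpy(float),
                                 sub[marker].to_numpy(float),
                                 sub[controls].to_numpy(float), d)
            rows.append((region, marker, ",".join(controls), r.r, r.ci_low,
                         r.ci_high, r.p_value, r.n))
    out["semipartial"] = pd.DataFrame(rows, columns=[
        "region", "biomarker", "controls", "r", "ci_low", "ci_high", "p", "n"])

    # marginal SwE model + wild bootstrap on the longitudinal activity
    long = _longitudinal_activity_table(cohort, fit, stages).dropna(
        subset=ACTIVITY_REGIONS + ["stage_adjusted"])
    swe = fit_marginal_swe(long, ACTIVITY_REGIONS)
    wb_rows = []
    for contrast in ("stage", "stage_sq"):
        wb = wild_bootstrap_fwe(swe, contrast, n_boot=n_boot, seed=seed)
        wb.insert(0, "contrast", contrast)
        wb_rows.append(wb)
    out["swe_wild_bootstrap"] = pd.concat(wb_rows, ignore_index=True)

    # random-intercept LME: time x stage
    out["lme_interaction"] = lme_time_by_stage(long, ACTIVITY_REGIONS)

    # slope-slope correlation
    st_slopes = stage_slopes(fit, cohort)
    slope_rows = []
    for region in ACTIVITY_REGIONS:
        act = long.dropna(subset=[region])
        slopes = {}
        for sid, sub in act.groupby("subject_id"):
            if sub["time_years_from_baseline"].nunique() < 2:
                continue
            slopes[sid] = float(np.polyfit(
                sub["time_years_from_baseline"], sub[region], 1)[0])
        sc = slope_change_corr(st_slopes, pd.Series(slopes))
        slope_rows.append((region, sc.r, sc.p_value, sc.n))
    out["slope_correlations"] = pd.DataFrame(
        slope_rows, columns=["region", "r", "p", "n"])
    return out


def make_report(bundle: dict, figures: bool = True) -> Path:
    """Write the human-readable report (markdown tables + figures).

    The early/late grouping in the interaction figure splits at the sample
    median of the adjusted disease stage.  Regeneration from the same bundle
    is byte-stable for the tables.
    """
    required = {"out", "fit", "stages", "fastest_change", "analysis"}
    missing = required - set(bundle)
    if missing:
        raise ValueError(f"incomplete bundle; missing {sorted(missing)}")
    out = Path(bundle["out"])
    stages = bundle["stages"]
    fc = bundle["fastest_change"]
    lines = ["# Cascade progression report", ""]
    lines += ["## Fastest-change ordering (earliest first)", "",
              fc.to_markdown(index=False), ""]
    lines += ["## Disease stages", "",
              f"- subjects staged: {len(stages)}",
              f"- anchored median (reference {bundle.get('reference', '?')}):"
              f" {stages['stage_anchored'].median():.3f}",
              f"- adjusted stage range: [{stages['stage_adjusted'].min():.2f},"
              f" {stages['stage_adjusted'].max():.2f}]", ""]
    median_split = float(stages["stage_adjusted"].median())
    lines += [f"- early/late split at median adjusted stage: "
              f"{median_split:.3f}", ""]
    if "nonlinearity" in bundle and len(bundle["nonlinearity"]):
        lines += ["## Non-linearity of activity trajectories", "",
                  bundle["nonlinearity"].to_markdown(index=False), ""]
    for name, table in bundle["analysis"].items():
        lines += [f"## {name}", "", table.to_markdown(index=False), ""]
    (out / "report.md").write_text("\n".join(lines))

    if figures:
        _report_figures(bundle, median_split)
    return out / "report.md"


def _report_figures(bundle, median_split: float) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(bundle["out"])
    fit = bundle["fit"]
    # progression curves
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for b in fit.trajectories:
        pred = fit.predict_trajectory(b)
        ax.plot(pred["grid"], pred["mean"], label=b)
        ax.fill_between(pred["grid"], pred["lower"], pred["upper"], alpha=0.15)
    ax.set_xlabel("disease time (years)")
    ax.set_ylabel("oriented abnormality (z)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "progression_curves.png", dpi=120)
    plt.close(fig)

    # fastest-change box summary
    fc = bundle["fastest_change"]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.errorbar(fc["median_years"], range(len(fc)),
                xerr=[fc["median_years"] - fc["q1"],
                      fc["q3"] - fc["median_years"]],
                fmt="o", capsize=3)
    ax.set_yticks(range(len(fc)), fc["biomarker"])
    ax.set_xlabel("timepoint of fastest change (years)")
    fig.tight_layout()
    fig.savefig(out / "fastest_change.png", dpi=120)
    plt.close(fig)

    # early/late interaction visualization on deactivation, if available
    stages = bundle["stages"]
    cohort = bundle.get("cohort")
    if cohort is None:
        return
    long = _longitudinal_activity_table(cohort, fit, stages)
    if "fmri_deactivation" not in long or \
            long["fmri_deactivation"].dropna().empty:
        logger.info("report: no activity values; interaction figure skipped")
        return
    long["group"] = np.where(long["stage_adjusted"] < median_split,
                             "early", "late")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for gname, sub in long.groupby("group"):
        agg = sub.groupby("time_years_from_baseline")["fmri_deactivation"] \
            .agg(["mean", "sem"])
        ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], label=gname,
                    capsize=3)
    ax.set_xlabel("time from baseline (years)")
    ax.set_ylabel("oriented deactivation (z)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "interaction_deactivation.png", dpi=120)
    plt.close(fig)
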