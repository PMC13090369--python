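"""Simulation configuration: biomarker specs, group stage distributions, schedules.

The default configuration encodes the study conditions of an
Alzheimer's-cascade cohort: seven disease-progression-model (DPM) biomarkers
(CSF Abeta42/40 and pTau181, entorhinal and hippocampal volume, episodic-memory
fMRI deactivation, PACC5 and ADAS-COG-13) plus an fMRI activation readout that
stays out of the DPM and is analysed downstream.  Each biomarker follows a
four-parameter logistic abnormality trajectory on a latent disease-time axis
spanning roughly two decades, with ground-truth midpoints ordered
CSF -> volumes -> fMRI deactivation -> cognition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = [
    "BiomarkerSpec",
    "GroupSpec",
    "SimulationConfig",
    "ConfigError",
    "make_default_config",
]

FAMILIES = ("csf", "volume", "cognition", "fmri_activation", "fmri_deactivation")


class ConfigError(ValueError):
    """A simulation configuration field is invalid; the message names it."""


@dataclass
class BiomarkerSpec:
    """Generating model of one biomarker.

    The oriented abnormality curve is the logistic
    ``g(t) = amplitude / (1 + exp(-sigmoid_slope * (t - sigmoid_midpoint)))``
    on the latent disease-time axis (years); the native-scale value is
    ``baseline_level + raw_direction * g(t)`` plus a subject random intercept
    and Gaussian observation noise.  ``raw_direction`` is the sign of change
    with disease on the native scale (-1 for Abeta42/40, volumes, PACC5 and
    fMRI activation magnitude; +1 for pTau181, ADAS-COG-13 and loss of
    deactivation).
    """

    name: str
    family: str
    raw_direction: int
    sigmoid_midpoint: float  # years on the latent axis
    sigmoid_slope: float  # 1 / years
    amplitude: float  # native units
    baseline_level: float  # native units, healthy asymptote
    noise_sd: float  # native units
    random_intercept_sd: float  # native units
    missing_rate: float  # probability per scheduled follow-up visit

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"biomarker {self.name}: unknown family {self.family!r}")
        if self.raw_direction not in (-1, 1):
            raise ConfigError(f"biomarker {self.name}: raw_direction must be -1 or +1")
        if not self.sigmoid_slope > 0:
            raise ConfigError(f"biomarker {self.name}: sigmoid_slope must be > 0")
        if self.amplitude <= 0:
            raise ConfigError(f"biomarker {self.name}: amplitude must be > 0")
        if self.noise_sd < 0:
            raise ConfigError(f"biomarker {self.name}: noise_sd must be >= 0")
        if self.random_intercept_sd < 0:
            raise ConfigError(
                f"biomarker {self.name}: random_intercept_sd must be >= 0"
            )
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError(f"biomarker {self.name}: missing_rate must be in [0,1]")

    def oriented_curve(self, t):
        """Noise-free oriented abnormality g(t) (native amplitude units)."""
        import numpy as np

        z = self.sigmoid_slope * (np.asarray(t, dtype=float) - self.sigmoid_midpoint)
        return self.amplitude / (1.0 + np.exp(-z))

    def native_curve(self, t):
        """Noise-free native-scale trajectory at latent time t."""
        return self.baseline_level + self.raw_direction * self.oriented_curve(t)


@dataclass
class GroupSpec:
    """Latent baseline-stage distribution of one diagnostic group (Gaussian)."""

    stage_mean: float  # years on the latent axis
    stage_sd: float
    proportion: float

    def validate(self, name: str) -> None:
        if self.stage_sd <= 0:
            raise ConfigError(f"group {name}: stage_sd must be > 0")
        if not 0 < self.proportion <= 1:
            raise ConfigError(f"group {name}: proportion must be in (0,1]")


@dataclass
class SimulationConfig:
    """Full description of the synthetic cohort generator."""

    biomarkers: list[BiomarkerSpec]
    groups: dict[str, GroupSpec]
    #: visit indices (years from baseline) at which each modality is scheduled
    schedules: dict[str, list[int]]
    #: biomarkers entering the disease progression model fit
    dpm_biomarkers: list[str]
    age_intercept: float = 70.0
    age_stage_coef: float = 0.5  # years of age per latent year
    age_noise_sd: float = 4.0
    education_mean: float = 14.0
    education_sd: float = 3.0
    n_sites: int = 8

    def validate(self) -> None:
        if not self.biomarkers:
            raise ConfigError("biomarkers: must not be empty")
        names = [b.name for b in self.biomarkers]
        if len(set(names)) != len(names):
            raise ConfigError("biomarkers: duplicate names")
        for b in self.biomarkers:
            b.validate()
        if not self.groups:
            raise ConfigError("groups: must not be empty")
        for g, spec in self.groups.items():
            spec.validate(g)
        total = sum(g.proportion for g in self.groups.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigError(f"groups: proportions must sum to 1 (got {total})")
        for fam in {b.family for b in self.biomarkers}:
            if fam not in self.schedules:
                raise ConfigError(f"schedules: missing schedule for family {fam!r}")
        for fam, visits in self.schedules.items():
            if not visits or sorted(visits) != list(visits) or visits[0] != 0:
                raise ConfigError(
                    f"schedules[{fam!r}]: visits must start at 0 and be increasing"
                )
        for name in self.dpm_biomarkers:
            if name not in names:
                raise ConfigError(f"dpm_biomarkers: unknown biomarker {name!r}")
        if self.age_noise_sd < 0 or self.education_sd < 0:
            raise ConfigError("age_noise_sd/education_sd must be >= 0")
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")

    def spec(self, name: str) -> BiomarkerSpec:
        for b in self.biomarkers:
            if b.name == name:
                return b
        raise KeyError(name)

    # ---- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = {k: asdict(v) for k, v in self.groups.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["biomarkers"] = [BiomarkerSpec(**b) for b in d["biomarkers"]]
        d["groups"] = {k: GroupSpec(**v) for k, v in d["groups"].items()}
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def make_default_config() -> SimulationConfig:
    """Default synthetic-cohort configuration.

    Ground-truth logistic midpoints are placed at the cascade ordering
    CSF (1.17, 2.79) -> volumes (4.09 entorhinal, 5.38 hippocampal) ->
    fMRI deactivation (6.36) -> cognition (8.95 PACC5, 10.57 ADAS-COG-13)
    years on the latent axis; fMRI activation sits at 7.5 years and is not a
    DPM biomarker.  Observation noise and random-intercept scales are ~8% of
    each trajectory's amplitude so oriented z-scored ranges are roughly
    [0, 1].  Group baseline-stage Gaussians are ordered CN < SCD < MCI < DAT
    with proportions echoing a memory-clinic cohort.
    """
    bm = [
        BiomarkerSpec("abeta42_40", "csf", -1, 1.17, 0.50, 0.050, 0.105,
                      0.004, 0.004, 0.30),
        BiomarkerSpec("ptau181", "csf", +1, 2.79, 0.50, 60.0, 45.0,
                      5.0, 5.0, 0.30),
        BiomarkerSpec("entorhinal_volume", "volume", -1, 4.09, 0.60, 2.0, 0.7,
                      0.16, 0.16, 0.10),
        BiomarkerSpec("hippocampal_volume", "volume", -1, 5.38, 0.60, 2.2, 0.8,
                      0.18, 0.18, 0.10),
        BiomarkerSpec("fmri_deactivation", "fmri_deactivation", +1, 6.36, 0.60,
                      1.0, -1.0, 0.09, 0.09, 0.15),
        BiomarkerSpec("fmri_activation", "fmri_activation", -1, 7.50, 0.60,
                      1.0, 1.1, 0.09, 0.09, 0.15),
        BiomarkerSpec("pacc5", "cognition", -1, 8.95, 0.55, 3.5, 0.5,
                      0.28, 0.28, 0.05),
        BiomarkerSpec("adas_cog13", "cognition", +1, 10.57, 0.55, 22.0, 7.0,
                      1.8, 1.8, 0.05),
    ]
    groups = {
        "CN": GroupSpec(-2.0, 3.0, 80 / 208),
        "SCD": GroupSpec(3.0, 3.0, 57 / 208),
        "MCI": GroupSpec(7.0, 3.0, 44 / 208),
        "DAT": GroupSpec(11.0, 2.5, 27 / 208),
    }
    schedules = {
        "csf": [0, 2, 4],
        "volume": [0, 1, 2, 3, 4],
        "cognition": [0, 1, 2, 3, 4],
        "fmri_activation": [0, 1, 2, 3],
        "fmri_deactivation": [0, 1, 2, 3],
    }
    dpm = ["abeta42_40", "ptau181", "entorhinal_volume", "hippocampal_volume",
           "fmri_deactivation", "pacc5", "adas_cog13"]
    cfg = SimulationConfig(bm, groups, schedules, dpm)
    cfg.validate()
    return cfg
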