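"""Behavioural and biomarker-classification primitives.

Three small, exactly specified building blocks used throughout the pipeline:

* :func:`a_prime` — the non-parametric recognition-memory sensitivity index
  A' (area under the cumulative hits-versus-false-alarms curve), computed from
  5-point confidence ratings of an old/new recognition test.  0.5 is chance,
  1.0 is perfect discrimination.
* :func:`arcsine_modulator` — the arcsine transform of a confidence rating
  used as a parametric modulator of encoding-related BOLD responses,
  ``arcsin((x - 3) / 2) * 2 / pi`` mapping ratings 1..5 onto [-1, 1].
* :func:`classify_at` — amyloid/tau (AT) positivity from CSF biomarkers with
  the cohort-specific Gaussian-mixture cutoffs: A+ iff Abeta42/40 <= 0.08,
  T+ iff pTau181 >= 73.65 (both boundaries inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ABETA_RATIO_CUTOFF",
    "PTAU181_CUTOFF",
    "ATLabel",
    "RecognitionSummary",
    "a_prime",
    "arcsine_modulator",
    "classify_at",
    "classify_at_frame",
]

#: A+ iff the CSF Abeta42/40 ratio is at or below this value.
ABETA_RATIO_CUTOFF = 0.08
#: T+ iff CSF pTau181 (pg/ml) is at or above this value.
PTAU181_CUTOFF = 73.65


@dataclass(frozen=True)
class RecognitionSummary:
    """Criterion-wise ROC points and the A' area for one responder.

    ``hit_rates``/``fa_rates`` are cumulative over the five confidence
    criteria swept from "sure novel" (rating 5) down to rating 1, with the
    (0, 0) origin prepended; both end at 1.
    """

    hit_rates: np.ndarray
    fa_rates: np.ndarray
    a_prime: float
    n_novel: int
    n_familiar: int

    def as_frame(self) -> pd.DataFrame:
        crit = ["origin", ">=5", ">=4", ">=3", ">=2", ">=1"]
        return pd.DataFrame(
            {"criterion": crit, "hit_rate": self.hit_rates, "fa_rate": self.fa_rates}
        )


@dataclass(frozen=True)
class ATLabel:
    """AT biomarker classification of a single participant.

    ``continuum_flag`` is False for profiles outside the Alzheimer's
    continuum (A-T+); missing inputs yield the 'indeterminate' label rather
    than a silent negative call.
    """

    amyloid: str | None
    tau: str | None
    label: str = field(init=False)
    continuum_flag: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.amyloid is None or self.tau is None:
            object.__setattr__(self, "label", "indeterminate")
            object.__setattr__(self, "continuum_flag", False)
        else:
            object.__setattr__(self, "label", f"{self.amyloid}{self.tau}")
            object.__setattr__(self, "continuum_flag", self.label != "A-T+")


def a_prime(trials: pd.DataFrame) -> RecognitionSummary:
    """Compute A', the area under the cumulative H(FA) recognition ROC.

    Parameters
    ----------
    trials
        Table with boolean column ``is_novel`` (ground-truth old/new status)
        and integer column ``confidence_rating`` in 1..5, where 5 means
        "sure novel".  The criterion sweep therefore runs from rating 5 down
        to rating 1; at each criterion c the hit rate is
        P(rating >= c | novel) and the false-alarm rate is
        P(rating >= c | familiar).

    Returns
    -------
    RecognitionSummary
        ROC points including the (0, 0) origin and the trapezoidal area.
        When the two empirical rating distributions coincide the ROC lies on
        the diagonal and A' is exactly 0.5; the trapezoidal construction is
        algebraically identical to the Mann-Whitney pair count with
        half-credit for rating ties.
    """
    ratings = np.asarray(trials["confidence_rating"], dtype=int)
    novel = np.asarray(trials["is_novel"], dtype=bool)
    if ratings.size == 0:
        raise ValueError("empty trial table")
    if not np.all((ratings >= 1) & (ratings <= 5)):
        raise ValueError("confidence ratings must lie in 1..5")
    n_novel = int(novel.sum())
    n_familiar = int((~novel).sum())
    if n_novel == 0 or n_familiar == 0:
        raise ValueError(
            "A' needs at least one novel and one familiar trial "
            f"(got {n_novel} novel, {n_familiar} familiar)"
        )
    criteria = np.array([5, 4, 3, 2, 1])
    hits = np.array([(ratings[novel] >= c).mean() for c in criteria])
    fas = np.array([(ratings[~novel] >= c).mean() for c in criteria])
    h = np.concatenate([[0.0], hits])
    fa = np.concatenate([[0.0], fas])
    area = float(np.trapezoid(h, fa))
    return RecognitionSummary(h, fa, area, n_novel, n_familiar)


def arcsine_modulator(rating):
    """Arcsine parametric modulator ``arcsin((x - 3) / 2) * 2 / pi``.

    Maps confidence ratings 1..5 to [-1, 1] with the closed-form values
    m(1) = -1, m(2) = -1/3, m(3) = 0, m(4) = 1/3, m(5) = 1.  Accepts a
    scalar or an array; out-of-range or non-integer ratings raise.
    """
    x = np.asarray(rating)
    if not np.issubdtype(x.dtype, np.integer):
        if not np.all(np.equal(np.mod(x, 1), 0)):
            raise ValueError("ratings must be integers in 1..5")
        x = x.astype(int)
    if np.any((x < 1) | (x > 5)):
        raise ValueError("ratings must lie in 1..5")
    out = np.arcsin((x - 3) / 2.0) * (2.0 / math.pi)
    if np.isscalar(rating) or np.ndim(rating) == 0:
        return float(out)
    return out


def classify_at(abeta_ratio: float, ptau181: float) -> ATLabel:
    """AT classification from CSF Abeta42/40 and pTau181.

    Cutoffs are inclusive exactly as printed: A+ iff ratio <= 0.08 and
    T+ iff pTau181 >= 73.65.  A non-finite input makes the corresponding
    axis indeterminate.
    """
    amyloid = tau = None
    if abeta_ratio is not None and np.isfinite(abeta_ratio):
        if abeta_ratio <= 0:
            raise ValueError("Abeta42/40 ratio must be positive")
        amyloid = "A+" if abeta_ratio <= ABETA_RATIO_CUTOFF else "A-"
    if ptau181 is not None and np.isfinite(ptau181):
        if ptau181 <= 0:
            raise ValueError("pTau181 must be positive")
        tau = "T+" if ptau181 >= PTAU181_CUTOFF else "T-"
    return ATLabel(amyloid, tau)


def classify_at_frame(abeta: pd.Series, ptau: pd.Series) -> pd.Series:
    """Vectorized :func:`classify_at` returning the combined label strings."""
    out = []
    for a, p in zip(abeta, ptau):
        a = np.nan if a is None else a
        p = np.nan if p is None else p
        out.append(classify_at(a if np.isfinite(a) else np.nan,
                               p if np.isfinite(p) else np.nan).label)
    return pd.Series(out, index=abeta.index)
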