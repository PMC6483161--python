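"""Closed-form confusion-matrix algebra for risk-stratified screening.

A screening scenario is fully determined by three numbers: the population
prevalence ``p`` of the condition, the fraction ``t`` of the population
called positive (the *target fraction*, e.g. everyone above a chosen PRS
percentile), and one discrimination parameter. The discrimination parameter
may be supplied in any of three equivalent currencies:

* **sensitivity** ``s`` — the fraction of all eventual cases inside the target;
* **relative risk** ``RR`` — prevalence inside the target divided by
  prevalence in the untargeted remainder, ``RR = [s·p/t] / [(1−s)·p/(1−t)]``
  (prevalence cancels, so RR pins down ``s`` given ``t`` alone);
* **PPV** (precision) — prevalence inside the target, ``PPV = s·p/t``.

Everything downstream (NPV, accuracy, specificity, prevention fractions,
NNT) is elementary algebra on the 2x2 table these three numbers induce.
All quantities are plain fractions in [0, 1]; conversion to the integer
percents used in printed tables happens only at output time via
:func:`round_percent`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .errors import DegenerateScenarioError, DomainError, InfeasibleScenarioError

__all__ = [
    "CohortScenario",
    "ConfusionFractions",
    "ClassificationSummary",
    "sensitivity_from_relative_risk",
    "sensitivity_from_ppv",
    "relative_risk_from_sensitivity",
    "confusion_from_scenario",
    "summarize",
    "round_percent",
    "round_half_away",
]

DiscriminationKind = Literal["sensitivity", "relative_risk", "ppv"]


def _check_fraction(name: str, x: float, *, closed_right: bool = False) -> None:
    hi_ok = x <= 1.0 if closed_right else x < 1.0
    if not (0.0 < x and hi_ok and math.isfinite(x)):
        rng = "(0, 1]" if closed_right else "(0, 1)"
        raise DomainError(f"{name} must be in {rng}, got {x!r}")


def sensitivity_from_relative_risk(relative_risk: float, target_fraction: float) -> float:
    """Sensitivity implied by a remainder-referenced relative risk.

    Solving ``RR = [s/t] / [(1−s)/(1−t)]`` for ``s`` gives

        s = RR·t / (1 − t + RR·t)

    independent of prevalence. ``RR = 1`` returns ``s = t`` (chance level).

    Parameters
    ----------
    relative_risk
        Target-group prevalence over remainder-group prevalence; > 0.
    target_fraction
        Fraction of the population called positive, in (0, 1).
    """
    if not (relative_risk > 0 and math.isfinite(relative_risk)):
        raise DomainError(f"relative_risk must be positive, got {relative_risk!r}")
    _check_fraction("target_fraction", target_fraction)
    rr_t = relative_risk * target_fraction
    return rr_t / (1.0 - target_fraction + rr_t)


def sensitivity_from_ppv(ppv: float, prevalence: float, target_fraction: float) -> float:
    """Sensitivity implied by a precision goal: ``s = PPV·t / p``.

    Raises
    ------
    InfeasibleScenarioError
        If ``PPV·t > p``: the target would have to contain more cases than
        exist in the whole population.
    """
    _check_fraction("ppv", ppv, closed_right=True)
    _check_fraction("prevalence", prevalence)
    _check_fraction("target_fraction", target_fraction)
    s = ppv * target_fraction / prevalence
    if s > 1.0 + 1e-15:
        raise InfeasibleScenarioError(
            f"PPV {ppv} over target fraction {target_fraction} needs sensitivity "
            f"{s:.4f} > 1 at prevalence {prevalence}"
        )
    return min(s, 1.0)


def relative_risk_from_sensitivity(sensitivity: float, target_fraction: float) -> float:
    """Inverse of :func:`sensitivity_from_relative_risk` (prevalence-free)."""
    _check_fraction("sensitivity", sensitivity, closed_right=True)
    _check_fraction("target_fraction", target_fraction)
    if sensitivity == 1.0:
        return math.inf
    return (sensitivity / target_fraction) / ((1.0 - sensitivity) / (1.0 - target_fraction))


@dataclass(frozen=True)
class CohortScenario:
    """Prevalence, target fraction, and exactly one discrimination parameter.

    Parameters
    ----------
    prevalence
        Fraction of the population affected, in (0, 1).
    target_fraction
        Fraction of the population called positive, in (0, 1).
    discrimination
        The supplied discrimination value.
    kind
        Which currency ``discrimination`` is in: ``"sensitivity"``,
        ``"relative_risk"`` or ``"ppv"``.

    Use the :meth:`from_relative_risk` / :meth:`from_sensitivity` /
    :meth:`from_ppv` constructors rather than the raw initializer.
    """

    prevalence: float
    target_fraction: float
    discrimination: float
    kind: DiscriminationKind

    def __post_init__(self) -> None:
        _check_fraction("prevalence", self.prevalence)
        _check_fraction("target_fraction", self.target_fraction)
        if self.kind not in ("sensitivity", "relative_risk", "ppv"):
            raise DomainError(f"unknown discrimination kind {self.kind!r}")
        # resolving validates the discrimination value and feasibility
        s = self.sensitivity
        p, t = self.prevalence, self.target_fraction
        if s * p > t + 1e-15:
            raise InfeasibleScenarioError(
                f"sensitivity {s:.4f} at prevalence {p} puts more cases in the "
                f"target than its size {t} (PPV would exceed 1)"
            )
        if (1.0 - s) * p > (1.0 - t) + 1e-15:
            raise InfeasibleScenarioError(
                f"sensitivity {s:.4f} at prevalence {p} leaves more missed cases "
                f"than the remainder size {1.0 - t} (NPV would be negative)"
            )

    @classmethod
    def from_relative_risk(cls, prevalence: float, target_fraction: float, relative_risk: float) -> "CohortScenario":
        return cls(prevalence, target_fraction, relative_risk, "relative_risk")

    @classmethod
    def from_sensitivity(cls, prevalence: float, target_fraction: float, sensitivity: float) -> "CohortScenario":
        return cls(prevalence, target_fraction, sensitivity, "sensitivity")

    @classmethod
    def from_ppv(cls, prevalence: float, target_fraction: float, ppv: float) -> "CohortScenario":
        return cls(prevalence, target_fraction, ppv, "ppv")

    @property
    def sensitivity(self) -> float:
        """The scenario's sensitivity, whichever currency it was supplied in."""
        if self.kind == "sensitivity":
            _check_fraction("sensitivity", self.discrimination, closed_right=True)
            return self.discrimination
        if self.kind == "relative_risk":
            return sensitivity_from_relative_risk(self.discrimination, self.target_fraction)
        return sensitivity_from_ppv(self.discrimination, self.prevalence, self.target_fraction)


@dataclass(frozen=True)
class ConfusionFractions:
    """TP/FP/FN/TN as fractions of the whole population (they sum to 1)."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < -1e-12 or not math.isfinite(v):
                raise DomainError(f"{name} must be a non-negative fraction, got {v!r}")
        total = self.tp + self.fp + self.fn + self.tn
        if abs(total - 1.0) > 1e-9:
            raise DomainError(f"confusion fractions must sum to 1, got {total!r}")

    @property
    def prevalence(self) -> float:
        return self.tp + self.fn

    @property
    def target_fraction(self) -> float:
        return self.tp + self.fp


@dataclass(frozen=True)
class ClassificationSummary:
    """All standard screening metrics of one 2x2 table.

    ``relative_risk`` is remainder-referenced: PPV divided by the prevalence
    among the untargeted, i.e. ``ppv / (1 − npv)``.
    """

    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    accuracy: float
    relative_risk: float


def confusion_from_scenario(scenario: CohortScenario) -> ConfusionFractions:
    """Build the population-fraction 2x2 table a scenario induces.

    ``tp = s·p``, ``fn = (1−s)·p``, ``fp = t − tp``, ``tn = 1 − t − fn``.
    """
    s = scenario.sensitivity
    p, t = scenario.prevalence, scenario.target_fraction
    tp = s * p
    fn = (1.0 - s) * p
    fp = t - tp
    tn = 1.0 - t - fn
    if fp < -1e-15 or tn < -1e-15:
        raise InfeasibleScenarioError(
            f"scenario (p={p}, t={t}, s={s:.6f}) yields a negative cell: fp={fp:.3g}, tn={tn:.3g}"
        )
    return ConfusionFractions(tp=tp, fp=max(fp, 0.0), fn=fn, tn=max(tn, 0.0))


def summarize(confusion: ConfusionFractions) -> ClassificationSummary:
    """All classification metrics of a 2x2 table of population fractions."""
    c = confusion
    t = c.tp + c.fp
    nt = c.fn + c.tn
    cases = c.tp + c.fn
    noncases = c.fp + c.tn
    if t <= 0.0 or nt <= 0.0 or cases <= 0.0 or noncases <= 0.0:
        raise DegenerateScenarioError(
            "a margin of the 2x2 table is empty; PPV/NPV/sensitivity/specificity undefined"
        )
    remainder_prevalence = c.fn / nt
    if remainder_prevalence == 0.0:
        rr = math.inf
    else:
        rr = (c.tp / t) / remainder_prevalence
    return ClassificationSummary(
        ppv=c.tp / t,
        npv=c.tn / nt,
        sensitivity=c.tp / cases,
        specificity=c.tn / noncases,
        accuracy=c.tp + c.tn,
        relative_risk=rr,
    )


def round_half_away(x: float) -> int:
    """Nearest integer, halves rounded away from zero (not banker's rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def round_percent(x: float) -> int:
    """Render a fraction as the nearest integer percent, half rounding up.

    Matches the integer rendering of printed screening tables
    (0.9379 -> 94, 0.005 -> 1).
    """
    if x < 0 or not math.isfinite(x):
        raise DomainError(f"round_percent expects a non-negative fraction, got {x!r}")
    return round_half_away(100.0 * x)
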