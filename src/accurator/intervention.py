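"""Prevention fractions and number needed to treat (NNT) for targeted therapy.

Given a screening scenario and a treatment that prevents a fraction ``e_t``
of treated cases inside the target group and ``e_r`` outside it, this module
answers the clinical-utility questions: what fraction of preventable events
does target-only treatment capture, what fraction of *all* events does it
prevent, and how many people must be treated per event prevented — both when
everyone is treated (NNT All) and within the target group (NNT Targeted).

Differential effectiveness (``e_t > e_r``) models the plausible situation
where high-risk patients respond better to therapy; with uniform
effectiveness the captured share of preventable events collapses exactly to
the scenario's sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_metrics import (
    CohortScenario,
    round_half_away,
    sensitivity_from_ppv,
)
from .errors import DegenerateScenarioError, DomainError, InfeasibleScenarioError

__all__ = [
    "EffectivenessModel",
    "InterventionOutcome",
    "intervention_outcomes",
    "required_rr_for_precision",
    "two_group_prevention",
]


@dataclass(frozen=True)
class EffectivenessModel:
    """Proportion of treated cases prevented, inside and outside the target.

    ``uniform(e)`` builds the common case where response does not depend on
    risk group.
    """

    effect_target: float
    effect_remainder: float

    def __post_init__(self) -> None:
        for name in ("effect_target", "effect_remainder"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise DomainError(f"{name} must be in [0, 1], got {v!r}")

    @classmethod
    def uniform(cls, effectiveness: float) -> "EffectivenessModel":
        return cls(effectiveness, effectiveness)

    @property
    def is_uniform(self) -> bool:
        return self.effect_target == self.effect_remainder


@dataclass(frozen=True)
class InterventionOutcome:
    """Prevention fractions and NNTs for treating only the target group.

    Attributes
    ----------
    percent_preventable
        Events prevented by target-only treatment as a fraction of events
        prevented if the whole population were treated.
    percent_all_prevented
        Events prevented by target-only treatment as a fraction of all events.
    nnt_all
        Persons treated per event prevented when everyone is treated.
    nnt_targeted
        Persons treated per event prevented within the target group;
        equals ``1 / (PPV · e_t)``.

    NNTs are stored raw; ``nnt_all_rounded`` / ``nnt_targeted_rounded`` give
    the nearest-integer rendering used in printed tables.
    """

    percent_preventable: float
    percent_all_prevented: float
    nnt_all: float
    nnt_targeted: float

    @property
    def nnt_all_rounded(self) -> int:
        return round_half_away(self.nnt_all)

    @property
    def nnt_targeted_rounded(self) -> int:
        return round_half_away(self.nnt_targeted)


def intervention_outcomes(
    scenario: CohortScenario, effectiveness: EffectivenessModel
) -> InterventionOutcome:
    """Prevention fractions and NNTs for a scenario under a treatment model.

    With sensitivity ``s``, prevalence ``p`` and effects ``(e_t, e_r)``:

    * events prevented treating the target only: ``s·p·e_t``
    * events prevented treating everyone: ``p·(s·e_t + (1−s)·e_r)``
      (target cases respond at ``e_t``, remainder cases at ``e_r``)
    * ``NNT All = 1 / [p·(s·e_t + (1−s)·e_r)]`` (denominator: whole population)
    * ``NNT Targeted = t / (s·p·e_t) = 1 / (PPV·e_t)``
    """
    s = scenario.sensitivity
    p = scenario.prevalence
    t = scenario.target_fraction
    e_t, e_r = effectiveness.effect_target, effectiveness.effect_remainder

    prevented_target = s * p * e_t
    preventable_all = p * (s * e_t + (1.0 - s) * e_r)
    if preventable_all == 0.0:
        raise DegenerateScenarioError(
            "treatment prevents no events anywhere (both effectiveness terms zero); NNT undefined"
        )
    return InterventionOutcome(
        percent_preventable=prevented_target / preventable_all,
        percent_all_prevented=s * e_t,
        nnt_all=1.0 / preventable_all,
        nnt_targeted=math.inf if prevented_target == 0.0 else t / prevented_target,
    )


def required_rr_for_precision(
    ppv_goal: float, prevalence: float, target_fraction: float
) -> float:
    """Relative risk a score must reach for a precision goal.

    Inverts the forward map PPV(RR) at fixed prevalence and target fraction:
    ``s = PPV·t/p`` and then ``RR = [s/t] / [(1−s)/(1−t)]``. For example a
    50% precision goal targeting 5% at 8% prevalence needs RR ≈ 8.64.

    Raises
    ------
    InfeasibleScenarioError
        If ``ppv_goal·t > p`` (goal unreachable even with a perfect score).
    """
    s = sensitivity_from_ppv(ppv_goal, prevalence, target_fraction)
    if s >= 1.0:
        raise InfeasibleScenarioError(
            f"precision goal {ppv_goal} at target {target_fraction} requires capturing "
            f"all cases (sensitivity 1); no finite relative risk achieves it"
        )
    t = target_fraction
    return (s / t) / ((1.0 - s) / (1.0 - t))


def two_group_prevention(
    prevalence: float,
    low_fraction: float,
    low_risk_ratio: float,
    success_rate: float,
) -> float:
    """Fraction of all cases prevented by intervening only in the high-risk group.

    A negative predictor splits the population into a low-risk group of size
    ``low_fraction`` whose per-person risk is ``low_risk_ratio`` times the
    high-risk group's. Group risks are solved so the mixture equals the
    overall prevalence, and an intervention succeeds in ``success_rate`` of
    the high-risk group's cases.

    Example: if two-thirds of the population carry half the risk of the rest
    at 8% overall prevalence, succeeding in half of the high-risk third's
    cases prevents 25% of all cases.
    """
    from .core_metrics import _check_fraction  # local import keeps the public surface small

    _check_fraction("prevalence", prevalence)
    _check_fraction("low_fraction", low_fraction)
    _check_fraction("low_risk_ratio", low_risk_ratio, closed_right=True)
    if not (0.0 <= success_rate <= 1.0):
        raise DomainError(f"success_rate must be in [0, 1], got {success_rate!r}")

    # mixture: low_fraction·(ratio·h) + (1−low_fraction)·h = prevalence
    high_risk = prevalence / (low_fraction * low_risk_ratio + (1.0 - low_fraction))
    if high_risk > 1.0:
        raise InfeasibleScenarioError(
            f"implied high-group risk {high_risk:.4f} exceeds 1 "
            f"(p={prevalence}, low_fraction={low_fraction}, ratio={low_risk_ratio})"
        )
    high_case_share = high_risk * (1.0 - low_fraction) / prevalence
    return high_case_share * success_rate
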