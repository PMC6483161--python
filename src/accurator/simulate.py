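"""Monte Carlo cohort simulator: the counting oracle behind every closed form.

Individuals are drawn from the same liability-threshold model the analytic
modules assume: genetic score ``g ~ N(0, r2)``, residual ``e ~ N(0, 1−r2)``,
disease when ``g + e`` exceeds the prevalence threshold. The target group is
the top ``target_fraction`` of the cohort ranked by ``g`` — by the score,
not by the (unobservable) outcome. Each person also receives a single
counterfactual response draw at their group's effectiveness, so the
"treat everyone" and "treat the target only" policies are compared on the
same potential outcomes rather than on independent randomness.

Every classification metric, prevention fraction and NNT is then obtained by
direct counting, with binomial standard errors, giving an estimator that is
model-free given the cohort — the independent check on the algebra in
:mod:`accurator.core_metrics`, :mod:`accurator.intervention` and
:mod:`accurator.liability`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_metrics import ClassificationSummary, ConfusionFractions, summarize
from .errors import DegenerateScenarioError, DomainError
from .intervention import EffectivenessModel, InterventionOutcome
from .liability import LiabilityModel

__all__ = ["SyntheticCohort", "EmpiricalReport", "simulate_cohort", "empirical_metrics"]


@dataclass(frozen=True)
class SyntheticCohort:
    """Individual-level draws: PRS liability, outcome, targeting, response."""

    model: LiabilityModel
    target_fraction: float
    effectiveness: EffectivenessModel
    seed: int
    prs_liability: np.ndarray  # genetic component g, variance r2
    disease: np.ndarray  # bool
    in_target: np.ndarray  # bool, top target_fraction by g
    would_respond: np.ndarray  # bool, counterfactual response if treated

    @property
    def n(self) -> int:
        return self.disease.shape[0]

    def to_frame(self):
        """One row per individual, suitable for TSV export."""
        import pandas as pd

        return pd.DataFrame(
            {
                "prs_liability": self.prs_liability,
                "disease": self.disease.astype(int),
                "in_target": self.in_target.astype(int),
                "would_respond": self.would_respond.astype(int),
            }
        )


@dataclass(frozen=True)
class EmpiricalReport:
    """Counted metrics with binomial standard errors."""

    n: int
    classification: ClassificationSummary
    intervention: InterventionOutcome
    se: dict[str, float]

    def as_dict(self) -> dict:
        c, iv = self.classification, self.intervention
        return {
            "n": self.n,
            "ppv": c.ppv,
            "npv": c.npv,
            "sensitivity": c.sensitivity,
            "specificity": c.specificity,
            "accuracy": c.accuracy,
            "relative_risk": c.relative_risk,
            "percent_preventable": iv.percent_preventable,
            "percent_all_prevented": iv.percent_all_prevented,
            "nnt_all": iv.nnt_all,
            "nnt_targeted": iv.nnt_targeted,
            "se": dict(self.se),
        }


def simulate_cohort(
    model: LiabilityModel,
    target_fraction: float,
    effectiveness: EffectivenessModel,
    n: int,
    seed: int,
) -> SyntheticCohort:
    """Draw a cohort of ``n`` individuals, deterministic given ``seed``.

    Exactly ``round(n * target_fraction)`` individuals are targeted (the top
    of the genetic-score ranking; ties broken by draw order), so the target
    fraction is honoured up to integer rounding even in small cohorts.
    """
    if n < 1:
        raise DomainError(f"cohort size must be >= 1, got {n!r}")
    if not (0.0 < target_fraction < 1.0):
        raise DomainError(f"target_fraction must be in (0, 1), got {target_fraction!r}")
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, math.sqrt(model.r2), size=n) if model.r2 > 0 else np.zeros(n)
    e = rng.normal(0.0, math.sqrt(1.0 - model.r2), size=n)
    disease = (g + e) > model.threshold

    k = int(round(n * target_fraction))
    k = min(max(k, 1), n - 1)
    in_target = np.zeros(n, dtype=bool)
    if model.r2 > 0:
        in_target[np.argpartition(-g, k - 1)[:k]] = True
    else:
        # uninformative score: the "top" is an arbitrary subset
        in_target[rng.permutation(n)[:k]] = True

    response_p = np.where(in_target, effectiveness.effect_target, effectiveness.effect_remainder)
    would_respond = rng.random(n) < response_p

    return SyntheticCohort(
        model=model,
        target_fraction=target_fraction,
        effectiveness=effectiveness,
        seed=seed,
        prs_liability=g,
        disease=disease,
        in_target=in_target,
        would_respond=would_respond,
    )


def empirical_metrics(cohort: SyntheticCohort) -> EmpiricalReport:
    """All metrics by direct counting, with binomial standard errors.

    Prevented events are counted on the counterfactual response draws:
    treating the target prevents the cases that are in the target *and*
    would respond; treating everyone prevents every case that would respond
    (target cases at ``e_t``, remainder cases at ``e_r``).
    """
    n = cohort.n
    disease, target, respond = cohort.disease, cohort.in_target, cohort.would_respond
    n_cases = int(disease.sum())
    n_target = int(target.sum())
    if n_cases == 0 or n_cases == n:
        raise DegenerateScenarioError(
            f"cohort has {n_cases} cases out of {n}; classification metrics undefined"
        )

    tp = int((disease & target).sum())
    fp = n_target - tp
    fn = n_cases - tp
    tn = n - n_target - fn
    classification = summarize(
        ConfusionFractions(tp=tp / n, fp=fp / n, fn=fn / n, tn=tn / n)
    )

    prevented_target = int((disease & target & respond).sum())
    preventable_all = int((disease & respond).sum())
    if preventable_all == 0:
        raise DegenerateScenarioError("no case responds under either policy; NNT undefined")
    intervention = InterventionOutcome(
        percent_preventable=prevented_target / preventable_all,
        percent_all_prevented=prevented_target / n_cases,
        nnt_all=n / preventable_all,
        nnt_targeted=math.inf if prevented_target == 0 else n_target / prevented_target,
    )

    def binom_se(p_hat: float, m: int) -> float:
        return math.sqrt(p_hat * (1.0 - p_hat) / m) if m > 0 else math.inf

    c = classification
    se = {
        "ppv": binom_se(c.ppv, n_target),
        "npv": binom_se(c.npv, n - n_target),
        "sensitivity": binom_se(c.sensitivity, n_cases),
        "specificity": binom_se(c.specificity, n - n_cases),
        "accuracy": binom_se(c.accuracy, n),
        "percent_preventable": binom_se(intervention.percent_preventable, preventable_all),
        "percent_all_prevented": binom_se(intervention.percent_all_prevented, n_cases),
    }
    return EmpiricalReport(n=n, classification=classification, intervention=intervention, se=se)
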