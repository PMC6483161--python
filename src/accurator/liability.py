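"""Liability-threshold model linking PRS percentile to disease risk.

The model: each person's liability is ``L = g + e`` with the genetic score
``g ~ N(0, r2)`` and residual ``e ~ N(0, 1−r2)``, so ``L`` is standard
normal; disease occurs when ``L`` exceeds the threshold ``T = Φ⁻¹(1−K)``
fixed by the population risk ``K``. Conditional on a person sitting at PRS
percentile ``q`` (i.e. ``g = √r2 · Φ⁻¹(q)``), the disease probability is

    risk(q) = Φ̄( (T − √r2·Φ⁻¹(q)) / √(1−r2) )

which rises from well below ``K`` at the bottom of the score distribution to
several-fold above it in the top percentiles — the familiar hockey-stick
curve of PRS profile plots. Integrating risk(q) over the percentile axis
recovers ``K`` (law of total probability), the basic self-consistency check
used throughout the tests.

The module also converts "treat everyone above percentile q" into a full
classification summary, and calibrates the variance explained ``r2`` so the
top tail matches a stated relative risk — the bridge between percentile
targeting and the RR-parameterized scenario algebra in
:mod:`accurator.core_metrics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .core_metrics import ClassificationSummary, ConfusionFractions, summarize
from .errors import DegenerateScenarioError, DomainError, InfeasibleScenarioError

__all__ = [
    "LiabilityModel",
    "RiskCurve",
    "risk_at_percentile",
    "integrated_risk",
    "risk_curve",
    "metrics_above_percentile",
    "calibrate_r2_to_rr",
]

# Gauss–Legendre nodes per integration panel; 24 nodes on each of the
# composite panels keeps the total-probability defect below 1e-10 even for
# extreme (K, r2).
_GL_ORDER = 24
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(_GL_ORDER)
# integration limit in liability units; the omitted normal tail mass is < 1e-17
_Z_CAP = 8.5


@dataclass(frozen=True)
class LiabilityModel:
    """Population risk ``K`` plus variance in liability explained by the PRS."""

    prevalence: float
    r2: float

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise DomainError(f"prevalence must be in (0, 1), got {self.prevalence!r}")
        if not (0.0 <= self.r2 < 1.0):
            if self.r2 == 1.0:
                raise DegenerateScenarioError(
                    "r2 = 1 makes risk a step function of percentile; the conditional-risk "
                    "formula is undefined (zero residual variance)"
                )
            raise DomainError(f"r2 must be in [0, 1), got {self.r2!r}")

    @property
    def threshold(self) -> float:
        """Liability threshold ``T = Φ⁻¹(1−K)``."""
        return norm.isf(self.prevalence)


def risk_at_percentile(model: LiabilityModel, q):
    """Conditional disease probability at PRS percentile ``q`` (vectorized).

    Equals ``K`` for every ``q`` when ``r2 = 0`` (uninformative score) and is
    strictly increasing in ``q`` otherwise.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0.0) | (q >= 1.0)):
        raise DomainError("percentile q must be strictly inside (0, 1)")
    if model.r2 == 0.0:
        out = np.full_like(q, model.prevalence)
        return float(out) if out.ndim == 0 else out
    g = math.sqrt(model.r2) * norm.ppf(q)
    z = (model.threshold - g) / math.sqrt(1.0 - model.r2)
    out = norm.sf(z)
    return float(out) if out.ndim == 0 else out


def integrated_risk(model: LiabilityModel, lo: float, hi: float, panels: int = 8) -> float:
    """``∫ risk(q) dq`` over ``(lo, hi)`` by composite Gauss–Legendre quadrature.

    This is the joint probability of having the disease *and* a PRS
    percentile in ``(lo, hi)``. The quadrature runs on the liability scale
    (``q = Φ(z)``), where the integrand is smooth all the way to the tails.
    """
    if not (0.0 <= lo < hi <= 1.0):
        raise DomainError(f"need 0 <= lo < hi <= 1, got ({lo}, {hi})")
    if model.r2 == 0.0:
        return model.prevalence * (hi - lo)
    # substitute q = Phi(z): the integrand Phibar((T - sqrt(r2) z)/sqrt(1-r2)) * phi(z)
    # is smooth, unlike the percentile-space integrand whose derivatives blow
    # up at q -> 0, 1 through the inverse normal
    z_lo = norm.ppf(lo) if lo > 0.0 else -_Z_CAP
    z_hi = norm.ppf(hi) if hi < 1.0 else _Z_CAP
    z_lo, z_hi = max(z_lo, -_Z_CAP), min(z_hi, _Z_CAP)
    edges = np.linspace(z_lo, z_hi, panels + 1)
    a, b = edges[:-1, None], edges[1:, None]
    z = 0.5 * (b - a) * _GL_NODES + 0.5 * (a + b)
    w = 0.5 * (b - a) * _GL_WEIGHTS
    g = math.sqrt(model.r2) * z
    integrand = norm.sf((model.threshold - g) / math.sqrt(1.0 - model.r2)) * norm.pdf(z)
    return float(np.sum(w * integrand))


@dataclass(frozen=True)
class RiskCurve:
    """Risk-by-percentile profile on a regular grid of percentile bins.

    Bins are half-open ``[i/bins, (i+1)/bins)``. ``risk_at[i]`` is the mean
    conditional risk within bin ``i``; ``sensitivity_above[i]`` is the
    fraction of all cases at or above the bin's lower edge;
    ``fold_vs_below[i]`` is bin risk divided by the mean risk of everyone in
    lower bins (NaN for the first bin, which has no one below it);
    ``ppv_above[i]`` is the precision of targeting everyone at or above the
    bin's lower edge.
    """

    model: LiabilityModel
    percentiles: np.ndarray
    risk_at: np.ndarray
    sensitivity_above: np.ndarray
    fold_vs_below: np.ndarray
    ppv_above: np.ndarray = field(repr=False)

    def to_frame(self):
        """Curve as a tidy :class:`pandas.DataFrame` (one row per bin)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "percentile": self.percentiles,
                "risk": self.risk_at,
                "fold_vs_below": self.fold_vs_below,
                "sensitivity_above": self.sensitivity_above,
                "ppv_above": self.ppv_above,
            }
        )


def risk_curve(model: LiabilityModel, bins: int = 100) -> RiskCurve:
    """Compute the full risk-by-percentile profile on ``bins`` equal bins."""
    if bins < 2:
        raise DomainError("need at least 2 percentile bins")
    edges = np.linspace(0.0, 1.0, bins + 1)
    width = 1.0 / bins
    bin_mass = np.array(
        [integrated_risk(model, edges[i], edges[i + 1], panels=2) for i in range(bins)]
    )
    risk_at = bin_mass / width

    cum_below = np.concatenate([[0.0], np.cumsum(bin_mass)])  # cases below each edge
    total = cum_below[-1]
    sens_above = (total - cum_below[:-1]) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_below = cum_below[:-1] / edges[:-1]  # mean risk of all lower percentiles
        fold = risk_at / mean_below
    fold[0] = np.nan
    ppv_above = (total - cum_below[:-1]) / (1.0 - edges[:-1])
    return RiskCurve(
        model=model,
        percentiles=edges[:-1],
        risk_at=risk_at,
        sensitivity_above=sens_above,
        fold_vs_below=fold,
        ppv_above=ppv_above,
    )


def metrics_above_percentile(model: LiabilityModel, q: float) -> ClassificationSummary:
    """Classification summary for targeting everyone above percentile ``q``.

    The target fraction is ``1 − q``; the true-positive mass is the
    integrated risk over ``(q, 1)``; the rest is 2x2-table algebra.
    """
    if not (0.0 < q < 1.0):
        raise DomainError(f"percentile q must be in (0, 1), got {q!r}")
    t = 1.0 - q
    tp = integrated_risk(model, q, 1.0)
    k = model.prevalence
    tp = min(tp, k, t)  # guard against quadrature overshoot at extreme tails
    confusion = ConfusionFractions(tp=tp, fp=t - tp, fn=k - tp, tn=1.0 - t - (k - tp))
    return summarize(confusion)


def calibrate_r2_to_rr(prevalence: float, target_rr: float, q: float) -> float:
    """Variance explained needed for a given top-tail relative risk.

    Finds ``r2`` such that targeting above percentile ``q`` yields the
    stated remainder-referenced relative risk. ``target_rr = 1`` maps to
    ``r2 = 0``; larger RR needs larger ``r2``; an RR at or above the
    perfect-score supremum ``(1−t)/(K−t)`` (for ``K > t = 1−q``) is
    infeasible.
    """
    if not (0.0 < q < 1.0):
        raise DomainError(f"percentile q must be in (0, 1), got {q!r}")
    if target_rr < 1.0:
        raise InfeasibleScenarioError(
            f"a score cannot make the top tail *less* risky than the remainder (RR={target_rr})"
        )
    if target_rr == 1.0:
        return 0.0
    t = 1.0 - q
    if prevalence > t:
        sup = (1.0 - t) / (prevalence - t)
        if target_rr >= sup:
            raise InfeasibleScenarioError(
                f"RR {target_rr} at q={q} unreachable: even a perfect score caps at {sup:.4f}"
            )

    def gap(r2: float) -> float:
        m = LiabilityModel(prevalence, r2)
        return metrics_above_percentile(m, q).relative_risk - target_rr

    lo, hi = 1e-12, 1.0 - 1e-9
    if gap(hi) < 0.0:
        raise InfeasibleScenarioError(
            f"RR {target_rr} at q={q}, K={prevalence} exceeds what any r2 < 1 can deliver"
        )
    r2 = optimize.brentq(gap, lo, hi, xtol=1e-12, rtol=1e-12)
    return float(r2)
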