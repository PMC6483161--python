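"""Confusion-matrix algebra: worked examples, inversions, and invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from accurator import (
    CohortScenario,
    ConfusionFractions,
    DegenerateScenarioError,
    DomainError,
    InfeasibleScenarioError,
    confusion_from_scenario,
    relative_risk_from_sensitivity,
    round_percent,
    sensitivity_from_ppv,
    sensitivity_from_relative_risk,
    summarize,
)


def rr_oracle_sensitivity(rr: float, t: float) -> float:
    """Independent root-find on the defining ratio equation.

    RR = [s/t] / [(1-s)/(1-t)] is solved numerically instead of using the
    closed form under test.
    """
    return brentq(
        lambda s: (s / t) / ((1.0 - s) / (1.0 - t)) - rr, 1e-12, 1.0 - 1e-12, xtol=1e-14
    )


class TestSensitivityFromRelativeRisk:
    @pytest.mark.parametrize(
        "rr, t, expected, tol",
        [
            (9.0, 0.10, 0.50, 1e-12),  # exceptional score capturing half the cases
            (1.0, 0.25, 0.25, 1e-12),  # no discrimination: sensitivity = target fraction
            (4.7, 0.05, 0.1983122362869198, 1e-9),  # frozen from the root-find oracle
        ],
    )
    def test_examples(self, rr, t, expected, tol):
        assert sensitivity_from_relative_risk(rr, t) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("rr, t", [(4.7, 0.05), (2.0, 0.33), (8.7, 0.05), (0.5, 0.4)])
    def test_agrees_with_root_find_oracle(self, rr, t):
        assert sensitivity_from_relative_risk(rr, t) == pytest.approx(
            rr_oracle_sensitivity(rr, t), abs=1e-9
        )

    @pytest.mark.parametrize("rr, t", [(0.0, 0.1), (-1.0, 0.1), (2.0, 0.0), (2.0, 1.0), (2.0, 1.5)])
    def test_domain_errors(self, rr, t):
        with pytest.raises(DomainError):
            sensitivity_from_relative_risk(rr, t)


class TestSensitivityFromPPV:
    def test_precision_goal_scenario(self):
        # 50% precision targeting 5% of an 8%-prevalence population
        assert sensitivity_from_ppv(0.50, 0.08, 0.05) == pytest.approx(0.3125, abs=1e-12)

    @pytest.mark.parametrize("p, t", [(0.08, 0.1), (0.3, 0.5), (0.02, 0.9)])
    def test_chance_level_classifier(self, p, t):
        # PPV equal to prevalence means no enrichment: sensitivity = target fraction
        assert sensitivity_from_ppv(p, p, t) == pytest.approx(t, abs=1e-12)

    def test_cross_check_against_rr_route(self):
        s_via_ppv = sensitivity_from_ppv(0.12, 0.08, 1.0 / 3.0)
        s_via_rr = sensitivity_from_relative_risk(2.0, 1.0 / 3.0)
        assert s_via_ppv == pytest.approx(0.50, abs=1e-12)
        assert s_via_ppv == pytest.approx(s_via_rr, abs=1e-12)

    def test_infeasible_goal_raises(self):
        with pytest.raises(InfeasibleScenarioError):
            sensitivity_from_ppv(0.9, 0.02, 0.10)  # needs 4.5x more cases than exist


class TestConfusionFromScenario:
    def test_rare_reasonable_cells(self):
        c = confusion_from_scenario(CohortScenario.from_relative_risk(0.02, 0.05, 4.7))
        assert c.tp == pytest.approx(0.0039662447, abs=1e-9)
        assert c.fp == pytest.approx(0.0460337553, abs=1e-9)
        assert c.fn == pytest.approx(0.0160337553, abs=1e-9)
        assert c.tn == pytest.approx(0.9339662447, abs=1e-9)
        assert c.tp + c.fp + c.fn + c.tn == pytest.approx(1.0, abs=1e-12)
        assert c.prevalence == pytest.approx(0.02, abs=1e-12)
        assert c.target_fraction == pytest.approx(0.05, abs=1e-12)

    def test_perfect_classifier_at_target_equal_prevalence(self):
        c = confusion_from_scenario(CohortScenario.from_sensitivity(0.02, 0.02, 1.0))
        assert (c.tp, c.fp, c.fn, c.tn) == pytest.approx((0.02, 0.0, 0.0, 0.98), abs=1e-12)

    def test_common_predictive_ppv(self):
        c = confusion_from_scenario(CohortScenario.from_relative_risk(0.20, 0.05, 4.7))
        assert round_percent(summarize(c).ppv) == 79

    def test_infeasible_scenario_rejected(self):
        # sensitivity 1 at p > t would need PPV > 1
        with pytest.raises(InfeasibleScenarioError):
            CohortScenario.from_sensitivity(0.30, 0.05, 1.0)


class TestSummarize:
    def test_rare_reasonable_metrics(self):
        s = summarize(confusion_from_scenario(CohortScenario.from_relative_risk(0.02, 0.05, 4.7)))
        assert s.ppv == pytest.approx(0.0793249, abs=1e-6)
        assert s.npv == pytest.approx(0.9831224, abs=1e-6)
        assert s.accuracy == pytest.approx(0.9379325, abs=1e-6)
        assert s.specificity == pytest.approx(0.9530269, abs=1e-6)
        assert (
            round_percent(s.ppv),
            round_percent(s.npv),
            round_percent(s.accuracy),
            round_percent(s.specificity),
        ) == (8, 98, 94, 95)

    def test_opioid_top1_ppv(self):
        s = summarize(confusion_from_scenario(CohortScenario.from_relative_risk(0.05, 0.01, 6.0)))
        assert s.ppv == pytest.approx(2.0 / 7.0, abs=1e-9)
        assert round_percent(s.ppv) == 29

    def test_symmetric_table_is_uninformative(self):
        s = summarize(ConfusionFractions(0.25, 0.25, 0.25, 0.25))
        assert (s.ppv, s.npv, s.sensitivity, s.specificity, s.accuracy) == (0.5,) * 5
        assert s.relative_risk == pytest.approx(1.0, abs=1e-12)

    def test_empty_margin_is_degenerate(self):
        with pytest.raises(DegenerateScenarioError):
            summarize(ConfusionFractions(0.0, 0.0, 0.02, 0.98))


class TestRoundPercent:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.9379, 94), (0.005, 1), (0.065113, 7), (0.0, 0), (1.0, 100), (0.425, 43)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_percent(x) == expected

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            round_percent(-0.01)


# ---------------------------------------------------------------------------
# invariants over random feasible scenarios

def feasible_scenarios():
    """Strategy over (p, t, s) triples satisfying both 2x2 feasibility bounds."""

    def build(p, t, u):
        s_lo = max(0.0, 1.0 - (1.0 - t) / p)  # NPV >= 0
        s_hi = min(1.0, t / p)  # PPV <= 1
        s = s_lo + u * (s_hi - s_lo)
        s = min(max(s, 1e-9), s_hi)
        return CohortScenario.from_sensitivity(p, t, s)

    return st.builds(
        build,
        st.floats(0.001, 0.5),
        st.floats(0.01, 0.99),
        st.floats(1e-6, 1.0 - 1e-6),
    )


@settings(max_examples=300, derandomize=True)
@given(feasible_scenarios())
def test_case_conservation(scenario):
    """ppv*t + (1-npv)*(1-t) recovers the prevalence to near machine precision."""
    s = summarize(confusion_from_scenario(scenario))
    t = scenario.target_fraction
    reconstructed = s.ppv * t + (1.0 - s.npv) * (1.0 - t)
    assert abs(reconstructed - scenario.prevalence) < 1e-12
    assert s.sensitivity * scenario.prevalence == pytest.approx(s.ppv * t, abs=1e-12)


@settings(max_examples=300, derandomize=True)
@given(
    st.floats(0.01, 50.0),
    st.floats(0.01, 0.99),
    st.floats(0.001, 0.5),
)
def test_relative_risk_round_trip(rr, t, p):
    """RR -> sensitivity -> summarize recovers RR; the map never sees p."""
    s = sensitivity_from_relative_risk(rr, t)
    assert relative_risk_from_sensitivity(s, t) == pytest.approx(rr, rel=1e-9)
    # prevalence invariance: summarize only when the 2x2 table is feasible
    if s * p <= t and (1.0 - s) * p <= 1.0 - t:
        summary = summarize(confusion_from_scenario(CohortScenario.from_relative_risk(p, t, rr)))
        assert summary.relative_risk == pytest.approx(rr, rel=1e-9)


@settings(max_examples=200, derandomize=True)
@given(st.floats(0.01, 0.9), st.floats(0.01, 0.99), st.floats(1e-4, 1.0))
def test_ppv_round_trip(p, t, u):
    """PPV -> sensitivity -> summarize recovers the input PPV to 1e-12."""
    ppv_max = min(1.0, p / t)  # keep sensitivity <= 1
    ppv = max(u * ppv_max, 1e-6)
    s = sensitivity_from_ppv(ppv, p, t)
    if (1.0 - s) * p > 1.0 - t:  # NPV side may still be infeasible
        return
    summary = summarize(confusion_from_scenario(CohortScenario.from_ppv(p, t, ppv)))
    assert summary.ppv == pytest.approx(ppv, abs=1e-12)


def test_metrics_nondecreasing_in_relative_risk():
    """At fixed p and t, every metric improves as the score gets stronger."""
    p, t = 0.05, 0.10
    rrs = [1.0, 1.5, 2.0, 3.0, 4.7, 6.0, 8.0]
    summaries = [
        summarize(confusion_from_scenario(CohortScenario.from_relative_risk(p, t, rr)))
        for rr in rrs
    ]
    for metric in ("ppv", "npv", "sensitivity", "specificity"):
        values = [getattr(s, metric) for s in summaries]
        assert all(b >= a - 1e-15 for a, b in zip(values, values[1:])), metric
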