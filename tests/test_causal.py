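"""The RR / AR / absolute-risk decision calculus and the >50% legal gate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crashcausal.causal import (
    absolute_risk_difference,
    assess_significance,
    attributable_risk,
    attributable_risk_from_probs,
    quantify_from_estimates,
    risk_ratio,
)
from crashcausal.errors import DomainError, UndefinedRatioError
from crashcausal.survey_glm import RiskEstimate, Z95
from scipy.special import expit, logit


def _estimate(p: float, se_logit: float = 0.0) -> RiskEstimate:
    if se_logit == 0.0:
        return RiskEstimate(p=p, se_logit=0.0, ci95=(p, p))
    eta = logit(p)
    return RiskEstimate(
        p=p,
        se_logit=se_logit,
        ci95=(float(expit(eta - Z95 * se_logit)), float(expit(eta + Z95 * se_logit))),
    )


class TestRiskRatio:
    def test_thirty_over_ten_is_three(self):
        assert risk_ratio(0.30, 0.10) == pytest.approx(3.0)

    def test_rollover_example_rounds_to_two_point_one(self):
        assert round(risk_ratio(0.27, 0.13), 1) == 2.1

    @given(st.floats(0.001, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_identical_risks_give_unity(self, p):
        assert risk_ratio(p, p) == pytest.approx(1.0)

    def test_zero_baseline_is_undefined_never_infinite(self):
        with pytest.raises(UndefinedRatioError):
            risk_ratio(0.2, 0.0)
        with pytest.raises(UndefinedRatioError):
            risk_ratio(0.0, 0.0)


class TestAttributableRisk:
    @pytest.mark.parametrize("rr, ar", [(3.0, 67), (1.5, 33), (1.0, 0)])
    def test_printed_values(self, rr, ar):
        assert round(attributable_risk(rr)) == ar

    def test_protective_ratio_goes_negative(self):
        assert attributable_risk(0.5) == pytest.approx(-100.0)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(DomainError):
            attributable_risk(0.0)

    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_rr(self, a, b):
        if a < b:
            assert attributable_risk(a) < attributable_risk(b)

    @pytest.mark.parametrize(
        "p1, p0, ar",
        [(0.27, 0.13, 52), (0.10, 0.01, 90), (0.5, 0.5, 0)],
    )
    def test_from_probabilities_printed_values(self, p1, p0, ar):
        assert round(attributable_risk_from_probs(p1, p0)) == ar

    @given(st.floats(0.001, 1.0), st.floats(0.001, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_two_routes_agree_algebraically(self, p1, p0):
        via_rr = attributable_risk(risk_ratio(p1, p0))
        direct = attributable_risk_from_probs(p1, p0)
        assert abs(via_rr - direct) < 1e-12 * max(1.0, abs(direct))


class TestAbsoluteRiskDifference:
    def test_printed_values(self):
        assert absolute_risk_difference(0.30, 0.10) == pytest.approx(0.20)
        assert absolute_risk_difference(10 / 1e7, 1 / 1e7) == pytest.approx(9 / 1e7)
        assert absolute_risk_difference(0.4, 0.4) == 0.0


class TestThresholdEquivalence:
    def test_ar_over_fifty_iff_rr_over_two_on_dense_grid(self):
        grid = np.concatenate([np.linspace(0.05, 10.0, 2000), [2.0]])
        for rr in grid:
            assert (attributable_risk(rr) > 50.0) == (rr > 2.0)

    def test_boundary_fails_strict_gate(self):
        # AR exactly 50% (RR exactly 2) does not meet a strict >50% standard
        e1, e0 = _estimate(0.30, 0.05), _estimate(0.15, 0.05)
        q = quantify_from_estimates(e1, e0)
        assert q.rr == pytest.approx(2.0)
        assert q.ar_percent == pytest.approx(50.0)
        assert not q.gate_passed
        assert q.apportionment == 0.0


class TestSignificance:
    def test_identical_estimates_not_significant_either_method(self):
        e = _estimate(0.3, 0.2)
        assert not assess_significance(e, e, "wald_difference").significant
        assert not assess_significance(e, e, "ci_overlap").significant

    def test_overlapping_cis_not_significant_under_heuristic(self):
        e1 = _estimate(0.66, 0.6)
        e0 = _estimate(0.78, 0.5)
        res = assess_significance(e1, e0, "ci_overlap")
        assert not res.significant

    def test_disjoint_cis_significant_under_heuristic(self):
        e1 = _estimate(0.60, 0.05)
        e0 = _estimate(0.10, 0.05)
        assert assess_significance(e1, e0, "ci_overlap").significant

    def test_wald_flags_large_standardised_difference(self):
        e1 = _estimate(0.30, 0.10)
        e0 = _estimate(0.10, 0.10)
        res = assess_significance(e1, e0, "wald_difference")
        assert res.significant and res.p_value < 0.05

    def test_degenerate_zero_variance_equal_estimates(self):
        e = _estimate(0.4, 0.0)
        res = assess_significance(e, e, "wald_difference")
        assert res.degenerate and not res.significant

    def test_unknown_method_rejected(self):
        e = _estimate(0.4, 0.1)
        with pytest.raises(DomainError):
            assess_significance(e, e, "bootstrap")


class TestTwoStageDecision:
    def test_worked_example_chain_gate_passes(self):
        # 30% vs 10%, clearly significant: AR 67% > 50%, share = 0.20
        e1, e0 = _estimate(0.30, 0.05), _estimate(0.10, 0.05)
        q = quantify_from_estimates(e1, e0)
        assert q.rr == pytest.approx(3.0)
        assert round(q.ar_percent) == 67
        assert q.gate_passed
        assert q.apportionment == pytest.approx(0.20)

    def test_rr_one_point_five_fails_gate(self):
        e1, e0 = _estimate(0.15, 0.02), _estimate(0.10, 0.02)
        q = quantify_from_estimates(e1, e0)
        assert q.rr == pytest.approx(1.5)
        assert round(q.ar_percent) == 33
        assert not q.gate_passed
        assert q.apportionment == 0.0
        assert "not proven causal" in q.narrative

    def test_protective_direction_surfaced_not_clamped(self):
        # unbelted risk below belted (as in very-high-speed frontal crashes)
        e1, e0 = _estimate(0.66, 0.3), _estimate(0.78, 0.3)
        q = quantify_from_estimates(e1, e0)
        assert q.rr < 1.0
        assert q.protective
        assert not q.gate_passed
        assert q.apportionment == 0.0

    def test_survivability_conclusion_when_both_risks_exceed_half(self):
        e1, e0 = _estimate(0.66, 0.6), _estimate(0.78, 0.6)
        q = quantify_from_estimates(e1, e0)
        assert q.survivable_regardless
        assert "regardless of restraint use" in q.narrative

    def test_significance_requirement_blocks_gate(self):
        # AR > 50% but wide uncertainty: not significant, gate fails
        e1, e0 = _estimate(0.30, 1.5), _estimate(0.10, 1.5)
        q = quantify_from_estimates(e1, e0)
        assert q.ar_percent > 50.0
        assert not q.significance.significant
        assert not q.gate_passed

    def test_product_defect_framing_apportions_attributable_fraction(self):
        e1, e0 = _estimate(0.10, 0.15), _estimate(0.01, 0.15)
        q = quantify_from_estimates(e1, e0, framing="product-defect")
        assert round(q.ar_percent) == 90
        if q.gate_passed:
            assert q.apportionment == pytest.approx(q.ar_percent / 100.0)

    @given(
        st.floats(0.01, 0.99),
        st.floats(0.01, 0.99),
        st.floats(0.0, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_apportionment_bounded_by_exposed_risk_and_zero_on_failed_gate(
        self, p1, p0, se
    ):
        q = quantify_from_estimates(_estimate(p1, se), _estimate(p0, se))
        if q.gate_passed:
            assert q.apportionment <= q.p_unbelted.p
            assert q.rr > 2.0  # AR > 50 <=> RR > 2
        else:
            assert q.apportionment == 0.0
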