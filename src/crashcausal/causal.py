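"""Relative, attributable and absolute risk: the medicolegal decision calculus.

Given the death (or injury) probability for the occupant's actual exposure
(unbelted, ``p1``) and the counterfactual belted scenario (``p0``), the
quantities of interest are:

* relative risk ``RR = p1 / p0``;
* attributable risk ``AR = (RR - 1) / RR x 100%``, equivalently
  ``(p1 - p0) / p1 x 100%`` — the share of the exposed group's risk that
  the exposure accounts for;
* absolute risk difference ``p1 - p0``.

The civil "more probable than not" standard maps to a strict AR > 50%
threshold, algebraically the same as RR > 2.0.  The two-stage rule is:
first, require statistically reliable evidence that AR exceeds 50%; only
then quantify the claimant's contributory share — and that share is the
absolute risk difference, not the attributable fraction, because the
population at risk is everyone in the crash, belted or not.  (Under a
product-defect framing, where the safety device's failure is proximate to
the injury, the attributable fraction itself is the apportionment; that
variant is available via ``framing="product-defect"``.)

Significance is assessed two ways: a formal two-sided Wald test on the
probability-scale risk difference (the default, governing the gate) and
the conservative confidence-interval-overlap heuristic, both reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import DomainError, NotConvergedError, UndefinedRatioError
from .records import CaseSpec
from .survey_glm import FittedRiskModel, RiskEstimate, predict_risk

__all__ = [
    "risk_ratio",
    "attributable_risk",
    "attributable_risk_from_probs",
    "absolute_risk_difference",
    "assess_significance",
    "SignificanceResult",
    "CausalQuantification",
    "quantify_case",
    "AR_GATE_PERCENT",
    "RR_GATE",
]

#: Strict thresholds for the "more probable than not" standard.
AR_GATE_PERCENT = 50.0
RR_GATE = 2.0


def risk_ratio(p1: float, p0: float) -> float:
    """Relative risk of the exposed (p1, unbelted) to unexposed (p0, belted)."""
    for name, p in (("p1", p1), ("p0", p0)):
        if not (0.0 <= p <= 1.0):
            raise DomainError(f"{name} must be a probability in [0, 1], got {p}")
    if p0 == 0.0:
        if p1 == 0.0:
            raise UndefinedRatioError("risk ratio 0/0 is undefined")
        raise UndefinedRatioError("risk ratio with zero baseline risk is undefined")
    return p1 / p0


def attributable_risk(rr: float) -> float:
    """Attributable risk percent, (RR - 1)/RR x 100.

    Negative (protective exposure) when RR < 1; strictly increasing in RR.
    """
    if rr <= 0.0:
        raise DomainError(f"risk ratio must be positive, got {rr}")
    return (rr - 1.0) / rr * 100.0


def attributable_risk_from_probs(p1: float, p0: float) -> float:
    """Attributable risk percent directly from probabilities, (p1 - p0)/p1 x 100.

    Identical to ``attributable_risk(risk_ratio(p1, p0))`` whenever p0 > 0.
    """
    for name, p in (("p1", p1), ("p0", p0)):
        if not (0.0 <= p <= 1.0):
            raise DomainError(f"{name} must be a probability in [0, 1], got {p}")
    if p1 == 0.0:
        raise DomainError("attributable risk undefined when the exposed risk is zero")
    return (p1 - p0) / p1 * 100.0


def absolute_risk_difference(p1: float, p0: float) -> float:
    """Excess probability p1 - p0: the contributory share once causation is shown."""
    for name, p in (("p1", p1), ("p0", p0)):
        if not (0.0 <= p <= 1.0):
            raise DomainError(f"{name} must be a probability in [0, 1], got {p}")
    return p1 - p0


@dataclass(frozen=True)
class SignificanceResult:
    """Verdict of one significance method with its supporting numbers."""

    significant: bool
    method: str
    statistic: Optional[float] = None
    p_value: Optional[float] = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "significant": self.significant,
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "degenerate": self.degenerate,
        }


def assess_significance(
    e1: RiskEstimate, e0: RiskEstimate, method: str = "wald_difference"
) -> SignificanceResult:
    """Test whether the unbelted/belted risk difference exceeds chance scatter.

    ``wald_difference``: two-sided z-test on p1 - p0 with the delta-method
    standard errors, alpha = 0.05.  ``ci_overlap``: significant iff the two
    95% intervals are disjoint — a conservative heuristic often shown on
    risk-curve charts, reported alongside the formal test.
    """
    if method == "wald_difference":
        se = float(np.hypot(e1.se_p, e0.se_p))
        diff = e1.p - e0.p
        if se == 0.0:
            return SignificanceResult(
                significant=diff != 0.0,
                method=method,
                statistic=None,
                p_value=None,
                degenerate=True,
            )
        z = diff / se
        p_value = 2.0 * float(stats.norm.sf(abs(z)))
        return SignificanceResult(
            significant=p_value < 0.05, method=method, statistic=float(z), p_value=p_value
        )
    if method == "ci_overlap":
        disjoint = e1.ci95[0] > e0.ci95[1] or e0.ci95[0] > e1.ci95[1]
        return SignificanceResult(significant=bool(disjoint), method=method)
    raise DomainError(f"unknown significance method {method!r}")


@dataclass(frozen=True)
class CausalQuantification:
    """Full decision record for one case: risks, ratios, gate, apportionment."""

    p_unbelted: RiskEstimate
    p_belted: RiskEstimate
    rr: float
    ar_percent: float
    abs_diff: float
    significance: SignificanceResult
    ci_overlap: SignificanceResult
    gate_passed: bool
    apportionment: float
    framing: str
    protective: bool
    survivable_regardless: bool
    narrative: str

    def to_dict(self) -> dict:
        return {
            "p_unbelted": self.p_unbelted.to_dict(),
            "p_belted": self.p_belted.to_dict(),
            "rr": self.rr,
            "ar_percent": self.ar_percent,
            "abs_diff": self.abs_diff,
            "significance": self.significance.to_dict(),
            "ci_overlap": self.ci_overlap.to_dict(),
            "gate_passed": self.gate_passed,
            "apportionment": self.apportionment,
            "framing": self.framing,
            "protective": self.protective,
            "survivable_regardless": self.survivable_regardless,
            "narrative": self.narrative,
        }


def _decide(
    e1: RiskEstimate,
    e0: RiskEstimate,
    significance: SignificanceResult,
    ci_overlap: SignificanceResult,
    framing: str,
) -> CausalQuantification:
    rr = risk_ratio(e1.p, e0.p)
    ar = attributable_risk(rr)
    diff = absolute_risk_difference(e1.p, e0.p)
    protective = rr < 1.0
    gate = (ar > AR_GATE_PERCENT) and significance.significant
    # the strict AR gate is algebraically RR > 2; both stored full precision
    if framing == "contributory-negligence":
        apportionment = diff if gate else 0.0
    elif framing == "product-defect":
        apportionment = ar / 100.0 if gate else 0.0
    else:
        raise DomainError(f"unknown framing {framing!r}")

    both_over_half = e1.p > 0.5 and e0.p > 0.5
    parts = []
    if gate:
        parts.append(
            f"Non-use passes the more-probable-than-not gate (AR {ar:.0f}% > 50%, "
            f"RR {rr:.1f} > 2.0, difference statistically significant); "
        )
        if framing == "contributory-negligence":
            parts.append(
                f"the contributory share is the absolute risk difference, {diff:.3g}."
            )
        else:
            parts.append(f"the attributable fraction, {ar:.0f}%, is the apportionment.")
    else:
        parts.append("non-use not proven causal at the more-probable-than-not standard")
        if protective:
            parts.append(
                " (estimated unbelted risk is below the belted risk; "
                "the apparent protective direction is surfaced, not clamped)"
            )
        elif ar <= AR_GATE_PERCENT:
            parts.append(f" (attributable risk {ar:.0f}% does not exceed 50%)")
        if not significance.significant:
            parts.append("; the risk difference is not statistically significant")
        parts.append(".")
    if both_over_half:
        parts.append(
            " Death was more probable than not regardless of restraint use: the "
            "estimated risk exceeds 50% for both the belted and unbelted scenario, "
            "so the crash was not survivable on a more-likely-than-not basis either way."
        )
    return CausalQuantification(
        p_unbelted=e1,
        p_belted=e0,
        rr=rr,
        ar_percent=ar,
        abs_diff=diff,
        significance=significance,
        ci_overlap=ci_overlap,
        gate_passed=gate,
        apportionment=apportionment,
        framing=framing,
        protective=protective,
        survivable_regardless=both_over_half,
        narrative="".join(parts),
    )


def quantify_from_estimates(
    e1: RiskEstimate,
    e0: RiskEstimate,
    framing: str = "contributory-negligence",
    significance_method: str = "wald_difference",
) -> CausalQuantification:
    """Run the two-stage decision on a pair of risk estimates directly."""
    governing = assess_significance(e1, e0, significance_method)
    overlap = assess_significance(e1, e0, "ci_overlap")
    return _decide(e1, e0, governing, overlap, framing)


def quantify_case(
    fit: FittedRiskModel,
    case: CaseSpec,
    framing: str = "contributory-negligence",
    significance_method: str = "wald_difference",
) -> CausalQuantification:
    """Evaluate the litigated case against the fitted risk model.

    Predicts the outcome risk at the case's crash profile under both belt
    states, then applies the two-stage rule: the AR > 50% gate with a
    significance requirement, followed (only on passing) by apportionment
    of the absolute risk difference.
    """
    if not fit.converged:
        raise NotConvergedError("risk model did not converge; case quantification refused")
    e1 = predict_risk(fit, case.profile("not_used"))
    e0 = predict_risk(fit, case.profile("used"))
    return quantify_from_estimates(e1, e0, framing=framing, significance_method=significance_method)
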