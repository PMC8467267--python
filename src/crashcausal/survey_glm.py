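"""Design-based weighted logistic regression for crash death-risk curves.

The model is the standard pseudo-maximum-likelihood estimator for binary
outcomes under a complex sampling design: coefficients maximise the
sampling-weighted binomial log-likelihood

    l(beta) = sum_i w_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ],
    logit p_i = x_i' beta,

fitted by iteratively reweighted least squares (Newton-Raphson with the
expected information).  Weights are sampling weights, never frequency
weights: they enter the score, but uncertainty comes from the
Taylor-linearization (sandwich) estimator

    V = A^{-1} B A^{-1},
    A = sum_i w_i p_i (1 - p_i) x_i x_i',

where B is the between-PSU variance of weighted score totals pooled within
strata, with the customary with-replacement first-stage approximation:

    B = sum_h n_h / (n_h - 1) * sum_j (z_hj - zbar_h)(z_hj - zbar_h)',

z_hj being the total of w_i (y_i - p_i) x_i over PSU j of stratum h.  This
is the same variance machinery survey packages (SAS SURVEYLOGISTIC, R
``survey``) use for stratified multistage crash samples.

Risk estimates at covariate profiles carry delta-method confidence
intervals computed on the logit scale and transformed, which guarantees
the interval stays inside [0, 1] and brackets the point estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import DomainError, NotConvergedError, SeparationError
from .injury import parse_injury_code
from .records import SurveyDesign

__all__ = [
    "ModelSpec",
    "FittedRiskModel",
    "RiskEstimate",
    "fit_weighted_logistic",
    "predict_risk",
    "risk_curve",
    "outcome_vector",
    "Z95",
]

#: Normal quantile for two-sided 95% intervals.
Z95 = 1.959964

_MAX_ITER = 100
_TOL = 1e-8
_RIDGE = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """Terms of the death-risk model.

    Delta V and the belt indicator are always present (they are the two
    variables of interest); airbag deployment, vehicle body type and model
    year are case-matching covariates.  The delta V x belt interaction is
    on by default so the belted and unbelted risk curves may cross, which a
    main-effects-only logistic model cannot produce.
    """

    outcome: object = "death_30day"
    include_airbag: bool = True
    include_body_type: bool = True
    include_model_year: bool = True
    interaction_dv_belt: bool = True
    quadratic_dv: bool = False
    model_year_center: float = 2005.0

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "include_airbag": self.include_airbag,
            "include_body_type": self.include_body_type,
            "include_model_year": self.include_model_year,
            "interaction_dv_belt": self.interaction_dv_belt,
            "quadratic_dv": self.quadratic_dv,
            "model_year_center": self.model_year_center,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if isinstance(d.get("outcome"), list):
            d["outcome"] = tuple(d["outcome"])
        return cls(**d)


@dataclass(frozen=True)
class RiskEstimate:
    """Probability of the outcome at a profile, with design-based uncertainty."""

    p: float
    se_logit: float
    ci95: tuple[float, float]
    extrapolated: bool = False

    def __post_init__(self):
        lo, hi = self.ci95
        if not (0.0 <= lo <= hi <= 1.0) or not (0.0 <= self.p <= 1.0):
            raise DomainError(f"CI ({lo}, {hi}) and p={self.p} must lie ordered in [0, 1]")
        # absorb round-off from the logit<->probability transform: the interval
        # must bracket the point estimate by contract
        object.__setattr__(self, "ci95", (min(lo, self.p), max(hi, self.p)))

    @property
    def se_p(self) -> float:
        """Delta-method standard error on the probability scale."""
        return self.se_logit * self.p * (1.0 - self.p)

    def to_dict(self) -> dict:
        return {
            "p": self.p,
            "se_logit": self.se_logit,
            "ci95": list(self.ci95),
            "extrapolated": self.extrapolated,
        }


@dataclass
class FittedRiskModel:
    """Pseudo-MLE logistic coefficients with a design-based covariance."""

    coefficients: np.ndarray
    covariance: np.ndarray
    term_names: list[str]
    spec: ModelSpec
    design: SurveyDesign
    converged: bool
    n_iter: int
    n_used: int
    weighted_n: float
    body_type_levels: tuple[str, ...] = ()
    delta_v_range: tuple[float, float] = (0.0, np.inf)
    n_dropped_missing_delta_v: int = 0
    warnings_: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.term_names.index(name)])

    def se(self, name: str) -> float:
        i = self.term_names.index(name)
        return float(np.sqrt(max(self.covariance[i, i], 0.0)))

    def to_dict(self) -> dict:
        return {
            "terms": self.term_names,
            "coefficients": [float(c) for c in self.coefficients],
            "covariance": [[float(v) for v in row] for row in self.covariance],
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_used": self.n_used,
            "weighted_n": self.weighted_n,
            "n_dropped_missing_delta_v": self.n_dropped_missing_delta_v,
            "model_spec": self.spec.to_dict(),
            "body_type_levels": list(self.body_type_levels),
            "delta_v_range": list(self.delta_v_range),
            "design": {s: list(p) for s, p in self.design.psus_by_stratum.items()},
            "warnings": list(self.warnings_),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedRiskModel":
        """Rebuild a fitted model from its JSON form (for staged pipelines)."""
        psus_by_stratum = {s: tuple(p) for s, p in d.get("design", {}).items()}
        if not psus_by_stratum:
            psus_by_stratum = {"S": ("PSU",)}
        design = SurveyDesign(
            strata=tuple(sorted(psus_by_stratum)), psus_by_stratum=psus_by_stratum
        )
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            covariance=np.asarray(d["covariance"], dtype=float),
            term_names=list(d["terms"]),
            spec=ModelSpec.from_dict(d["model_spec"]),
            design=design,
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
            n_used=int(d["n_used"]),
            weighted_n=float(d["weighted_n"]),
            body_type_levels=tuple(d.get("body_type_levels", ())),
            delta_v_range=tuple(d.get("delta_v_range", (0.0, np.inf))),
            n_dropped_missing_delta_v=int(d.get("n_dropped_missing_delta_v", 0)),
            warnings_=list(d.get("warnings", [])),
        )


def outcome_vector(df: pd.DataFrame, outcome) -> np.ndarray:
    """Binary outcome per record: 30-day death, or max AIS at/above a cut."""
    if outcome == "death_30day":
        return df["died_30day"].to_numpy(dtype=float)
    if isinstance(outcome, (tuple, list)) and len(outcome) == 2 and outcome[0] == "max_ais_ge_k":
        k = int(outcome[1])

        def _max_ais_row(cell) -> int:
            if pd.isna(cell) or not str(cell):
                return 0
            sev = [parse_injury_code(c).ais_severity for c in str(cell).split(";") if c]
            sev = [s for s in sev if s != 7]
            return max(sev, default=0)

        return (df["injury_codes"].map(_max_ais_row) >= k).to_numpy(dtype=float)
    raise DomainError(f"unrecognised outcome definition {outcome!r}")


def _design_row(
    profile: dict, spec: ModelSpec, body_type_levels: Sequence[str]
) -> np.ndarray:
    dv = float(profile["delta_v_mph"])
    unbelted = 1.0 if profile["belt_used"] == "not_used" else 0.0
    cols = [1.0, dv, unbelted]
    if spec.interaction_dv_belt:
        cols.append(dv * unbelted)
    if spec.quadratic_dv:
        cols.append(dv * dv)
    if spec.include_airbag:
        cols.append(1.0 if profile["airbag_deployed"] == "deployed" else 0.0)
    if spec.include_body_type:
        for level in body_type_levels[1:]:
            cols.append(1.0 if profile["body_type"] == level else 0.0)
    if spec.include_model_year:
        cols.append(float(profile["model_year"]) - spec.model_year_center)
    return np.asarray(cols, dtype=float)


def _design_matrix(
    df: pd.DataFrame, spec: ModelSpec, body_type_levels: Optional[Sequence[str]] = None
) -> tuple[np.ndarray, list[str], tuple[str, ...]]:
    dv = df["delta_v_mph"].to_numpy(dtype=float)
    unbelted = (df["belt_used"] == "not_used").to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones(len(df)), dv, unbelted]
    names = ["intercept", "delta_v", "unbelted"]
    if spec.interaction_dv_belt:
        cols.append(dv * unbelted)
        names.append("delta_v:unbelted")
    if spec.quadratic_dv:
        cols.append(dv * dv)
        names.append("delta_v_sq")
    if spec.include_airbag:
        cols.append((df["airbag_deployed"] == "deployed").to_numpy(dtype=float))
        names.append("airbag_deployed")
    if spec.include_body_type:
        if body_type_levels is None:
            body_type_levels = tuple(sorted(df["body_type"].astype(str).unique()))
        for level in body_type_levels[1:]:
            cols.append((df["body_type"] == level).to_numpy(dtype=float))
            names.append(f"body_type[{level}]")
    else:
        body_type_levels = ()
    if spec.include_model_year:
        cols.append(df["model_year"].to_numpy(dtype=float) - spec.model_year_center)
        names.append("model_year_c")
    return np.column_stack(cols), names, tuple(body_type_levels or ())


def _sandwich_meat(
    X: np.ndarray, resid_w: np.ndarray, strata: np.ndarray, psus: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Between-PSU covariance of weighted score totals, pooled within strata."""
    k = X.shape[1]
    scores = X * resid_w[:, None]  # w_i (y_i - p_i) x_i
    totals = pd.DataFrame(scores).groupby([strata, psus], sort=False).sum()
    B = np.zeros((k, k))
    notes: list[str] = []
    stratum_of_cluster = totals.index.get_level_values(0)
    for stratum in pd.unique(stratum_of_cluster):
        Z = totals.loc[stratum_of_cluster == stratum].to_numpy()
        n_h = Z.shape[0]
        if n_h < 2:
            # a lone PSU contributes no between-PSU spread; its score total is
            # centred at the stratum mean (itself), i.e. a zero contribution
            notes.append(
                f"stratum {stratum!r} has a single PSU; its variance contribution "
                "is zero (centered-at-stratum-mean fallback)"
            )
            continue
        D = Z - Z.mean(axis=0, keepdims=True)
        B += (n_h / (n_h - 1)) * (D.T @ D)
    return B, notes


def fit_weighted_logistic(
    cohort: pd.DataFrame,
    spec: Optional[ModelSpec] = None,
    design: Optional[SurveyDesign] = None,
) -> FittedRiskModel:
    """Fit the survey-weighted logistic death-risk model.

    Rows with missing delta V are dropped here (and counted in
    ``n_dropped_missing_delta_v``); the cohort filter deliberately leaves
    them in so the exclusion is visible at the modelling stage.

    Raises
    ------
    DomainError
        If the fitted rows lack both outcome classes or both belt states.
    SeparationError
        On (quasi-)complete separation, naming the runaway term.
    """
    spec = spec or ModelSpec()
    fit_warnings: list[str] = []

    usable = cohort["delta_v_mph"].notna()
    n_dropped = int((~usable).sum())
    if n_dropped:
        fit_warnings.append(f"dropped {n_dropped} record(s) with missing delta V at fit time")
    df = cohort.loc[usable]
    if df.empty:
        raise DomainError("no records with known delta V to fit")

    y = outcome_vector(df, spec.outcome)
    if y.min() == y.max():
        raise DomainError("cohort contains a single outcome class; logistic fit undefined")
    belts = set(df["belt_used"].unique())
    if not {"used", "not_used"} <= belts:
        raise DomainError(f"cohort must contain both belt states, found {sorted(belts)}")

    X, names, bt_levels = _design_matrix(df, spec)
    w = df["weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise DomainError("all sampling weights must be positive")

    # IRLS on the weighted pseudo-likelihood
    k = X.shape[1]
    beta = np.zeros(k)
    pbar = np.average(y, weights=w)
    beta[0] = logit(min(max(pbar, 1e-6), 1 - 1e-6))
    converged = False
    n_iter = 0
    for n_iter in range(1, _MAX_ITER + 1):
        eta = X @ beta
        p = expit(eta)
        wk = w * p * (1.0 - p)
        A = (X * wk[:, None]).T @ X
        g = X.T @ (w * (y - p))
        try:
            step = np.linalg.solve(A, g)
        except np.linalg.LinAlgError:
            fit_warnings.append(f"singular information matrix; ridge {_RIDGE} applied")
            step = np.linalg.solve(A + _RIDGE * np.eye(k), g)
        beta = beta + step
        if np.max(np.abs(step)) <= _TOL * max(1.0, np.max(np.abs(beta))):
            converged = True
            break

    if np.max(np.abs(beta[1:])) > 50.0 or (not converged and np.max(np.abs(beta)) > 50.0):
        runaway = int(np.argmax(np.abs(beta[1:]))) + 1
        raise SeparationError(names[runaway])

    eta = X @ beta
    p = expit(eta)
    wk = w * p * (1.0 - p)
    A = (X * wk[:, None]).T @ X
    strata = df["stratum"].astype(str).to_numpy()
    psus = df["psu"].astype(str).to_numpy()
    B, notes = _sandwich_meat(X, w * (y - p), strata, psus)
    for note in notes:
        warnings.warn(note, stacklevel=2)
    fit_warnings.extend(notes)
    Ainv = np.linalg.pinv(A)
    V = Ainv @ B @ Ainv
    V = 0.5 * (V + V.T)  # enforce symmetry against round-off

    if design is None:
        design = SurveyDesign.from_frame(df)
    dv = df["delta_v_mph"].to_numpy(dtype=float)
    return FittedRiskModel(
        coefficients=beta,
        covariance=V,
        term_names=names,
        spec=spec,
        design=design,
        converged=converged,
        n_iter=n_iter,
        n_used=len(df),
        weighted_n=float(w.sum()),
        body_type_levels=bt_levels,
        delta_v_range=(float(dv.min()), float(dv.max())),
        n_dropped_missing_delta_v=n_dropped,
        warnings_=fit_warnings,
    )


def predict_risk(fit: FittedRiskModel, profile: dict) -> RiskEstimate:
    """Outcome probability at a covariate profile with a 95% CI.

    The interval is computed on the logit scale by the delta method and
    transformed back, so it always lies inside [0, 1].  Profiles whose
    delta V falls outside the fitted support are flagged as extrapolated
    (with a warning) but still evaluated.
    """
    if not fit.converged:
        raise NotConvergedError(
            f"model did not converge in {fit.n_iter} iterations; refusing to predict"
        )
    x = _design_row(profile, fit.spec, fit.body_type_levels)
    eta = float(x @ fit.coefficients)
    var = float(x @ fit.covariance @ x)
    se = float(np.sqrt(max(var, 0.0)))
    p = float(expit(eta))
    lo = float(expit(eta - Z95 * se))
    hi = float(expit(eta + Z95 * se))
    dv = float(profile["delta_v_mph"])
    extrapolated = not (fit.delta_v_range[0] <= dv <= fit.delta_v_range[1])
    if extrapolated:
        warnings.warn(
            f"profile delta V {dv} mph is outside the fitted support "
            f"{fit.delta_v_range}; estimate is an extrapolation",
            stacklevel=2,
        )
    return RiskEstimate(p=p, se_logit=se, ci95=(lo, hi), extrapolated=extrapolated)


def risk_curve(
    fit: FittedRiskModel,
    profile_base: dict,
    delta_v_grid: Iterable[float],
    belt_states: Sequence[str] = ("used", "not_used"),
) -> pd.DataFrame:
    """Risk-by-delta-V table for each belt state (the plotting-ready curve).

    Columns: ``delta_v_mph, belt_state, p, se_logit, ci_low, ci_high``.
    """
    grid = [float(v) for v in delta_v_grid]
    if not grid:
        raise DomainError("delta V grid is empty")
    if any(b - a < 0 for a, b in zip(grid, grid[1:])):
        raise DomainError("delta V grid must be ascending")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # grid edges may extrapolate; flag kept per-row
        for belt in belt_states:
            for dv in grid:
                profile = dict(profile_base, delta_v_mph=dv, belt_used=belt)
                est = predict_risk(fit, profile)
                rows.append(
                    {
                        "delta_v_mph": dv,
                        "belt_state": belt,
                        "p": est.p,
                        "se_logit": est.se_logit,
                        "ci_low": est.ci95[0],
                        "ci_high": est.ci95[1],
                    }
                )
    return pd.DataFrame(rows)
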