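"""Weighted logistic fitter: oracle equivalence, variance behaviour, risk curves."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from crashcausal.cohort import CohortSpec, apply_cohort_spec
from crashcausal.errors import DomainError, NotConvergedError, SeparationError
from crashcausal.simulate import GeneratorParams, simulate_sample
from crashcausal.survey_glm import (
    FittedRiskModel,
    ModelSpec,
    RiskEstimate,
    fit_weighted_logistic,
    outcome_vector,
    predict_risk,
    risk_curve,
)

SIMPLE_SPEC = ModelSpec(
    include_airbag=True,
    include_body_type=False,
    include_model_year=False,
    interaction_dv_belt=False,
)

BASE_PROFILE = {
    "delta_v_mph": 30.0,
    "belt_used": "used",
    "airbag_deployed": "not_deployed",
    "body_type": "car",
    "model_year": 2008,
}


def _random_frame(n=150, seed=0, equal_weight=True):
    rng = np.random.default_rng(seed)
    dv = rng.gamma(3.0, 7.0, size=n)
    unbelted = rng.random(n) < 0.35
    airbag = rng.random(n) < 0.3
    eta = -3.0 + 0.09 * dv + 0.6 * unbelted - 0.2 * airbag
    died = rng.random(n) < expit(eta)
    return pd.DataFrame(
        {
            "record_id": [f"r{i}" for i in range(n)],
            "year": 2010,
            "delta_v_mph": dv,
            "pdof_deg": 300.0,
            "belt_used": np.where(unbelted, "not_used", "used"),
            "airbag_deployed": np.where(airbag, "deployed", "not_deployed"),
            "rollover": False,
            "ejected": False,
            "role": "driver",
            "body_type": "car",
            "model_year": 2008,
            "died_30day": died,
            "injury_codes": "",
            "weight": 1.0 if equal_weight else rng.uniform(1, 20, size=n),
            "stratum": "S0",
            "psu": [f"P{i}" for i in range(n)],  # each row its own PSU
        }
    )


class TestFitterOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equal_weight_fit_matches_statsmodels(self, seed):
        df = _random_frame(n=180, seed=seed)
        fit = fit_weighted_logistic(df, SIMPLE_SPEC)
        X = np.column_stack(
            [
                np.ones(len(df)),
                df["delta_v_mph"],
                (df["belt_used"] == "not_used").astype(float),
                (df["airbag_deployed"] == "deployed").astype(float),
            ]
        )
        oracle = sm.GLM(df["died_30day"].astype(float), X, family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.coefficients - oracle.params)) < 1e-6

    def test_halved_weight_duplication_leaves_coefficients_unchanged(self):
        df = _random_frame(n=120, seed=3)
        fit_a = fit_weighted_logistic(df, SIMPLE_SPEC)
        doubled = pd.concat([df, df], ignore_index=True)
        doubled["weight"] = 0.5
        doubled["record_id"] = [f"d{i}" for i in range(len(doubled))]
        fit_b = fit_weighted_logistic(doubled, SIMPLE_SPEC)
        assert np.allclose(fit_a.coefficients, fit_b.coefficients, atol=1e-8)

    def test_weighted_fit_matches_statsmodels_var_weights(self):
        df = _random_frame(n=200, seed=4, equal_weight=False)
        fit = fit_weighted_logistic(df, SIMPLE_SPEC)
        X = np.column_stack(
            [
                np.ones(len(df)),
                df["delta_v_mph"],
                (df["belt_used"] == "not_used").astype(float),
                (df["airbag_deployed"] == "deployed").astype(float),
            ]
        )
        oracle = sm.GLM(
            df["died_30day"].astype(float),
            X,
            family=sm.families.Binomial(),
            var_weights=df["weight"].to_numpy(),
        ).fit()
        assert np.max(np.abs(fit.coefficients - oracle.params)) < 1e-6


class TestFitterGuards:
    def test_single_outcome_class_rejected(self):
        df = _random_frame(n=50, seed=5)
        df["died_30day"] = False
        with pytest.raises(DomainError, match="outcome class"):
            fit_weighted_logistic(df, SIMPLE_SPEC)

    def test_single_belt_state_rejected(self):
        df = _random_frame(n=50, seed=6)
        df["belt_used"] = "used"
        with pytest.raises(DomainError, match="belt"):
            fit_weighted_logistic(df, SIMPLE_SPEC)

    def test_complete_separation_names_term(self):
        df = _random_frame(n=80, seed=7)
        df["died_30day"] = df["belt_used"] == "not_used"  # belt separates perfectly
        with pytest.raises(SeparationError) as err:
            fit_weighted_logistic(df, SIMPLE_SPEC)
        assert "unbelted" in str(err.value)

    def test_missing_delta_v_dropped_and_counted(self):
        df = _random_frame(n=100, seed=8)
        df.loc[:9, "delta_v_mph"] = np.nan
        fit = fit_weighted_logistic(df, SIMPLE_SPEC)
        assert fit.n_dropped_missing_delta_v == 10
        assert fit.n_used == 90

    def test_single_psu_stratum_warns_and_still_fits(self):
        df = _random_frame(n=100, seed=9)
        df["stratum"] = np.where(np.arange(len(df)) < 10, "LONE", "S0")
        df.loc[df["stratum"] == "LONE", "psu"] = "ONLY"
        with pytest.warns(UserWarning, match="single PSU"):
            fit = fit_weighted_logistic(df, SIMPLE_SPEC)
        assert fit.converged


class TestSandwichVariance:
    def test_reduces_to_model_based_variance_under_iid_equal_weights(self):
        # one PSU per record, equal weights, correctly specified model:
        # the sandwich should agree with inverse-information within 25%
        rng = np.random.default_rng(10)
        ratios = []
        for seed in range(8):
            df = _random_frame(n=2000, seed=100 + seed)
            fit = fit_weighted_logistic(df, SIMPLE_SPEC)
            X = np.column_stack(
                [
                    np.ones(len(df)),
                    df["delta_v_mph"],
                    (df["belt_used"] == "not_used").astype(float),
                    (df["airbag_deployed"] == "deployed").astype(float),
                ]
            )
            p = expit(X @ fit.coefficients)
            info = (X * (p * (1 - p))[:, None]).T @ X
            model_var = np.diag(np.linalg.inv(info))
            ratios.append(np.diag(fit.covariance) / model_var)
        mean_ratio = np.mean(ratios, axis=0)
        assert np.all(mean_ratio > 0.75) and np.all(mean_ratio < 1.25)


@pytest.fixture(scope="module")
def fitted():
    df = _random_frame(n=400, seed=11)
    return fit_weighted_logistic(df, SIMPLE_SPEC)


class TestPredictRisk:
    def test_probability_half_at_zero_linear_predictor(self, fitted):
        # solve for the delta V at which the belted linear predictor vanishes
        b = fitted.coefficients
        dv0 = -b[0] / b[1]
        est = predict_risk(fitted, dict(BASE_PROFILE, delta_v_mph=dv0))
        assert est.p == pytest.approx(0.5, abs=1e-12)

    def test_zero_covariance_degenerates_ci_to_point(self, fitted):
        from dataclasses import replace

        degenerate = replace(fitted, covariance=np.zeros_like(fitted.covariance))
        est = predict_risk(degenerate, BASE_PROFILE)
        assert est.ci95 == (est.p, est.p)

    def test_ci_brackets_point_inside_unit_interval(self, fitted):
        est = predict_risk(fitted, BASE_PROFILE)
        assert 0.0 <= est.ci95[0] <= est.p <= est.ci95[1] <= 1.0

    def test_extrapolation_flagged_outside_support(self, fitted):
        with pytest.warns(UserWarning, match="extrapolation"):
            est = predict_risk(fitted, dict(BASE_PROFILE, delta_v_mph=500.0))
        assert est.extrapolated

    def test_refuses_unconverged_fit(self, fitted):
        from dataclasses import replace

        broken = replace(fitted, converged=False)
        with pytest.raises(NotConvergedError):
            predict_risk(broken, BASE_PROFILE)

    def test_consistency_with_generator_truth_at_case_profile(self):
        # large-sample fitted risk lands within 2 design SEs of the exact
        # mechanism risk at a 56 mph profile
        from crashcausal.simulate import true_risk

        params = GeneratorParams(seed=17)
        sample, _, _ = simulate_sample(params)
        cohort, _ = apply_cohort_spec(sample, CohortSpec(pdof_window=((10, 0), (2, 0))))
        fit = fit_weighted_logistic(
            cohort, ModelSpec(include_body_type=False, include_model_year=False)
        )
        for belt in ("used", "not_used"):
            est = predict_risk(
                fit,
                dict(BASE_PROFILE, delta_v_mph=56.0, belt_used=belt, airbag_deployed="deployed"),
            )
            truth = true_risk(params, {"delta_v": 56.0, "belt": belt, "airbag": "deployed"})
            assert abs(est.p - truth) <= 2 * max(est.se_p, 1e-6)


class TestRiskCurve:
    def test_grid_cardinality(self, fitted):
        curve = risk_curve(fitted, BASE_PROFILE, np.arange(30.0, 81.0, 1.0))
        assert len(curve) == 102  # 51 grid points x 2 belt states

    def test_monotone_when_slope_positive(self, fitted):
        assert fitted.coef("delta_v") > 0
        curve = risk_curve(fitted, BASE_PROFILE, np.arange(10.0, 81.0, 1.0))
        for _, grp in curve.groupby("belt_state"):
            assert (np.diff(grp["p"].to_numpy()) >= -1e-15).all()

    def test_curves_coincide_under_null_belt_coefficient(self, fitted):
        from dataclasses import replace

        b = fitted.coefficients.copy()
        b[fitted.term_names.index("unbelted")] = 0.0
        nulled = replace(fitted, coefficients=b)
        curve = risk_curve(nulled, BASE_PROFILE, [20.0, 40.0, 60.0])
        belted = curve[curve["belt_state"] == "used"]["p"].to_numpy()
        unbelted = curve[curve["belt_state"] == "not_used"]["p"].to_numpy()
        assert np.allclose(belted, unbelted)

    def test_empty_or_descending_grid_rejected(self, fitted):
        with pytest.raises(DomainError):
            risk_curve(fitted, BASE_PROFILE, [])
        with pytest.raises(DomainError):
            risk_curve(fitted, BASE_PROFILE, [50.0, 40.0])


class TestOutcomeAndSerialisation:
    def test_ais_threshold_outcome(self):
        df = _random_frame(n=4, seed=13)
        df["injury_codes"] = ["1111113;2222221", "1111112", "", "1111117"]
        y = outcome_vector(df, ("max_ais_ge_k", 3))
        assert list(y) == [1.0, 0.0, 0.0, 0.0]

    def test_fit_round_trips_through_json_dict(self):
        df = _random_frame(n=150, seed=14)
        fit = fit_weighted_logistic(df, SIMPLE_SPEC)
        back = FittedRiskModel.from_dict(fit.to_dict())
        est_a = predict_risk(fit, BASE_PROFILE)
        est_b = predict_risk(back, BASE_PROFILE)
        assert est_a.p == pytest.approx(est_b.p, rel=1e-12)
        assert est_a.se_logit == pytest.approx(est_b.se_logit, rel=1e-12)
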