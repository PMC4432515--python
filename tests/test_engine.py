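"""Single-study simulation: logistic fits, conclusions, determinism."""

import numpy as np
import pytest
from scipy import optimize, special

from confsim import (
    ConfoundingScenario,
    ReplicateResult,
    SimulationConfig,
    ValidationError,
    classify_conclusion,
    fit_logistic,
    run_cell,
    run_replicate,
)


def direct_ml_fit(y, X_with_const):
    """Independent oracle: minimize the negative log-likelihood numerically."""

    def nll(beta):
        eta = X_with_const @ beta
        return np.sum(np.logaddexp(0.0, eta)) - y @ eta

    res = optimize.minimize(nll, np.zeros(X_with_const.shape[1]), method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
    return res.x


class TestFitLogistic:
    def test_coefficients_match_direct_likelihood_optimizer(self, rng):
        n = 300
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(size=n)
        eta = -0.5 + 0.8 * x1 + 1.2 * x2
        y = (rng.random(n) < special.expit(eta)).astype(float)
        X = np.column_stack([x1, x2])
        coef, se, pvals, converged = fit_logistic(y, X)
        assert converged
        oracle = direct_ml_fit(y, np.column_stack([np.ones(n), X]))
        np.testing.assert_allclose(coef, oracle, atol=1e-4)
        assert np.all(se > 0) and np.all((pvals >= 0) & (pvals <= 1))

    def test_perfect_separation_flagged_not_raised(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        x = np.column_stack([y.copy(), np.random.default_rng(0).normal(size=20)])
        *_, converged = fit_logistic(y, x)
        assert not converged

    def test_zero_variance_covariate_rejected(self):
        y = np.array([0.0, 1.0] * 10)
        with pytest.raises(ValidationError):
            fit_logistic(y, np.zeros((20, 1)))

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic(np.ones(20), np.random.default_rng(0).normal(size=(20, 1)))


class TestRunReplicate:
    def test_deterministic_given_seed_and_index(self, unimodal, high_scenario):
        cfg = SimulationConfig(
            population=unimodal, scenario=high_scenario, true_or=0.8, n=500,
            adjuster_sigma=0.5, reps=1, seed=42,
        )
        r1 = run_replicate(cfg, 7)
        r2 = run_replicate(cfg, 7)
        assert r1 == r2
        assert r1 != run_replicate(cfg, 8)

    def test_matches_independent_ml_fit_on_reconstructed_data(self, unimodal, low_scenario):
        # rebuild the replicate's data from its substream and fit with the
        # direct optimizer; the engine's measured OR must agree
        from confsim._rng import substream
        from confsim.adjuster import generate_adjuster
        from confsim.confounding import assign_treatment
        from confsim.population import sample_cohort
        from confsim.treatment import apply_odds_ratio

        cfg = SimulationConfig(
            population=unimodal, scenario=low_scenario, true_or=0.8, n=200,
            adjuster_sigma=0.4, reps=1, seed=11,
        )
        result = run_replicate(cfg, 0)
        assert result.converged

        rng = substream(11, 0)
        cohort = sample_cohort(unimodal, 200, rng)
        score = generate_adjuster(cohort, 0.4, rng)
        treat = assign_treatment(cohort, low_scenario, rng)
        risk = np.where(treat == 1, apply_odds_ratio(cohort.baseline_risk, 0.8),
                        cohort.baseline_risk)
        died = (rng.random(200) < risk).astype(float)
        X = np.column_stack([np.ones(200), treat, score])
        oracle = direct_ml_fit(died, X)
        assert result.measured_or == pytest.approx(np.exp(oracle[1]), abs=1e-4)
        assert result.deaths == int(died.sum())
        assert result.treated == int(treat.sum())

    def test_unadjusted_replicate_has_no_realized_auroc(self, unimodal, low_scenario):
        cfg = SimulationConfig(
            population=unimodal, scenario=low_scenario, true_or=1.0, n=300,
            adjuster_sigma=None, target_auroc="unadjusted", reps=1, seed=13,
        )
        r = run_replicate(cfg, 0)
        assert np.isnan(r.realized_auroc)
        assert r.converged

    def test_unbiased_when_unconfounded_and_perfectly_adjusted(self, unimodal):
        cfg = SimulationConfig(
            population=unimodal, scenario=ConfoundingScenario.none(0.45),
            true_or=0.8, n=1000, adjuster_sigma=0.0, reps=300, seed=14,
        )
        ors = [r.measured_or for r in run_cell(cfg) if r.converged]
        assert np.mean(ors) == pytest.approx(0.8, abs=0.03)

    def test_unadjusted_bias_monotone_in_confounding(self, unimodal):
        means = []
        for scen in (ConfoundingScenario.none(0.45), ConfoundingScenario.low(),
                     ConfoundingScenario.high()):
            cfg = SimulationConfig(
                population=unimodal, scenario=scen, true_or=0.8, n=4000,
                adjuster_sigma=None, target_auroc="unadjusted", reps=100, seed=15,
            )
            means.append(np.mean([r.measured_or for r in run_cell(cfg) if r.converged]))
        assert means[0] < means[1] < means[2]

    def test_config_validation(self, unimodal, low_scenario):
        with pytest.raises(ValidationError):
            SimulationConfig(population=unimodal, scenario=low_scenario, n=50)
        with pytest.raises(ValidationError):
            SimulationConfig(population=unimodal, scenario=low_scenario, alpha=1.5)
        with pytest.raises(ValidationError):
            SimulationConfig(population=unimodal, scenario=low_scenario, true_or=-0.5)


def make_result(measured_or, p_value):
    return ReplicateResult(
        measured_or=measured_or, p_value=p_value, realized_auroc=np.nan,
        deaths=100, treated=100,
        conclusion=("harm" if p_value < 0.05 and measured_or > 1
                    else "benefit" if p_value < 0.05 else "null"),
        converged=True,
    )


class TestClassifyConclusion:
    @pytest.mark.parametrize(
        "measured_or,p,true_or,expected",
        [
            (1.3, 0.01, 1.0, "false_harm"),
            (1.1, 0.20, 0.8, "false_negative"),
            (0.8, 0.001, 0.8, "true_benefit"),
            (1.4, 0.02, 0.6, "false_harm"),
            (0.9, 0.60, 1.0, "true_null"),
            (0.7, 0.01, 1.0, "false_benefit"),
        ],
    )
    def test_label_table(self, measured_or, p, true_or, expected):
        assert classify_conclusion(make_result(measured_or, p), true_or, 0.05) == expected

    def test_every_nondegenerate_replicate_gets_exactly_one_label(self, rng):
        labels = {"false_negative", "false_harm", "true_benefit",
                  "true_null", "false_benefit"}
        for _ in range(200):
            r = make_result(float(np.exp(rng.normal(0, 0.5))), float(rng.random()))
            for true_or in (1.0, 0.8):
                assert classify_conclusion(r, true_or, 0.05) in labels

    def test_degenerate_passthrough(self):
        r = ReplicateResult(np.nan, np.nan, np.nan, 0, 0, "degenerate", False)
        assert classify_conclusion(r, 0.8, 0.05) == "degenerate"
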