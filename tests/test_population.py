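"""Baseline-risk distributions: anchor fits, sampling, intrinsic AUROC."""

import numpy as np
import pytest

from confsim import (
    CalibrationError,
    PopulationModel,
    ValidationError,
    empirical_population,
    estimate_intrinsic_auroc,
    fit_bimodal,
    fit_unimodal,
    sample_cohort,
)
from confsim._rng import substream


class TestUnimodalFit:
    def test_anchor_quantiles_within_tolerance(self, unimodal):
        for level, risk in ((0.10, 0.15), (0.50, 0.35), (0.90, 0.75)):
            assert unimodal.quantile(level) == pytest.approx(risk, abs=0.02)

    def test_quantile_cdf_round_trip(self, unimodal):
        for q in np.arange(0.1, 0.95, 0.1):
            assert unimodal.cdf(unimodal.quantile(q)) == pytest.approx(q, abs=1e-6)

    def test_two_anchor_fit_is_exact(self):
        # two anchors generated from a known Beta are matched with zero error
        from scipy import stats

        a, b = 2.0, 3.0
        anchors = [(0.10, stats.beta.ppf(0.10, a, b)), (0.90, stats.beta.ppf(0.90, a, b))]
        model = fit_unimodal(anchors)
        for level, risk in anchors:
            assert model.quantile(level) == pytest.approx(risk, abs=1e-4)

    def test_invalid_anchors_rejected(self):
        with pytest.raises(ValidationError):
            fit_unimodal([(0.10, 0.5), (0.50, 0.3)])  # non-monotone risk
        with pytest.raises(ValidationError):
            fit_unimodal([(0.10, 0.15)])  # single anchor


class TestSampling:
    def test_draws_strictly_inside_unit_interval(self, unimodal, rng):
        cohort = sample_cohort(unimodal, 50_000, rng)
        assert cohort.n == 50_000
        assert np.all(cohort.baseline_risk > 0) and np.all(cohort.baseline_risk < 1)

    def test_same_stream_state_reproduces_cohort(self, unimodal):
        c1 = sample_cohort(unimodal, 1000, substream(99, 3))
        c2 = sample_cohort(unimodal, 1000, substream(99, 3))
        np.testing.assert_array_equal(c1.baseline_risk, c2.baseline_risk)

    def test_empirical_quantiles_converge_to_model(self, unimodal, rng):
        r = unimodal.sample(400_000, rng)
        for q in (0.1, 0.5, 0.9):
            assert np.quantile(r, q) == pytest.approx(unimodal.quantile(q), abs=0.01)

    def test_tiny_cohort_rejected(self, unimodal, rng):
        with pytest.raises(ValidationError):
            sample_cohort(unimodal, 1, rng)


class TestIntrinsicAUROC:
    def test_no_discrimination_when_risk_constant(self, rng):
        model = empirical_population(np.full(100, 0.5))
        assert estimate_intrinsic_auroc(model, 20_000, rng) == 0.5

    def test_two_point_population_matches_closed_form(self, rng):
        # equal mass at risks 0.01 and 0.99: expected concordance is
        # [r_hi(1-r_lo) + 0.5(r_hi(1-r_hi) + r_lo(1-r_lo))] / (4 pbar (1-pbar))
        r_lo, r_hi = 0.01, 0.99
        num = 0.25 * r_hi * (1 - r_lo) + 0.5 * 0.25 * (
            r_hi * (1 - r_hi) + r_lo * (1 - r_lo)
        )
        expected = num / (0.5 * 0.5)
        model = empirical_population(np.array([r_lo, r_hi]).repeat(50))
        est = estimate_intrinsic_auroc(model, 100_000, rng)
        assert est == pytest.approx(expected, abs=0.01)

    def test_stable_across_seeds(self, unimodal):
        vals = [
            estimate_intrinsic_auroc(unimodal, 100_000, substream(s, 0)) for s in (1, 2, 3)
        ]
        assert max(vals) - min(vals) < 0.005
        assert all(0.5 < v < 1 for v in vals)

    def test_logit_scale_spread_does_not_decrease_auroc(self, rng):
        # mean-preserving spread of logit(risk): wider spread separates
        # deaths from survivors at least as well
        from scipy.special import expit

        narrow = empirical_population(expit(rng.normal(-0.5, 0.8, 30_000)))
        wide = empirical_population(expit(rng.normal(-0.5, 1.6, 30_000)))
        a_narrow = estimate_intrinsic_auroc(narrow, 100_000, substream(5, 0))
        a_wide = estimate_intrinsic_auroc(wide, 100_000, substream(5, 1))
        assert a_wide >= a_narrow

    def test_small_mc_sample_rejected(self, unimodal, rng):
        with pytest.raises(ValidationError):
            estimate_intrinsic_auroc(unimodal, 100, rng)


@pytest.fixture(scope="module")
def bimodal():
    return fit_bimodal()


class TestBimodal:
    def test_calibrated_to_target_ceiling(self, bimodal):
        assert 0.84 <= bimodal.intrinsic_auroc <= 0.86

    def test_independent_reestimate_agrees(self, bimodal):
        est = estimate_intrinsic_auroc(bimodal, 200_000, substream(77, 0))
        assert est == pytest.approx(bimodal.intrinsic_auroc, abs=0.01)

    def test_mixture_collapse_equals_single_component(self, rng):
        # identical components: intrinsic AUROC equals the single Beta's
        params = np.array([0.15, 2.0, 4.0, 2.0, 4.0])
        mixture = PopulationModel(family="bimodal-mixture", parameters=params)
        single = PopulationModel(family="unimodal-beta", parameters=np.array([2.0, 4.0]))
        a_mix = estimate_intrinsic_auroc(mixture, 150_000, substream(6, 0))
        a_single = estimate_intrinsic_auroc(single, 150_000, substream(6, 1))
        assert a_mix == pytest.approx(a_single, abs=0.01)

    def test_quantile_cdf_round_trip(self, bimodal):
        for q in (0.1, 0.3, 0.5, 0.7, 0.9):
            assert bimodal.cdf(bimodal.quantile(q)) == pytest.approx(q, abs=1e-6)

    def test_unattainable_target_raises(self):
        # the point-mass floor of the default modes is ~0.77; a target below
        # it cannot be reached by any concentration
        with pytest.raises(CalibrationError):
            fit_bimodal(target_intrinsic_auroc=0.60)


def test_serialization_round_trip(unimodal):
    clone = PopulationModel.from_dict(unimodal.to_dict())
    assert clone.family == unimodal.family
    np.testing.assert_allclose(clone.parameters, unimodal.parameters)
    r1 = clone.sample(100, substream(4, 0))
    r2 = unimodal.sample(100, substream(4, 0))
    np.testing.assert_array_equal(r1, r2)
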