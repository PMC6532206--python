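import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lungcea import (
    DistributionSpec,
    ParameterError,
    SurvivalPoints,
    TransitionBand,
    beta_from_mean_count,
    beta_from_mean_variance,
    gamma_from_mean_se,
    load_base_case,
)
from lungcea.parameters import get_value, iter_paths, params_from_dict, params_to_dict, set_value


class TestBetaFromMeanCount:
    def test_published_year1_removal_row(self):
        spec = beta_from_mean_count(0.020, 251)
        assert spec.shape_a == pytest.approx(5.02)
        assert spec.shape_b == pytest.approx(245.98)
        assert spec.point_value == 0.020

    def test_uniform_case(self):
        spec = beta_from_mean_count(0.5, 2)
        assert (spec.shape_a, spec.shape_b) == (1.0, 1.0)

    def test_mean_round_trip_is_identity(self):
        spec = beta_from_mean_count(0.772, 334.95)
        assert spec.mean() == pytest.approx(0.772, abs=1e-12)

    @given(
        mean=st.floats(0.01, 0.99),
        n=st.floats(1.0, 1e4),
    )
    def test_round_trip_property(self, mean, n):
        spec = beta_from_mean_count(mean, n)
        assert spec.mean() == pytest.approx(mean, abs=1e-12)
        assert spec.shape_a + spec.shape_b == pytest.approx(n, rel=1e-12)

    @pytest.mark.parametrize("mean,n", [(-0.1, 10), (1.1, 10), (0.5, 0), (0.5, -3)])
    def test_invalid_inputs(self, mean, n):
        with pytest.raises(ParameterError):
            beta_from_mean_count(mean, n)


class TestBetaFromMeanVariance:
    def test_refit_recovers_published_waitlist_utility(self):
        # moments of Beta(2292.2, 1782.4), then refit
        a, b = 2292.2, 1782.4
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        spec = beta_from_mean_variance(mean, var)
        assert spec.shape_a == pytest.approx(a, rel=1e-3)
        assert spec.shape_b == pytest.approx(b, rel=1e-3)

    def test_symmetry(self):
        spec = beta_from_mean_variance(0.5, 0.05)
        assert spec.shape_a == pytest.approx(spec.shape_b)

    def test_vanishing_variance_concentrates(self):
        spec = beta_from_mean_variance(0.3, 1e-9)
        assert spec.shape_a + spec.shape_b > 1e8

    def test_variance_too_large(self):
        with pytest.raises(ParameterError):
            beta_from_mean_variance(0.5, 0.25)

    @given(mean=st.floats(0.05, 0.95), frac=st.floats(0.01, 0.9))
    def test_fit_moments_fit_idempotent(self, mean, frac):
        var = frac * mean * (1 - mean) * 0.5
        s1 = beta_from_mean_variance(mean, var)
        s2 = beta_from_mean_variance(s1.mean(), s1.variance())
        assert s2.shape_a == pytest.approx(s1.shape_a, rel=1e-9)
        assert s2.shape_b == pytest.approx(s1.shape_b, rel=1e-9)


class TestGammaFromMeanSE:
    def test_round_trip(self):
        spec = gamma_from_mean_se(23829.0, 2345.0)
        refit = gamma_from_mean_se(
            spec.shape_a * spec.shape_b, np.sqrt(spec.shape_a) * spec.shape_b
        )
        assert refit.shape_a == pytest.approx(spec.shape_a, rel=1e-9)
        assert refit.shape_b == pytest.approx(spec.shape_b, rel=1e-9)

    def test_equal_mean_and_se_is_exponential(self):
        assert gamma_from_mean_se(500.0, 500.0).shape_a == pytest.approx(1.0)

    def test_small_se_degenerates_at_mean(self):
        spec = gamma_from_mean_se(1000.0, 1e-3)
        assert spec.shape_a > 1e10
        assert spec.mean() == pytest.approx(1000.0)

    @pytest.mark.parametrize("mean,se", [(0, 1), (-5, 1), (5, 0), (5, -1)])
    def test_invalid_inputs(self, mean, se):
        with pytest.raises(ParameterError):
            gamma_from_mean_se(mean, se)


class TestDistributionSpec:
    def test_invariants_enforced(self):
        with pytest.raises(ParameterError):
            DistributionSpec("beta", -1.0, 2.0, 0.5)
        with pytest.raises(ParameterError):
            DistributionSpec("beta", 2.0, 2.0, 1.5)
        with pytest.raises(ParameterError):
            DistributionSpec("gamma", 2.0, 2.0, -1.0)
        with pytest.raises(ParameterError):
            DistributionSpec("cauchy", 1.0, 1.0, 0.0)

    @pytest.mark.parametrize(
        "path",
        [
            "transitions.year1.p_std_tx",
            "utilities.u_wait",
            "costs.c_wait_per_year",
            "evlp_uplift",
        ],
    )
    def test_sampling_mean_matches_law(self, base, path):
        """10^5 draws land within 3 standard errors of the law's mean."""
        spec = base.psa_specs[path]
        rng = np.random.default_rng(42)
        draws = spec.sample(rng, size=100_000)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - spec.mean()) < 3 * se


class TestBaseCase:
    def test_published_point_values(self, base):
        assert base.transitions["year1"].p_std_tx == 0.510
        assert base.costs.c_tx["evlp"] == 137527
        assert base.utilities.u_tx_post["standard"] == 0.734
        assert base.evlp_uplift == 0.10
        assert base.discount_rate == 0.035
        assert base.conversion_ratio == (53, 18)

    def test_specs_cover_all_uncertain_parameters(self, base):
        # every transition, survival point, utility and cost has a law
        for path in base.psa_specs:
            get_value(base, path)  # path resolves
        assert len(base.psa_specs) == 32

    def test_transplant_slots_mirrored_in_base_case(self, base):
        assert base.psa_specs["survival.evlp.s1"] == base.psa_specs["survival.standard.s1"]
        assert base.utilities.u_tx_year1["evlp"] == base.utilities.u_tx_year1["standard"]


class TestValidation:
    def test_transition_band_bounds(self):
        with pytest.raises(ParameterError):
            TransitionBand(p_removed=0.5, p_death=0.4, p_std_tx=0.2)
        with pytest.raises(ParameterError):
            TransitionBand(p_removed=-0.1, p_death=0.1, p_std_tx=0.1)

    def test_survival_points_monotone(self):
        with pytest.raises(ParameterError):
            SurvivalPoints(s1=0.5, s3=0.6, s5=0.4, s10=0.2)
        with pytest.raises(ParameterError):
            SurvivalPoints(s1=0.8, s3=0.7, s5=0.6, s10=0.5, t_max=9.0)


class TestSerialization:
    def test_round_trip(self, base):
        data = params_to_dict(base)
        back = params_from_dict(data)
        for path in iter_paths(base):
            assert get_value(back, path) == pytest.approx(get_value(base, path))
        assert back.psa_specs == base.psa_specs
        assert back.conversion_ratio == base.conversion_ratio

    def test_set_value_unknown_path(self, base):
        p = base.copy()
        with pytest.raises(ParameterError):
            set_value(p, "costs.nonexistent", 1.0)
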