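import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from arfcea import (
    PARAMETER_NAMES,
    ConfigError,
    DistributionSpec,
    builtin_acute_parameters,
    builtin_nma_parameters,
    dump_config,
    load_parameters,
    mean_draw,
    sample_draw,
    sample_draws,
)


class TestDistributionSpec:
    @pytest.mark.parametrize(
        "family,params,expected_mean",
        [
            ("beta", (9, 26), 9 / 35),
            ("beta", (640, 425), 640 / 1065),
            ("gamma", (80, 40), 3200.0),
            ("gamma", (90, 40), 3600.0),
            ("gamma", (60, 100), 6000.0),
            ("normal", (2.67, 0.16), 2.67),
            ("empirical", (1.0, 2.0, 3.0), 2.0),
        ],
    )
    def test_analytic_mean(self, family, params, expected_mean):
        spec = DistributionSpec("x", family, params)
        assert spec.mean() == pytest.approx(expected_mean)

    @pytest.mark.parametrize(
        "family,params",
        [
            ("beta", (0, 5)),
            ("beta", (-1, 5)),
            ("gamma", (-1, 40)),
            ("gamma", (80,)),
            ("normal", (0, -1)),
            ("empirical", ()),
            ("empirical", (1.0, float("nan"))),
            ("weibull", (1, 1)),
        ],
    )
    def test_invalid_specs_rejected(self, family, params):
        with pytest.raises(ConfigError):
            DistributionSpec("x", family, params)

    @pytest.mark.parametrize(
        "family,params,sd",
        [
            ("beta", (9, 26), math.sqrt(9 * 26 / (35**2 * 36))),
            ("gamma", (80, 40), math.sqrt(80) * 40),
            ("normal", (33, 3.3), 3.3),
        ],
    )
    def test_sample_mean_matches_analytic_mean(self, family, params, sd, rng):
        spec = DistributionSpec("x", family, params)
        n = 100_000
        draws = spec.sample(rng, n)
        assert draws.mean() == pytest.approx(spec.mean(), abs=4 * sd / math.sqrt(n))

    def test_empirical_sampling_uniform_with_replacement(self, rng):
        spec = DistributionSpec("x", "empirical", (1.0, 2.0))
        draws = spec.sample(rng, 10_000)
        assert set(np.unique(draws)) == {1.0, 2.0}
        assert abs((draws == 1.0).mean() - 0.5) < 0.02

    def test_degenerate_normal(self, rng):
        spec = DistributionSpec("c_cpap", "normal", (33, 0))
        assert np.all(spec.sample(rng, 1000) == 33.0)


class TestBuiltinRegistries:
    def test_base_case_registry_as_printed(self, acute_params):
        p = acute_params
        assert (p.p_death0.family, p.p_death0.params) == ("beta", (9.0, 26.0))
        assert (p.p_int0.family, p.p_int0.params) == ("beta", (1.0, 28.0))
        assert (p.logor_death.family, p.logor_death.params) == ("normal", (0.145, 0.521))
        assert (p.logor_int.family, p.logor_int.params) == ("normal", (0.591, 1.403))
        assert (p.life_years.family, p.life_years.params) == ("normal", (2.67, 0.16))
        assert (p.utility.family, p.utility.params) == ("beta", (640.0, 425.0))
        assert (p.c_cpap.family, p.c_cpap.params) == ("normal", (33.0, 3.3))
        assert (p.c_hosp.family, p.c_hosp.params) == ("gamma", (80.0, 40.0))
        assert (p.c_int.family, p.c_int.params) == ("gamma", (90.0, 40.0))
        assert (p.c_annual.family, p.c_annual.params) == ("gamma", (60.0, 100.0))

    def test_base_case_means(self, acute_params):
        assert acute_params.p_death0.mean() == pytest.approx(0.257, abs=5e-4)
        assert acute_params.c_hosp.mean() == pytest.approx(3200)
        assert acute_params.c_int.mean() == pytest.approx(3600)
        assert acute_params.c_annual.mean() == pytest.approx(6000)

    def test_nma_effectiveness_samples(self, nma_params):
        # pseudo-posterior emulation: normal on the log-odds scale with
        # mean ln(OR point) and sd from the 95% credible interval
        spec = nma_params.logor_death
        assert spec.family == "empirical"
        n = len(spec.params)
        assert n == 10_000
        sd_oracle = (math.log(1.4) - math.log(0.2)) / 3.92
        samples = np.asarray(spec.params)
        assert samples.mean() == pytest.approx(
            math.log(0.5), abs=3 * sd_oracle / math.sqrt(n)
        )
        assert samples.std(ddof=1) == pytest.approx(sd_oracle, rel=0.05)

        spec_int = nma_params.logor_int
        sd_int_oracle = (math.log(0.9) - math.log(0.1)) / 3.92
        assert sd_int_oracle == pytest.approx(0.5605, abs=5e-4)
        samples_int = np.asarray(spec_int.params)
        assert samples_int.mean() == pytest.approx(
            math.log(0.4), abs=3 * sd_int_oracle / math.sqrt(n)
        )
        assert samples_int.std(ddof=1) == pytest.approx(sd_int_oracle, rel=0.05)

    def test_nma_other_parameters_unchanged(self, acute_params, nma_params):
        for name in PARAMETER_NAMES:
            if name in ("logor_death", "logor_int"):
                continue
            assert getattr(nma_params, name) == getattr(acute_params, name)

    def test_nma_reproducible_from_seed(self):
        a = builtin_nma_parameters(n_samples=2000, seed=7)
        b = builtin_nma_parameters(n_samples=2000, seed=7)
        c = builtin_nma_parameters(n_samples=2000, seed=8)
        assert a.logor_death.params == b.logor_death.params
        assert a.logor_death.params != c.logor_death.params

    def test_nma_refuses_small_sample(self):
        with pytest.raises(ValueError, match="1000"):
            builtin_nma_parameters(n_samples=500, seed=0)


class TestConfigRoundTrip:
    def test_round_trip_identity(self, acute_params):
        assert load_parameters(dump_config(acute_params)) == acute_params

    def test_missing_parameter_named(self, acute_params):
        text = dump_config(acute_params).replace("c_cpap:", "c_cpap_typo:")
        with pytest.raises(ConfigError, match="c_cpap"):
            load_parameters(text)

    def test_negative_gamma_shape_rejected(self, acute_params):
        text = dump_config(acute_params).replace("- 80.0", "- -1.0")
        with pytest.raises(ConfigError, match="c_hosp"):
            load_parameters(text)

    def test_unknown_family_rejected(self, acute_params):
        text = dump_config(acute_params).replace("family: gamma", "family: cauchy")
        with pytest.raises(ConfigError, match="family"):
            load_parameters(text)

    def test_non_mapping_config_rejected(self):
        with pytest.raises(ConfigError):
            load_parameters("[1, 2, 3]")

    def test_probability_empirical_outside_unit_interval_rejected(self, acute_params):
        text = dump_config(acute_params).replace(
            "p_death0:\n  family: beta\n  params:\n  - 9.0\n  - 26.0",
            "p_death0:\n  family: empirical\n  params:\n  - 1.5",
        )
        with pytest.raises(ConfigError, match="p_death0"):
            load_parameters(text)


class TestSampling:
    def test_fixed_seed_bit_reproducible(self, acute_params):
        d1 = sample_draws(acute_params, 1000, np.random.default_rng(42))
        d2 = sample_draws(acute_params, 1000, np.random.default_rng(42))
        for name in PARAMETER_NAMES:
            np.testing.assert_array_equal(
                getattr(d1, name), getattr(d2, name)
            )

    def test_scalar_draw_matches_vector_head(self, acute_params):
        scalar = sample_draw(acute_params, np.random.default_rng(42))
        assert isinstance(scalar.p_death0, float)
        assert 0 <= scalar.p_death0 <= 1

    def test_draw_means(self, acute_params, rng):
        draws = sample_draws(acute_params, 100_000, rng)
        assert draws.p_death0.mean() == pytest.approx(0.257, abs=0.002)
        assert draws.c_int.mean() == pytest.approx(3600, rel=0.005)
        assert draws.utility.mean() == pytest.approx(640 / 1065, abs=0.001)

    def test_parameter_independence(self, acute_params, rng):
        draws = sample_draws(acute_params, 100_000, rng)
        mat = np.column_stack([getattr(draws, n) for n in PARAMETER_NAMES])
        corr = np.corrcoef(mat, rowvar=False)
        off_diag = corr[~np.eye(len(PARAMETER_NAMES), dtype=bool)]
        assert np.all(np.abs(off_diag) < 0.02)

    def test_truncation(self, rng, degenerate_params):
        from dataclasses import replace

        params = replace(
            degenerate_params,
            life_years=DistributionSpec("life_years", "normal", (0.0, 5.0)),
            utility=DistributionSpec("utility", "normal", (0.5, 5.0)),
        )
        draws = sample_draws(params, 10_000, rng)
        assert draws.life_years.min() >= 0.0
        assert draws.utility.min() >= 0.0 and draws.utility.max() <= 1.0

    def test_mean_draw(self, acute_params):
        md = mean_draw(acute_params)
        assert md.p_death0 == pytest.approx(9 / 35)
        assert md.utility == pytest.approx(640 / 1065)
        assert md.life_years == pytest.approx(2.67)
        assert md.c_hosp == pytest.approx(3200)


@given(
    alpha=st.floats(0.5, 500),
    beta=st.floats(0.5, 500),
)
def test_beta_mean_formula(alpha, beta):
    spec = DistributionSpec("x", "beta", (alpha, beta))
    assert spec.mean() == pytest.approx(alpha / (alpha + beta))
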