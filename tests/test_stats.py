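import math

import numpy as np
import pytest
from scipy import integrate, stats as sps

import orthoscan as osc
from _oracles import step_up_fdr


class TestMixedT:
    def test_hand_evaluated_example(self):
        t_prime, df = osc.mixed_t(2, [0, 1, 2, 3, 4], [-2, -1, 0, 1, 2])
        assert t_prime == pytest.approx(-2.0, abs=1e-12)
        assert df == pytest.approx(8.0, abs=1e-12)

    def test_zero_numerator(self):
        obs = [1.0, 2.0, 3.0]
        bkg = [4.0, 5.0, 6.0]  # same spread as obs
        t_prime, _ = osc.mixed_t(np.mean(bkg), obs, bkg)
        assert t_prime == pytest.approx(0.0, abs=1e-12)

    def test_reduces_to_pooled_two_sample_t_at_obs_mean(self):
        rng = np.random.default_rng(4)
        obs = rng.normal(1.0, 2.0, size=15)
        bkg = rng.normal(0.0, 1.5, size=40)
        t_prime, _ = osc.mixed_t(obs.mean(), obs, bkg)
        classic = sps.ttest_ind(bkg, obs, equal_var=True).statistic
        assert t_prime == pytest.approx(classic, rel=1e-12)

    def test_reduces_to_shared_sample_form_when_obs_equals_bkg(self):
        sample = [0.5, 1.5, 2.5, 4.5, 6.0]
        one = 4.5
        t_prime, _ = osc.mixed_t(one, sample, sample)
        n = len(sample)
        s = np.std(sample, ddof=1)
        expected = (np.mean(sample) - one) / (s * math.sqrt(2.0 / n))
        assert t_prime == pytest.approx(expected, rel=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            osc.mixed_t(1.0, [1.0, 1.0, 1.0], [2.0, 2.0])

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            osc.mixed_t(1.0, [1.0], [0.0, 1.0])

    def test_welch_df_between_min_and_sum(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            obs = rng.normal(size=rng.integers(2, 30))
            bkg = rng.normal(size=rng.integers(2, 100))
            _, df = osc.mixed_t(obs[0], obs, bkg)
            assert 0 < df <= len(obs) + len(bkg) - 2 + 1e-9


class TestPValue:
    def test_zero_statistic_gives_half(self):
        for df in (1, 5, 50):
            assert osc.p_value(0.0, df) == pytest.approx(0.5)

    def test_matches_numerical_integration_of_t_density(self):
        df = 8.0

        def density(x):
            c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
            return c * (1 + x**2 / df) ** (-(df + 1) / 2)

        expected, _ = integrate.quad(density, -np.inf, -2.0)
        assert osc.p_value(-2.0, df) == pytest.approx(expected, abs=1e-8)
        assert expected == pytest.approx(0.0403, abs=1e-4)

    def test_lower_tail_symmetry(self):
        for t in (0.3, 1.7, 4.2):
            assert osc.p_value(t, 6) + osc.p_value(-t, 6) == pytest.approx(1.0)

    def test_two_sided_doubles_tail(self):
        assert osc.p_value(-2.0, 8, tail="two_sided") == pytest.approx(
            2 * osc.p_value(-2.0, 8), rel=1e-12
        )

    def test_non_finite_statistic_clamped(self):
        assert osc.p_value(-math.inf, 5) == 0.0
        assert osc.p_value(math.inf, 5) == 1.0

    def test_monotone_in_one(self):
        obs = list(np.linspace(-1, 1, 9))
        bkg = list(np.linspace(-2, 0, 20))
        previous = 1.1
        for one in np.linspace(-1, 3, 10):
            t_prime, df = osc.mixed_t(one, obs, bkg)
            p = osc.p_value(t_prime, df)
            assert p < previous
            previous = p


class TestDiagnostics:
    def test_ccv_hand_example(self):
        assert osc.ccv(2, [1, 2, 3]) == pytest.approx(2 / math.sqrt(2 / 3))

    def test_ccv_perfect_conservation_is_infinite(self):
        assert osc.ccv(2.0, [2.0, 2.0, 2.0]) == math.inf

    def test_ccv_zero_mean_with_spread(self):
        assert osc.ccv(1.0, [-1.0, 0.0, 1.0]) == 0.0

    def test_ccv_empty_rejected(self):
        with pytest.raises(ValueError):
            osc.ccv(1.0, [])

    def test_sd_examples(self):
        assert osc.sd_effect(-10.0, [-10.0, -10.0]) == 0.0
        assert osc.sd_effect(-6.0, [-10.0, -10.0]) == pytest.approx(0.4)

    def test_sd_sign_follows_excess_over_background(self):
        for bkg_mean in (-10.0, -0.5, 3.0):
            bkg = [bkg_mean - 1, bkg_mean + 1]
            assert osc.sd_effect(bkg_mean + 0.7, bkg) > 0
            assert osc.sd_effect(bkg_mean - 0.7, bkg) < 0

    def test_sd_zero_background_mean_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            osc.sd_effect(1.0, [-1.0, 1.0])


class TestBhFdr:
    def test_single_p_is_unchanged(self):
        assert osc.bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_hand_derived_step_up(self):
        np.testing.assert_allclose(
            osc.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(osc.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_textbook_oracle_in_input_order(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=57)
        np.testing.assert_allclose(osc.bh_fdr(p), step_up_fdr(list(p)), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            osc.bh_fdr([0.5, 1.5])


def test_mixed_test_bundles_all_quantities():
    obs, bkg = [0, 1, 2, 3, 4], [-4, -3, -2, -1, 0]
    res = osc.mixed_test(2, obs, bkg)
    t_expected, df_expected = osc.mixed_t(2, obs, bkg)
    assert res.t_prime == pytest.approx(t_expected)
    assert res.df == pytest.approx(df_expected)
    assert res.p == pytest.approx(osc.p_value(t_expected, df_expected))
    assert res.ccv == pytest.approx(osc.ccv(2, obs))
    assert res.sd == pytest.approx(osc.sd_effect(2, bkg))


def test_significance_surface_monotone_in_ccv_and_sd():
    """1 - p rises with conservation (CCV) and with effect size (SD)."""
    rng = np.random.default_rng(12)
    bkg = rng.normal(-10.0, 5.0, size=100)
    u = np.linspace(-1.0, 1.0, 31)
    u[15] = 0.0  # keep `one` an element of obs
    u = (u - u.mean()) / math.sqrt(float(np.mean((u - u.mean()) ** 2)))
    spreads = [2.0, 1.0, 0.5, 0.25]  # decreasing spread -> increasing CCV
    ones = [2.0, 4.0, 6.0, 8.0]  # increasing target score -> increasing SD
    p = np.empty((len(spreads), len(ones)))
    ccv_grid = np.empty_like(p)
    sd_grid = np.empty_like(p)
    for i, r in enumerate(spreads):
        for j, one in enumerate(ones):
            obs = one + r * u
            res = osc.mixed_test(one, obs, bkg)
            p[i, j], ccv_grid[i, j], sd_grid[i, j] = res.p, res.ccv, res.sd
    assert np.all(np.diff(ccv_grid, axis=0) > 0)  # CCV grows as spread shrinks
    assert np.all(np.diff(sd_grid, axis=1) > 0)  # SD grows with the target score
    surface = 1.0 - p
    assert np.all(np.diff(surface, axis=0) >= -1e-9)
    assert np.all(np.diff(surface, axis=1) >= -1e-9)
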