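import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smrlink.experiments import wasserstein_lp
from smrlink.mass_response import (
    MassSample,
    bootstrap_t_test,
    emd_sorted,
    harmonize,
    mass_response,
    theta,
)


def brute_force_quantile(values, p):
    """CDF-inversion oracle: order statistic i (1-based) sits at (i-0.5)/n,
    linear interpolation between, clamped at the extremes."""
    v = np.sort(np.asarray(values, float))
    n = v.size
    probs = (np.arange(1, n + 1) - 0.5) / n
    if p <= probs[0]:
        return v[0]
    if p >= probs[-1]:
        return v[-1]
    j = np.searchsorted(probs, p) - 1
    w = (p - probs[j]) / (probs[j + 1] - probs[j])
    return v[j] * (1 - w) + v[j + 1] * w


class TestHarmonize:
    def test_equal_sizes_pass_through_sorted(self):
        a, b = harmonize([3.0, 1.0, 2.0], [5.0, 4.0, 6.0])
        assert a.tolist() == [1, 2, 3] and b.tolist() == [4, 5, 6]
        a, b = harmonize([3.0, 1.0, 2.0], [5.0, 4.0, 6.0], policy="subsample", seed=0)
        assert a.tolist() == [1, 2, 3] and b.tolist() == [4, 5, 6]

    def test_subsample_reduces_to_smaller_size(self):
        a, b = harmonize(np.arange(1.0, 6.0), np.array([1.0, 2.0, 3.0]), policy="subsample", seed=1)
        assert a.size == b.size == 3
        assert np.all(np.diff(a) >= 0)

    def test_quantile_interp_hand_example(self):
        # N = 2 midpoint grid: probabilities 1/4 and 3/4
        a, b = harmonize([0.0, 10.0], [0.0, 5.0, 10.0])
        np.testing.assert_allclose(a, [0.0, 10.0])  # own grid -> identity
        np.testing.assert_allclose(b, [1.25, 8.75])

    @given(
        vals=st.lists(st.floats(1, 100), min_size=2, max_size=12),
        n_out=st.integers(2, 12),
    )
    @settings(max_examples=100, deadline=None)
    def test_quantile_interp_matches_cdf_inversion_oracle(self, vals, n_out):
        from smrlink.mass_response import _hazen_quantiles

        got = _hazen_quantiles(np.sort(np.array(vals)), n_out)
        expected = [brute_force_quantile(vals, (j + 0.5) / n_out) for j in range(n_out)]
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError):
            harmonize([1.0], [1.0, 2.0])


class TestEMD:
    def test_identity_and_hand_example(self):
        assert emd_sorted([1.0, 2.0], [1.0, 2.0]) == 0
        assert emd_sorted([2.0, 3.0, 4.0], [1.0, 2.0, 3.0]) == 3

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            emd_sorted([1.0], [1.0, 2.0])

    def test_pure_shift_closed_form(self, rng):
        z = np.sort(rng.uniform(10, 20, 6))
        assert emd_sorted(z + 2.5, z) == pytest.approx(6 * 2.5, rel=1e-12)
        assert wasserstein_lp(z + 2.5, z) == pytest.approx(2.5, rel=1e-8)

    def test_matches_transport_lp_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 8))
            x, z = np.sort(rng.uniform(0, 50, n)), np.sort(rng.uniform(0, 50, n))
            assert emd_sorted(x, z) / n == pytest.approx(wasserstein_lp(x, z), abs=1e-10)


class TestMassResponseStatistic:
    def test_identity_and_hand_value(self):
        assert mass_response([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0
        assert mass_response([2.0, 3.0, 4.0], [1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_scale_invariance(self, rng):
        x, z = rng.uniform(10, 30, 40), rng.uniform(10, 30, 40)
        assert mass_response(10 * x, 10 * z) == pytest.approx(mass_response(x, z), rel=1e-12)

    def test_pure_shift_value(self, rng):
        z = rng.uniform(40, 60, 100)
        delta = 3.0
        assert mass_response(z + delta, z) == pytest.approx(delta / z.mean(), rel=1e-9)

    def test_nonnegative(self, rng):
        for _ in range(20):
            x, z = rng.lognormal(4, 0.3, 30), rng.lognormal(4, 0.3, 50)
            assert mass_response(x, z) >= 0


class TestTheta:
    def test_zero_when_arms_equal(self, rng):
        x = rng.uniform(10, 20, 30)
        z = rng.uniform(10, 20, 30)
        assert theta(x, x, z) == 0

    def test_antisymmetry(self, rng):
        x, y, z = (rng.lognormal(4, 0.25, n) for n in (40, 35, 50))
        assert theta(x, y, z) == pytest.approx(-theta(y, x, z), rel=1e-12)

    def test_sign_follows_mass_reduction(self, rng):
        z = rng.lognormal(4, 0.25, 1000)
        y = rng.lognormal(4, 0.25, 1000)
        x = 0.8 * rng.lognormal(4, 0.25, 1000)
        assert theta(x, y, z) > 0

    def test_mass_sample_validation(self):
        with pytest.raises(ValueError):
            MassSample("bad", np.array([1.0, -2.0]))
        s = MassSample("ok", np.array([50.0, 60.0]), condition="drug")
        assert s.n == 2


class TestBootstrapT:
    def test_theta_obs_consistent_with_theta(self, rng):
        x, y, z = (rng.lognormal(4, 0.25, n) for n in (120, 100, 150))
        res = bootstrap_t_test(x, y, z, n_boot=300, seed=5)
        assert res.theta == pytest.approx(theta(x, y, z), rel=1e-12)
        assert res.theta == pytest.approx(
            res.mass_response_drug - res.mass_response_vehicle, rel=1e-12
        )

    def test_bit_identical_for_fixed_seed(self, rng):
        x, y, z = (rng.lognormal(4, 0.25, 80) for _ in range(3))
        r1 = bootstrap_t_test(x, y, z, n_boot=500, seed=11)
        r2 = bootstrap_t_test(x, y, z, n_boot=500, seed=11)
        assert r1 == r2

    def test_degenerate_identical_masses_gives_p_one(self):
        const = np.full(60, 55.0)
        res = bootstrap_t_test(const, const, const, n_boot=300, seed=0)
        assert res.p_value == 1.0 and not res.decision

    def test_small_n_boot_rejected(self, rng):
        x = rng.lognormal(4, 0.25, 50)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_t_test(x, x, x, n_boot=100, seed=0)

    def test_strong_effect_rejected_weak_not(self, rng):
        z = rng.lognormal(4, 0.25, 800)
        y = rng.lognormal(4, 0.25, 800)
        x = 0.8 * rng.lognormal(4, 0.25, 800)
        hit = bootstrap_t_test(x, y, z, n_boot=500, seed=3)
        assert hit.decision and hit.p_value < 0.01
        null = bootstrap_t_test(rng.lognormal(4, 0.25, 800), y, z, n_boot=500, seed=3)
        assert null.p_value > 0.01

    def test_two_sided_detects_negative_theta(self, rng):
        z = rng.lognormal(4, 0.25, 800)
        y = 0.8 * rng.lognormal(4, 0.25, 800)  # vehicle diverges instead
        x = rng.lognormal(4, 0.25, 800)
        one = bootstrap_t_test(x, y, z, n_boot=500, seed=4, alternative="greater")
        two = bootstrap_t_test(x, y, z, n_boot=500, seed=4, alternative="two_sided")
        assert one.p_value > 0.5  # wrong direction for the one-sided test
        assert two.p_value < 0.05

    def test_unequal_arm_sizes_supported(self, rng):
        x, y, z = (rng.lognormal(4, 0.25, n) for n in (130, 90, 200))
        res = bootstrap_t_test(x, y, z, n_boot=300, seed=9)
        assert res.harmonized_n == 90
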