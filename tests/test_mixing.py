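import numpy as np
import pytest
from scipy.linalg import expm

from oracles import gillespie_two_state
from ufdexsy.encoding import encode
from ufdexsy.mixing import apply_mixing, diffusion_blur, exchange_propagator, guard_band
from ufdexsy.model_core import EncodingSpec, TwoSiteSample, rate_matrix

TINY_D = 1e-30


class TestExchangePropagator:
    def test_zero_time_is_identity(self):
        K = rate_matrix(14.0, [0.24, 0.76])
        assert exchange_propagator(K, 0.0) == pytest.approx(np.eye(2))

    def test_long_time_limit_reaches_stationary_populations(self):
        K = rate_matrix(14.0, [0.24, 0.76])
        P = exchange_propagator(K, 1e6)
        expected = np.column_stack([[0.24, 0.76], [0.24, 0.76]])
        assert P == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("tau", [0.0, 1e-3, 0.1, 10.0])
    def test_column_stochastic(self, tau):
        K = rate_matrix(14.0, [0.24, 0.76])
        P = exchange_propagator(K, tau)
        assert P.sum(axis=0) == pytest.approx([1.0, 1.0], abs=1e-12)
        assert np.all(P >= 0)

    def test_matches_scaling_and_squaring_exponential(self, rng):
        """Closed form vs scipy's expm on random valid rate matrices."""
        for _ in range(20):
            k = rng.uniform(0.0, 200.0)
            p = rng.uniform(0.05, 0.95)
            tau = rng.uniform(0.0, 0.5)
            K = rate_matrix(k, [p, 1.0 - p])
            assert np.max(np.abs(exchange_propagator(K, tau) - expm(K * tau))) < 1e-10

    def test_cross_site_fraction_at_study_parameters(self):
        # total fraction switching site in 10 ms: 2 p_a p_b (1 - e^{-0.14})
        K = rate_matrix(14.0, [0.24, 0.76])
        P = exchange_propagator(K, 10e-3)
        p = np.array([0.24, 0.76])
        cross = P[1, 0] * p[0] + P[0, 1] * p[1]
        assert cross == pytest.approx(2 * 0.24 * 0.76 * (1 - np.exp(-0.14)), rel=1e-12)
        assert cross == pytest.approx(0.0477, abs=5e-4)

    def test_matches_two_state_jump_simulation(self, rng):
        """Propagator vs a 1e5-particle Gillespie simulation, within 3 SE."""
        K = rate_matrix(14.0, [0.24, 0.76])
        tau = 0.05
        P_mc = gillespie_two_state(K[1, 0], K[0, 1], tau, 100_000, rng)
        se = np.sqrt(0.25 / 100_000)  # worst-case binomial SE per column
        assert np.max(np.abs(P_mc - exchange_propagator(K, tau))) < 3 * se

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            exchange_propagator(rate_matrix(1.0, [0.5, 0.5]), -1e-3)


class TestDiffusionBlur:
    dz = 300e-6 / 128

    def test_zero_time_is_identity(self, rng):
        v = rng.uniform(size=64)
        assert np.array_equal(diffusion_blur(v, 2e-9, 0.0, 0.0, self.dz), v)

    def test_uniform_profile_with_matching_pad_unchanged(self):
        v = np.full(64, 0.7)
        out = diffusion_blur(v, 3.6e-9, 0.1, 0.7, self.dz)
        assert out == pytest.approx(v, abs=1e-12)

    def test_spike_spreads_to_free_diffusion_width(self):
        """Moment-matching oracle: a near-delta spike blurred for 100 ms at
        D = 3.6e-9 m^2/s acquires standard deviation sqrt(2 D t) ~ 26.8 um."""
        n = 512
        v = np.zeros(n)
        v[n // 2] = 1.0
        out = diffusion_blur(v, 3.6e-9, 0.1, 0.0, self.dz)
        x = (np.arange(n) - n // 2) * self.dz
        mass = out.sum()
        mean = (x * out).sum() / mass
        sigma = np.sqrt(((x - mean) ** 2 * out).sum() / mass)
        assert sigma == pytest.approx(np.sqrt(2 * 3.6e-9 * 0.1), rel=1e-3)
        assert sigma == pytest.approx(26.8e-6, rel=5e-3)

    def test_mass_conserved_on_periodic_extension(self, rng):
        v = rng.uniform(size=128)
        out = diffusion_blur(v, 3.6e-9, 0.05, 0.0, self.dz, mode="wrap")
        assert out.sum() == pytest.approx(v.sum(), rel=1e-12)

    def test_semigroup_composition_is_exact(self, rng):
        """n short blurs compose to one long blur (discrete Gaussian kernel),
        even for substep widths below the grid spacing; residual error is
        only the 5-sigma kernel truncation."""
        v = rng.uniform(size=256)
        one = diffusion_blur(v, 3.6e-9, 0.01, 0.0, self.dz, mode="wrap")
        many = v
        for _ in range(32):
            many = diffusion_blur(many, 3.6e-9, 0.01 / 32, 0.0, self.dz, mode="wrap")
        assert many == pytest.approx(one, abs=1e-6)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            diffusion_blur(np.ones(8), -1e-9, 0.1, 0.0, self.dz)
        with pytest.raises(ValueError):
            diffusion_blur(np.ones(8), 1e-9, -0.1, 0.0, self.dz)


class TestApplyMixing:
    def test_static_sample_unchanged(self, encoding_spec, flat_instrument):
        sample = TwoSiteSample.yeast_water(k=0.0, D_intra=TINY_D, D_extra=TINY_D)
        prof = encode(sample, encoding_spec, flat_instrument)
        mix = apply_mixing(prof, sample, 0.1, n_substeps=8)
        assert mix.profile.values == pytest.approx(prof.values, abs=1e-15)

    def test_zero_mixing_time_is_identity(self, encoding_spec, instrument, yeast_sample):
        prof = encode(yeast_sample, encoding_spec, instrument)
        mix = apply_mixing(prof, yeast_sample, 0.0)
        assert np.array_equal(mix.profile.values, prof.values)
        assert mix.joint_weights == pytest.approx(
            np.diag(yeast_sample.populations), abs=1e-15)

    def test_pure_exchange_reduces_to_pointwise_propagator(
            self, encoding_spec, instrument):
        sample = TwoSiteSample.yeast_water(D_intra=TINY_D, D_extra=TINY_D)
        prof = encode(sample, encoding_spec, instrument)
        mix = apply_mixing(prof, sample, 0.03, n_substeps=16)
        K = rate_matrix(sample.k, sample.populations)
        expected = exchange_propagator(K, 0.03) @ prof.values
        assert mix.profile.values == pytest.approx(expected, abs=1e-12)

    def test_no_exchange_reduces_to_independent_blurs(
            self, encoding_spec, instrument):
        sample = TwoSiteSample.yeast_water(k=0.0)
        prof = encode(sample, encoding_spec, instrument)
        tau = 0.05
        mix = apply_mixing(prof, sample, tau, n_substeps=16)
        dz = prof.z_grid[1] - prof.z_grid[0]
        for j, site in enumerate(sample.sites):
            g = guard_band(site.D, tau, dz)
            ext = np.full(prof.z_grid.size + 2 * g, prof.pad_values[j])
            ext[g:g + prof.z_grid.size] = prof.values[j]
            single = diffusion_blur(ext, site.D, tau, prof.pad_values[j], dz)
            assert mix.profile.values[j] == pytest.approx(
                single[g:g + prof.z_grid.size], abs=1e-6)

    def test_joint_weights_sum_to_one(self, encoding_spec, instrument, yeast_sample):
        prof = encode(yeast_sample, encoding_spec, instrument)
        mix = apply_mixing(prof, yeast_sample, 0.03)
        assert mix.joint_weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(mix.joint_weights >= 0)

    def test_splitting_converges(self, encoding_spec, instrument, yeast_sample):
        """Relative change between 32 and 64 substeps below 1% at the
        longest study mixing time."""
        prof = encode(yeast_sample, encoding_spec, instrument)
        a = apply_mixing(prof, yeast_sample, 0.1, n_substeps=32).profile.total
        b = apply_mixing(prof, yeast_sample, 0.1, n_substeps=64).profile.total
        assert np.max(np.abs(a - b)) / np.max(np.abs(b)) < 0.01

    def test_profile_contrast_shrinks_with_mixing_time(
            self, encoding_spec, instrument, yeast_sample):
        prof = encode(yeast_sample, encoding_spec, instrument)
        contrasts = []
        for tau in (0.0, 0.01, 0.03, 0.1):
            tot = apply_mixing(prof, yeast_sample, tau).profile.total
            contrasts.append(tot.max() - tot.min())
        assert all(a >= b - 1e-12 for a, b in zip(contrasts, contrasts[1:]))

    def test_invalid_arguments_rejected(self, encoding_spec, instrument, yeast_sample):
        prof = encode(yeast_sample, encoding_spec, instrument)
        with pytest.raises(ValueError):
            apply_mixing(prof, yeast_sample, -0.01)
        with pytest.raises(ValueError):
            apply_mixing(prof, yeast_sample, 0.01, n_substeps=0)
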