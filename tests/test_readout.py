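import numpy as np
import pytest

from oracles import brownian_cpmg
from ufdexsy.encoding import encode
from ufdexsy.mixing import MixingResult, apply_mixing
from ufdexsy.model_core import CpmgSpec, EncodingSpec, TwoSiteSample
from ufdexsy.readout import add_noise, cpmg_attenuation, simulate_raw

TINY_D = 1e-30


def _mix(sample, encoding_spec, instrument, tau=0.01, n_substeps=8):
    prof = encode(sample, encoding_spec, instrument)
    return apply_mixing(prof, sample, tau, n_substeps)


class TestCpmgAttenuation:
    def test_no_decay_without_diffusion_or_relaxation(self, instrument):
        n = np.arange(0, 50)
        out = cpmg_attenuation(0.0, np.inf, 150e-6, n, instrument)
        assert out == pytest.approx(np.ones(50))

    def test_exponential_in_echo_index(self, instrument):
        f = cpmg_attenuation(3.6e-9, 0.1, 150e-6, np.array([3, 6]), instrument)
        assert f[1] == pytest.approx(f[0] ** 2, rel=1e-12)

    def test_diffusion_dominates_t2_in_strong_gradient(self, instrument):
        """At G = 7.28 T/m an echo time can always be chosen so that the
        per-echo diffusion term exceeds the T2 term by >= 10x for free
        water even at T2 as short as 100 ms (diffusion scales as tE^3, T2
        loss only as tE)."""
        tE, D, T2 = 400e-6, 3.6e-9, 0.1
        gamma = 2 * np.pi * instrument.gammabar
        diff_term = gamma**2 * instrument.G**2 * tE**3 * D / 12
        t2_term = tE / T2
        assert diff_term > 10 * t2_term
        combined = cpmg_attenuation(D, T2, tE, 1, instrument)
        assert combined == pytest.approx(np.exp(-diff_term - t2_term), rel=1e-12)

    def test_matches_random_walk_cpmg_simulation(self, instrument, rng):
        """Closed form vs 1e5-walker random-walk phase simulation."""
        amps, errs = brownian_cpmg(3.6e-9, 150e-6, 5, instrument.G,
                                   instrument.gammabar, 100_000, rng)
        exact = cpmg_attenuation(3.6e-9, np.inf, 150e-6, np.arange(1, 6), instrument)
        assert np.all(np.abs(amps - exact) < 3 * errs)

    def test_nonpositive_echo_time_rejected(self, instrument):
        with pytest.raises(ValueError):
            cpmg_attenuation(1e-9, np.inf, 0.0, 1, instrument)


class TestSimulateRaw:
    def test_single_site_ideal_conditions_give_outer_product(self, flat_instrument):
        spec = EncodingSpec(edge_depth=0.0)
        sample = TwoSiteSample.yeast_water(k=0.0, D_intra=3.6e-9, D_extra=3.6e-9,
                                           p_intra=0.5)
        mix = _mix(sample, spec, flat_instrument, tau=1e-9, n_substeps=1)
        raw = simulate_raw(mix, CpmgSpec(), flat_instrument, sample)
        u, s, vt = np.linalg.svd(raw.matrix)
        assert s[1] / s[0] < 1e-12  # numerically rank one

    def test_diffusion_free_sample_has_identical_echoes(self, encoding_spec, instrument):
        sample = TwoSiteSample.yeast_water(D_intra=TINY_D, D_extra=TINY_D)
        mix = _mix(sample, encoding_spec, instrument)
        raw = simulate_raw(mix, CpmgSpec(), instrument, sample)
        assert raw.matrix == pytest.approx(
            np.tile(raw.matrix[:, :1], (1, raw.n_echoes)))

    def test_linear_in_joint_components(self, encoding_spec, instrument, yeast_sample):
        """Scaling the start/end-resolved components scales the output:
        simulating a weighted state equals the weighted sum of the four
        single-component simulations, to 1e-10."""
        cpmg = CpmgSpec()
        mix = _mix(yeast_sample, encoding_spec, instrument, tau=0.03)
        full = simulate_raw(mix, cpmg, instrument, yeast_sample).matrix
        acc = np.zeros_like(full)
        for j in range(2):
            for i in range(2):
                comp = np.zeros_like(mix.components)
                comp[j, i] = mix.components[j, i]
                sub = MixingResult(
                    profile=mix.profile.__class__(
                        z_grid=mix.profile.z_grid, values=comp.sum(axis=0),
                        amplitude=mix.profile.amplitude,
                        pad_values=mix.pad_components.sum(axis=0)),
                    components=comp, pad_components=mix.pad_components,
                    joint_weights=mix.joint_weights, tau_M=mix.tau_M,
                    n_substeps=mix.n_substeps)
                acc += simulate_raw(sub, cpmg, instrument, yeast_sample).matrix
        assert np.max(np.abs(full - acc)) < 1e-10

    def test_noiseless_entries_nonnegative_and_axes_consistent(
            self, encoding_spec, instrument, yeast_sample):
        mix = _mix(yeast_sample, encoding_spec, instrument)
        raw = simulate_raw(mix, CpmgSpec(), instrument, yeast_sample)
        assert np.all(raw.matrix >= 0)
        assert raw.freq_axis == pytest.approx(
            instrument.gammabar * instrument.G * raw.depth_axis)

    def test_diagnostic_slices_are_first_row_and_peak_column(
            self, encoding_spec, instrument, yeast_sample):
        mix = _mix(yeast_sample, encoding_spec, instrument)
        raw = simulate_raw(mix, CpmgSpec(), instrument, yeast_sample)
        row, col = raw.diagnostic_slices()
        assert np.array_equal(row, raw.matrix[:, 0])
        assert np.array_equal(col, raw.matrix[np.argmax(row), :])
        # echo train at the peak is a decreasing two-exponential mixture
        assert np.all(np.diff(col) < 0)

    def test_grid_mismatch_rejected(self, encoding_spec, instrument, yeast_sample):
        mix = _mix(yeast_sample, encoding_spec, instrument)
        with pytest.raises(ValueError):
            simulate_raw(mix, CpmgSpec(points_per_echo=64), instrument, yeast_sample)


class TestAddNoise:
    def _raw(self, encoding_spec, instrument):
        sample = TwoSiteSample.yeast_water()
        mix = _mix(sample, encoding_spec, instrument)
        return simulate_raw(mix, CpmgSpec(), instrument, sample)

    def test_fixed_seed_reproducible(self, encoding_spec, instrument):
        raw = self._raw(encoding_spec, instrument)
        a = add_noise(raw, 280.0, seed=99)
        b = add_noise(raw, 280.0, seed=99)
        assert np.array_equal(a.matrix, b.matrix)
        assert a.noise_sigma == b.noise_sigma

    def test_infinite_snr_is_identity(self, encoding_spec, instrument):
        raw = self._raw(encoding_spec, instrument)
        out = add_noise(raw, np.inf, seed=1)
        assert np.array_equal(out.matrix, raw.matrix)
        assert out.noise_sigma == 0.0

    def test_empirical_snr_close_to_nominal(self, encoding_spec, instrument):
        """max|S| / std(noise) within 5% of the requested SNR ~ 280 on a
        >= 1e4 element matrix."""
        raw = self._raw(encoding_spec, instrument)
        assert raw.matrix.size >= 10_000
        out = add_noise(raw, 280.0, seed=5)
        noise = out.matrix - raw.matrix
        emp = np.max(np.abs(raw.matrix)) / noise.std()
        assert emp == pytest.approx(280.0, rel=0.05)

    def test_nonpositive_snr_rejected(self, encoding_spec, instrument):
        raw = self._raw(encoding_spec, instrument)
        with pytest.raises(ValueError):
            add_noise(raw, 0.0, seed=1)
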