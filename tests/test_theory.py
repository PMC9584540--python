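"""Analytic predictions: kernel spectrum, bump shape, Lyapunov, dynamics."""

import numpy as np
import pytest

from ringbump import (
    DriftField,
    ModelConfig,
    build_connectivity,
    bump_shape,
    growth_rate,
    kernel_fourier,
    lyapunov,
    predict_drift_field,
    predict_drive_velocity,
    predict_escape_drive,
    predict_input_diffusion,
    predict_speed_stats,
    predict_spike_diffusion,
    preferred_wavelength,
    sample_connectivity_noise,
)
from ringbump.simulate import relax_to_steady_state
from ringbump.theory import TheoryError, lyapunov_closed_form, preferred_wavenumber
from ringbump.tracking import bump_positions, count_bumps, ring_difference


class TestKernelFourier:
    def test_zero_wavenumber_limit(self):
        cfg = ModelConfig(N=600, M=3)
        k = np.pi / cfg.l
        assert kernel_fourier(cfg, 0.0) == pytest.approx(-2 * np.pi * cfg.w / k)
        assert kernel_fourier(cfg, 1e-13) == pytest.approx(-2 * np.pi * cfg.w / k)

    def test_matches_fft_of_sampled_kernel(self):
        cfg = ModelConfig(N=600, M=3)  # l = 88
        conn = build_connectivity(cfg)
        m = np.arange(1, 40)
        q = 2 * np.pi * m / cfg.N
        dft = np.fft.rfft(conn.base_kernel).real[1:40]
        closed = kernel_fourier(cfg, q)
        scale = np.abs(closed).max()
        np.testing.assert_allclose(dft, closed, atol=0.01 * scale)

    def test_decay_at_large_wavenumber(self):
        cfg = ModelConfig(N=200, M=3)
        k = np.pi / cfg.l
        assert abs(kernel_fourier(cfg, 100 * k)) < 1e-3 * abs(kernel_fourier(cfg, 0.0))


class TestPreferredWavelength:
    @pytest.mark.parametrize("l", [20.0, 29.0, 50.0, 88.0, 100.0])
    def test_ratio_is_2_28(self, l):
        cfg = ModelConfig(N=1000, M=1, l=l, w=1.0)
        assert round(preferred_wavelength(cfg) / l, 2) == 2.28

    def test_ratio_independent_of_amplitude(self):
        a = preferred_wavelength(ModelConfig(N=600, M=1, w=0.01))
        b = preferred_wavelength(ModelConfig(N=600, M=1, w=5.0))
        assert a == pytest.approx(b, rel=1e-6)

    def test_reference_configuration(self):
        # l = 29 selects lambda ~ 66, i.e. 3 bumps in a 200-neuron ring
        lam = preferred_wavelength(ModelConfig(N=200, M=3, l=29.0))
        assert lam == pytest.approx(66.1, abs=0.2)
        assert round(200 / lam) == 3

    def test_optimizer_agrees_with_fine_grid_search(self):
        cfg = ModelConfig(N=600, M=3)
        k = np.pi / cfg.l
        grid = np.arange(1e-5, 3 * k, 1e-5 * k)
        brute = grid[np.argmax(kernel_fourier(cfg, grid))]
        assert preferred_wavenumber(cfg) == pytest.approx(brute, abs=1e-4 * k)


class TestGrowthRate:
    def test_marginal_mode(self):
        cfg = ModelConfig(N=200, M=3)
        # find q where W-tilde = 1/2 by scanning, rate must vanish there
        q = np.linspace(1e-4, 3 * np.pi / cfg.l, 20000)
        w = kernel_fourier(cfg, q)
        i = np.argmin(np.abs(w - 0.5))
        assert growth_rate(cfg, q[i]) == pytest.approx(0.0, abs=1e-3)

    def test_fastest_mode_positive_and_at_spectrum_peak(self):
        cfg = ModelConfig(N=600, M=3)
        qstar = preferred_wavenumber(cfg)
        assert growth_rate(cfg, qstar) > 0
        q = np.linspace(0.2 * qstar, 3 * qstar, 5000)
        assert np.argmax(growth_rate(cfg, q)) == np.argmax(kernel_fourier(cfg, q))


class TestBumpShape:
    def test_profile_zero_at_half_width_even_and_periodic(self):
        cfg = ModelConfig(N=200, M=3, l=29.0)
        sh = bump_shape(cfg)
        assert 0 < sh.psi < np.pi
        assert sh.profile(sh.z) == pytest.approx(0.0, abs=1e-9)
        x = np.linspace(0, sh.lam, 33)
        np.testing.assert_allclose(sh.profile(x), sh.profile(-x), atol=1e-12)
        np.testing.assert_allclose(sh.profile(x), sh.profile(x + sh.lam), atol=1e-12)

    def test_matches_simulated_baseline_in_firing_region(self, net203):
        # The single-harmonic closed form tracks the simulated baseline
        # closely over the active (firing) region; in the inhibited troughs
        # it overshoots by up to ~20% of max|g|, as expected of a
        # lowest-mode truncation.
        cfg, conn, g = net203
        sh = bump_shape(cfg)
        p = bump_positions(2 * np.maximum(g, 0.0), cfg.M)[0]
        x = np.arange(cfg.N)
        prof = sh.profile(ring_difference(x, p, sh.lam))
        scale = np.abs(g).max()
        active = g > 0
        assert np.abs(prof - g)[active].max() <= 0.10 * scale
        assert np.abs(prof - g).max() <= 0.25 * scale

    def test_invalid_wavelength_rejected(self):
        cfg = ModelConfig(N=200, M=3, l=29.0)
        with pytest.raises(TheoryError):
            bump_shape(cfg, lam=6.0)  # W-tilde < 0 there


class TestLyapunov:
    def test_zero_rates_give_zero(self, net203):
        cfg, conn, _ = net203
        assert lyapunov(cfg, conn, np.zeros(cfg.N)) == 0.0

    def test_full_and_reduced_agree_at_steady_state(self, net203):
        cfg, conn, g = net203
        s = np.maximum(g, 0.0)
        full = lyapunov(cfg, conn, s)
        red = lyapunov(cfg, conn, s, reduced=True)
        assert full == pytest.approx(red, rel=0.01)

    def test_minimized_at_preferred_bump_number(self):
        # N=500, l=55: among persistent 3-, 4- and 5-bump states the 4-bump
        # state (the preferred one) has the lowest Lyapunov value
        cfg = ModelConfig(N=500, M=4, l=55.0)
        conn = build_connectivity(cfg)
        values = {}
        for M in (3, 4, 5):
            prof = bump_shape(cfg, lam=500 / M).profile(np.arange(500))
            state = relax_to_steady_state(cfg, conn, np.stack([prof, prof]), extra_steps=8000)
            s = 0.5 * (np.maximum(state.g_L, 0) + np.maximum(state.g_R, 0))
            assert count_bumps(s) == M
            values[M] = lyapunov(cfg, conn, s)
        assert min(values, key=values.get) == 4
        # closed form shows the same ordering
        closed = {M: lyapunov_closed_form(cfg, lam=500 / M) for M in (3, 4, 5)}
        assert min(closed, key=closed.get) == 4

    def test_negative_rates_rejected(self, net203):
        cfg, conn, _ = net203
        with pytest.raises(ValueError):
            lyapunov(cfg, conn, np.full(cfg.N, -1.0))


class TestDriveVelocity:
    def test_zero_drive_and_antisymmetry(self, net203):
        cfg, conn, g = net203
        assert predict_drive_velocity(cfg, g, 0.0) == 0.0
        assert predict_drive_velocity(cfg, g, -1.5) == pytest.approx(
            -predict_drive_velocity(cfg, g, 1.5)
        )

    def test_flat_profile_rejected(self, net203):
        cfg, conn, _ = net203
        with pytest.raises(TheoryError):
            predict_drive_velocity(cfg, np.full(cfg.N, -1.0), 1.0)


class TestDiffusionPredictions:
    def test_input_zero_noise_and_quadratic_scaling(self, net203):
        cfg, conn, g = net203
        assert predict_input_diffusion(cfg, g, 0.0) == 0.0
        assert predict_input_diffusion(cfg, g, 1.0) == pytest.approx(
            4.0 * predict_input_diffusion(cfg, g, 0.5)
        )

    def test_input_bump_number_ratio(self, network_cache):
        # linear mapping: D ∝ N/M², so at N=600 D(M=3)/D(M=6) = 4
        _, _, g3 = network_cache(600, 3)
        _, _, g6 = network_cache(600, 6)
        D3 = predict_input_diffusion(ModelConfig(N=600, M=3), g3, 0.5)
        D6 = predict_input_diffusion(ModelConfig(N=600, M=6), g6, 0.5)
        assert D3 / D6 == pytest.approx(4.0, rel=0.05)

    def test_spike_linear_in_fano(self, network_cache):
        cfg, _, g = network_cache(200, 1, mode="spiking")
        assert predict_spike_diffusion(cfg, g, 2.0) == pytest.approx(
            2.0 * predict_spike_diffusion(cfg, g, 1.0)
        )

    def test_degenerate_profile_rejected(self, net203):
        cfg, _, _ = net203
        with pytest.raises(TheoryError):
            predict_spike_diffusion(cfg, np.zeros(cfg.N), 1.0)


class TestDriftField:
    def test_zero_noise_gives_zero_field(self, net601):
        cfg, conn, g = net601
        field = predict_drift_field(cfg, g, np.zeros((2 * cfg.N, 2 * cfg.N)))
        np.testing.assert_allclose(field.v, 0.0, atol=1e-12)

    def test_field_odd_in_noise_matrix(self, net601):
        cfg, conn, g = net601
        V = sample_connectivity_noise(cfg, 0.002, seed=5)
        a = predict_drift_field(cfg, g, V).v
        b = predict_drift_field(cfg, g, -V).v
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_escape_drive_zero_noise_and_translation_invariance(self, net601):
        cfg, conn, g = net601
        zero = predict_drift_field(cfg, g, np.zeros((2 * cfg.N, 2 * cfg.N)))
        assert predict_escape_drive(cfg, zero, g) == 0.0
        V = sample_connectivity_noise(cfg, 0.002, seed=5)
        f = predict_drift_field(cfg, g, V)
        rolled = DriftField(f.theta_grid, np.roll(f.v, 123))
        assert predict_escape_drive(cfg, rolled, g) == pytest.approx(
            predict_escape_drive(cfg, f, g)
        )


class TestSpeedStats:
    def test_zero_field(self):
        f = DriftField(np.arange(10), np.zeros(10))
        assert predict_speed_stats(f, 30.0) == (0.0, 0.0)

    def test_doubling_drive_halves_both(self, rng):
        f = DriftField(np.arange(100), rng.normal(0, 3.0, 100))
        d1, v1 = predict_speed_stats(f, 30.0)
        d2, v2 = predict_speed_stats(f, 60.0)
        assert d2 == pytest.approx(d1 / 2)
        assert v2 == pytest.approx(v1 / 2)

    def test_trapping_regime_rejected(self):
        f = DriftField(np.arange(10), np.linspace(-40, 40, 10))
        with pytest.raises(TheoryError):
            predict_speed_stats(f, 30.0)
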