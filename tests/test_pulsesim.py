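"""Pulse simulation: Gaussian transits, exponential decay, spillover, noise."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.signal import correlate

from cytopulse import (
    CrossoverMatrix,
    DecaySpec,
    GaussianPulseParams,
    SimConfig,
    TimeGrid,
    add_noise,
    apply_decay,
    estimate_delay,
    gaussian_pulse,
    mix_crossover,
    simulate_batch,
    simulate_event,
    simulate_led_pair,
)
from cytopulse.waveform import Waveform


class TestGaussianPulse:
    def test_value_at_center_and_inflection(self, grid):
        c = grid.start_time + 1024 * grid.sample_period  # on-grid center
        w = gaussian_pulse(GaussianPulseParams(1.0, c, 0.5e-6), grid)
        t = w.times()
        i_c = np.argmin(np.abs(t - c))
        assert w.values[i_c] == pytest.approx(1.0)
        i_s = np.argmin(np.abs(t - (c + 0.5e-6)))
        assert w.values[i_s] == pytest.approx(np.exp(-0.5))

    def test_peak_equals_amplitude_for_preset_pulse(self, grid):
        # fluorochrome-1 amplitude of the first preset parameter row
        c = grid.start_time + 1024 * grid.sample_period  # on-grid center
        w = gaussian_pulse(GaussianPulseParams(1.40, c, 0.5e-6), grid)
        assert w.values.max() == pytest.approx(1.40)

    @pytest.mark.parametrize("amplitude,sigma", [(-1.0, 1e-6), (0.0, 1e-6), (1.0, 0.0), (1.0, -2e-6)])
    def test_invalid_parameters_rejected(self, amplitude, sigma):
        with pytest.raises(ValueError):
            GaussianPulseParams(amplitude, 0.0, sigma)

    def test_clipped_pulse_warns(self, grid):
        with pytest.warns(UserWarning, match="clipped"):
            gaussian_pulse(GaussianPulseParams(1.0, 0.0, 1e-6), grid)


class TestApplyDecay:
    def test_zero_lifetime_is_pure_gain(self, grid):
        c = grid.start_time + 0.5 * grid.span
        w = gaussian_pulse(GaussianPulseParams(1.0, c, 0.5e-6), grid)
        out = apply_decay(w, DecaySpec(lifetime=0.0, gain=2.5))
        np.testing.assert_array_equal(out.values, 2.5 * w.values)

    def test_negative_lifetime_rejected(self):
        with pytest.raises(ValueError):
            DecaySpec(lifetime=-1e-9)

    def test_correlation_lag_equals_lifetime_on_dense_grid(self):
        # Fine grid so the discrete kernel's first moment ~ tau: the decayed
        # pulse's correlation against the input peaks at lag tau.
        tau = 8.48e-9
        T = 1e-10
        fine = TimeGrid(sample_period=T, n_samples=60000)
        c = fine.start_time + 0.45 * fine.span
        x = gaussian_pulse(GaussianPulseParams(1.0, c, 0.5e-6), fine)
        y = apply_decay(x, DecaySpec(tau))
        r = correlate(y.values, x.values, mode="full", method="fft")
        lag = (np.argmax(r) - (len(x) - 1)) * T
        assert abs(lag - tau) < 0.5e-9

    def test_cross_spectrum_phase_matches_analytic_transfer_function(self):
        # Transfer function of the decay kernel is 1/(1 + j w tau): its phase
        # is -arctan(w tau).  Checked where the pulse has spectral content.
        tau = 100e-9
        T = tau / 1000.0
        fine = TimeGrid(sample_period=T, n_samples=20000)
        c = fine.start_time + 0.3 * fine.span
        x = gaussian_pulse(GaussianPulseParams(1.0, c, 50e-9), fine)
        y = apply_decay(x, DecaySpec(tau))
        X = np.fft.rfft(x.values)
        Y = np.fft.rfft(y.values)
        freqs = np.fft.rfftfreq(len(x), T)
        omega = 2 * np.pi * freqs
        keep = (omega * tau <= 1.0) & (omega > 0) & (np.abs(X) > 1e-3 * np.abs(X).max())
        phase = np.angle(Y[keep] / X[keep])
        np.testing.assert_allclose(phase, -np.arctan(omega[keep] * tau), atol=1e-3)

    def test_unit_area_kernel_preserves_integral(self):
        tau = 2e-6
        fine = TimeGrid(sample_period=1e-8, n_samples=4000)  # spans 10 sigma + 10 tau
        c = fine.start_time + 5 * 1e-6
        x = gaussian_pulse(GaussianPulseParams(1.0, c, 1e-6), fine)
        y = apply_decay(x, DecaySpec(tau))
        assert np.sum(y.values) == pytest.approx(np.sum(x.values), rel=1e-3)


class TestMixCrossover:
    def test_identity_matrix_leaves_channels_unchanged(self, gaussian_pair):
        fl1, fl2 = gaussian_pair(0.33e-6)
        fla, flb = mix_crossover(fl1, fl2, CrossoverMatrix.identity())
        np.testing.assert_array_equal(fla.values, fl1.values)
        np.testing.assert_array_equal(flb.values, fl2.values)

    def test_single_fluorochrome_scales_by_coefficients(self, grid, gaussian_pair):
        fl1, _ = gaussian_pair(0.0)
        zero = Waveform(grid, np.zeros(grid.n_samples))
        k = CrossoverMatrix(0.8, 0.15, 0.15, 0.8)
        fla, flb = mix_crossover(fl1, zero, k)
        np.testing.assert_allclose(fla.values, 0.8 * fl1.values)
        np.testing.assert_allclose(flb.values, 0.15 * fl1.values)

    def test_grid_mismatch_rejected(self, grid):
        other = TimeGrid(sample_period=2e-7, n_samples=2048)
        w1 = Waveform(grid, np.ones(grid.n_samples))
        w2 = Waveform(other, np.ones(other.n_samples))
        with pytest.raises(ValueError):
            mix_crossover(w1, w2, CrossoverMatrix.identity())

    @given(a=st.floats(0.1, 10.0))
    def test_linearity_in_scalar_scaling(self, a):
        grid = TimeGrid(1e-7, 256)
        c = 12.8e-6
        fl1 = gaussian_pulse(GaussianPulseParams(1.4, c, 0.5e-6), grid)
        fl2 = gaussian_pulse(GaussianPulseParams(1.2, c + 0.02e-6, 0.5e-6), grid)
        k = CrossoverMatrix(0.8, 0.15, 0.15, 0.8)
        fla, flb = mix_crossover(fl1, fl2, k)
        fla_s, flb_s = mix_crossover(
            Waveform(grid, a * fl1.values), Waveform(grid, a * fl2.values), k
        )
        np.testing.assert_allclose(fla_s.values, a * fla.values, rtol=1e-12)
        np.testing.assert_allclose(flb_s.values, a * flb.values, rtol=1e-12)

    def test_mixed_peak_lies_between_own_term_and_sum(self, grid):
        # First preset row, noiseless: spillover raises the peak above the
        # own-fluorochrome contribution but below the sum of both peaks.
        c = grid.start_time + 0.5 * grid.span
        fl1 = gaussian_pulse(GaussianPulseParams(1.40, c + 0.33e-6, 0.5e-6), grid)
        fl2 = gaussian_pulse(GaussianPulseParams(1.20, c + 0.35e-6, 0.5e-6), grid)
        k = CrossoverMatrix(0.8, 0.15, 0.15, 0.8)
        fla, _ = mix_crossover(fl1, fl2, k)
        peak = fla.values.max()
        assert 0.8 * 1.40 < peak < 0.8 * 1.40 + 0.15 * 1.20


class TestAddNoise:
    def test_infinite_snr_returns_waveform_unchanged(self, gaussian_pair):
        w, _ = gaussian_pair(0.0)
        for snr in (None, np.inf):
            out = add_noise(w, snr, 0)
            np.testing.assert_array_equal(out.values, w.values)

    def test_fixed_seed_is_deterministic(self, gaussian_pair):
        w, _ = gaussian_pair(0.0)
        a = add_noise(w, 30.0, 42)
        b = add_noise(w, 30.0, 42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_realized_snr_matches_request(self):
        grid = TimeGrid(1e-7, 100_000)
        w = Waveform(grid, np.ones(grid.n_samples))
        noisy = add_noise(w, 40.0, 7)
        realized = 10 * np.log10(w.power() / np.mean((noisy.values - w.values) ** 2))
        assert abs(realized - 40.0) < 0.2

    def test_zero_power_rejected(self, grid):
        w = Waveform(grid, np.zeros(grid.n_samples))
        with pytest.raises(ValueError):
            add_noise(w, 30.0, 0)


class TestSimulateEvent:
    def test_trivial_configuration_gives_fla_equal_fl1(self):
        cfg = SimConfig(delay1=0.0, delay2=0.0, snr_db=None)
        ev = simulate_event(cfg, 0)
        np.testing.assert_allclose(ev.fla.values, ev.fl1.values)

    def test_observed_peak_delay_between_component_delays(self):
        # A fine grid so that the raw argmax resolves the 20 ns bracket.
        cfg = SimConfig(
            grid=TimeGrid(sample_period=2e-9, n_samples=4096),
            delay1=0.33e-6,
            delay2=0.35e-6,
            crossover=CrossoverMatrix(0.8, 0.15, 0.15, 0.8),
            snr_db=None,
        )
        ev = simulate_event(cfg, 0)
        t = ev.fs.times()
        shift = t[np.argmax(ev.fla.values)] - t[np.argmax(ev.fs.values)]
        assert 0.33e-6 < shift < 0.35e-6

    def test_batch_is_reproducible_event_by_event(self):
        cfg = SimConfig(snr_db=35.0)
        a = simulate_batch(cfg, 20, seed=99)
        b = simulate_batch(cfg, 20, seed=99)
        for ev_a, ev_b in zip(a, b):
            np.testing.assert_array_equal(ev_a.fla.values, ev_b.fla.values)
            np.testing.assert_array_equal(ev_a.fs.values, ev_b.fs.values)

    def test_peak_ordering_under_positive_crossover(self, grid):
        # Spillover drags the channel-a peak toward the later fluorochrome-2
        # pulse and the channel-b peak toward the earlier fluorochrome 1.
        cfg = SimConfig(
            delay1=0.33e-6,
            delay2=0.35e-6,
            crossover=CrossoverMatrix(0.8, 0.15, 0.15, 0.8),
            snr_db=None,
        )
        ev = simulate_event(cfg, 0)
        N = len(ev.fs)
        da = estimate_delay(ev.fs, ev.fla, 10 * N, 100 * N, refine=True).delay
        db = estimate_delay(ev.fs, ev.flb, 10 * N, 100 * N, refine=True).delay
        assert da > 0.33e-6
        assert db < 0.35e-6


class TestSimulateLedPair:
    def test_equal_hardware_delays_give_zero_interchannel_delay(self, grid):
        ch0, ch1 = simulate_led_pair(2e-6, 2.0, 50e-9, 50e-9, grid)
        np.testing.assert_array_equal(ch0.values, ch1.values)

    def test_peak_positions_differ_by_delay_difference(self, grid):
        ch0, ch1 = simulate_led_pair(2e-6, 2.0, 0.0, 50e-9, grid)
        N = len(ch0)
        est = estimate_delay(ch0, ch1, 10 * N, 100 * N, refine=True)
        assert est.delay == pytest.approx(50e-9, abs=0.5e-9)

    def test_width_sweep_produces_distinct_groups(self, grid):
        widths = np.arange(1.0, 5.0 + 0.25, 0.5) * 1e-6
        assert len(widths) == 9
        peaks = []
        for w in widths:
            ch0, _ = simulate_led_pair(w, 2.0, 0.0, 0.0, grid)
            peaks.append(np.sum(ch0.values))  # integral grows with width
        assert len(np.unique(np.round(peaks, 6))) == 9
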