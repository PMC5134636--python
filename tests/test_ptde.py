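"""Lock-in spillover elimination: phases, modulation, decomposition, recovery."""

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from cytopulse import (
    CrossoverMatrix,
    ModulationConfig,
    SimConfig,
    TimeGrid,
    Waveform,
    lowpass_recover,
    mix_reference,
    modulate,
    phase_decompose,
    phase_from_lifetime,
    run_ptde,
    simulate_event,
)

MOD10 = ModulationConfig.from_frequency_mhz(10.0)


def constant_envelope(mod: ModulationConfig, value=1.0, n_periods=200) -> Waveform:
    period = 1.0 / mod.carrier_rate
    n = int(round(n_periods * mod.carrier_rate / mod.f0))
    return Waveform(TimeGrid(period, n), np.full(n, value))


class TestPhaseFromLifetime:
    def test_zero_lifetime_gives_zero_phase(self):
        assert phase_from_lifetime(0.0, MOD10) == 0.0

    @pytest.mark.parametrize(
        "f_mhz,tau_ns,expected_deg",
        [(20.0, 8.28, 89.65), (50.0, 8.28, 89.86), (20.0, 4.86, 89.41)],
    )
    def test_numeric_convention_phase_table_cells(self, f_mhz, tau_ns, expected_deg):
        mod = ModulationConfig.from_frequency_mhz(f_mhz, convention="mhz-ns")
        phi = np.degrees(phase_from_lifetime(tau_ns * 1e-9, mod))
        assert phi == pytest.approx(expected_deg, abs=0.05)

    def test_si_convention_closed_form(self):
        mod = ModulationConfig.from_frequency_mhz(10.0, convention="si")
        assert phase_from_lifetime(8.28e-9, mod) == pytest.approx(
            np.arctan(2 * np.pi * 1e7 * 8.28e-9)
        )

    def test_strictly_increasing_and_bounded(self):
        taus = np.array([1, 2, 5, 8, 20, 100]) * 1e-9
        phis = [phase_from_lifetime(t, MOD10) for t in taus]
        assert np.all(np.diff(phis) > 0)
        freqs = [1, 2, 5, 10, 20, 50]
        phis_f = [
            phase_from_lifetime(8.28e-9, ModulationConfig.from_frequency_mhz(f)) for f in freqs
        ]
        assert np.all(np.diff(phis_f) > 0)
        assert all(p < np.pi / 2 for p in phis + phis_f)


class TestModulate:
    def test_unit_envelope_gives_pure_cosine(self):
        env = constant_envelope(MOD10)
        out = modulate(env, 0.0, MOD10)
        np.testing.assert_allclose(out.values, np.cos(MOD10.omega0 * env.times()), atol=1e-12)

    def test_zero_envelope_gives_zero(self):
        env = constant_envelope(MOD10, value=0.0)
        env = Waveform(env.grid, np.zeros(len(env)))
        assert np.all(modulate(env, 0.3, MOD10).values == 0)

    def test_rms_is_envelope_rms_over_sqrt2(self):
        env = constant_envelope(MOD10, value=2.0)
        out = modulate(env, 0.7, MOD10)
        assert np.sqrt(out.power()) == pytest.approx(2.0 / np.sqrt(2), rel=1e-3)

    def test_undersampled_carrier_rejected(self):
        coarse = Waveform(TimeGrid(1e-7, 256), np.ones(256))  # 10 MS/s vs 10 MHz carrier
        with pytest.raises(ValueError, match="under-samples"):
            modulate(coarse, 0.0, MOD10)


class TestPhaseDecompose:
    def test_basis_phases_give_unit_vectors(self):
        phi1, phi2 = 0.49, 0.28
        assert phase_decompose(phi1, phi1, phi2) == pytest.approx((1.0, 0.0), abs=1e-15)
        assert phase_decompose(phi2, phi1, phi2) == pytest.approx((0.0, 1.0), abs=1e-15)

    def test_degenerate_basis_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            phase_decompose(0.3, 0.5, 0.5)

    @given(
        phi_x=st.floats(-1.5, 1.5),
        phi1=st.floats(-1.5, 1.5),
        phi2=st.floats(-1.5, 1.5),
    )
    def test_reconstruction_identity(self, phi_x, phi1, phi2):
        assume(abs(np.sin(phi1 - phi2)) > 1e-3)
        c1, c2 = phase_decompose(phi_x, phi1, phi2)
        wt = np.linspace(0.0, 4 * np.pi, 2000)
        resid = np.cos(wt - phi_x) - c1 * np.cos(wt - phi1) - c2 * np.cos(wt - phi2)
        assert np.max(np.abs(resid)) < 1e-12


class TestMixReference:
    def _dc(self, w: Waveform, mod: ModulationConfig) -> float:
        # Mean over an integer number of carrier periods isolates DC exactly.
        samples_per_period = int(round(mod.carrier_rate / mod.f0))
        n = (len(w) // samples_per_period) * samples_per_period
        return float(np.mean(w.values[:n]))

    def test_cophasal_cosine_reference_gives_half_envelope(self):
        env = constant_envelope(MOD10)
        mixed = mix_reference(modulate(env, 0.6, MOD10), 0.6, MOD10)
        assert self._dc(mixed, MOD10) == pytest.approx(0.5, abs=1e-9)

    def test_cophasal_quadrature_reference_nullifies(self):
        env = constant_envelope(MOD10)
        mixed = mix_reference(modulate(env, 0.6, MOD10), 0.6, MOD10, quadrature=True)
        assert abs(self._dc(mixed, MOD10)) < 1e-9

    def test_dc_is_half_cosine_of_phase_difference(self):
        p, q = np.radians(30.0), np.radians(75.0)
        env = constant_envelope(MOD10)
        mixed = mix_reference(modulate(env, p, MOD10), q, MOD10)
        assert self._dc(mixed, MOD10) == pytest.approx(0.5 * np.cos(np.radians(45.0)), abs=1e-6)


class TestLowpassRecover:
    def test_dc_input_passes_unchanged(self):
        w = constant_envelope(MOD10, value=1.0)
        out = lowpass_recover(w, MOD10)
        np.testing.assert_allclose(out.values, 1.0, rtol=1e-3)

    def test_double_frequency_tone_suppressed(self):
        # Steady-state suppression of the 2*f0 mixing product; the first and
        # last samples carry the zero-phase filter's start-up transient, which
        # is irrelevant for pulse envelopes that vanish at the record edges.
        env = constant_envelope(MOD10)
        tone = Waveform(env.grid, np.cos(2 * MOD10.omega0 * env.times()))
        out = lowpass_recover(tone, MOD10)
        interior = out.values[400:-400]
        assert np.sqrt(np.mean(interior**2)) <= 1e-3 * np.sqrt(tone.power())

    def test_frequency_response_attenuation_at_double_carrier(self):
        from scipy.signal import butter, sosfreqz

        rate = MOD10.carrier_rate
        sos = butter(6, MOD10.lpf_cutoff / (rate / 2), btype="low", output="sos")
        _, h = sosfreqz(sos, worN=[2 * np.pi * 2 * MOD10.f0 / rate])
        # double pass (forward-backward) squares the magnitude: >> 60 dB down
        assert abs(h[0]) ** 2 < 1e-6

    def test_gaussian_envelope_recovered_with_half_cos_scale(self):
        mod = MOD10
        period = 1.0 / mod.carrier_rate
        n = 4096
        grid = TimeGrid(period, n)
        t = grid.times()
        c = 0.5 * grid.span
        env = np.exp(-(((t - c) / 2e-6) ** 2))
        p, q = 0.49, 0.28
        mixed = Waveform(grid, env * np.cos(mod.omega0 * t - p) * np.cos(mod.omega0 * t - q))
        out = lowpass_recover(mixed, mod)
        expected = 0.5 * np.cos(p - q) * env
        assert np.max(np.abs(out.values - expected)) < 0.01 * expected.max()

    def test_cutoff_above_carrier_rejected(self):
        with pytest.raises(ValueError):
            ModulationConfig.from_frequency_mhz(10.0, lpf_cutoff=20e6)


class TestRunPtde:
    def _event(self, crossover, snr=None, seed=0):
        cfg = SimConfig(
            delay1=8.48e-9,
            delay2=4.67e-9,
            lifetime1=8.48e-9,
            lifetime2=4.67e-9,
            crossover=crossover,
            snr_db=snr,
            mode="shift",
        )
        return simulate_event(cfg, seed)

    def test_identity_crossover_nothing_to_remove(self):
        ev = self._event(CrossoverMatrix.identity())
        rec = run_ptde(ev.channels(), 8.48e-9, 4.67e-9, 8.48e-9, 4.67e-9, MOD10)
        assert rec.residual_unwanted < 1e-6
        assert rec.coeffs.C3 == pytest.approx(1.0, abs=1e-12)
        assert rec.coeffs.C4 == pytest.approx(0.0, abs=1e-12)
        # Recovered pulse is the observed channel scaled by the amplitude factor.
        expected_peak = rec.amplitude_factor * ev.fla.values.max()
        assert np.max(rec.fl1_hat.values) == pytest.approx(expected_peak, rel=5e-3)

    def test_amplitude_factor_matches_closed_form_per_mode(self):
        ev = self._event(CrossoverMatrix(0.8, 0.15, 0.15, 0.8))
        phi1 = phase_from_lifetime(8.48e-9, MOD10)
        phi2 = phase_from_lifetime(4.67e-9, MOD10)
        quad = run_ptde(ev.channels(), 8e-9, 5e-9, 8.48e-9, 4.67e-9, MOD10)
        assert quad.amplitude_factor == 0.5 * abs(np.sin(phi1 - phi2))
        lit = run_ptde(
            ev.channels(), 8e-9, 5e-9, 8.48e-9, 4.67e-9, MOD10, literal_cos_reference=True
        )
        assert lit.amplitude_factor == 0.5 * np.cos(phi1 - phi2)

    def test_quadrature_nullification_residual_below_threshold(self):
        ev = self._event(CrossoverMatrix(0.8, 0.15, 0.15, 0.8))
        rec = run_ptde(ev.channels(), 7.95e-9, 5.35e-9, 8.48e-9, 4.67e-9, MOD10)
        assert 0 < rec.residual_unwanted < 1e-3

    def test_literal_cosine_reference_does_not_nullify(self):
        ev = self._event(CrossoverMatrix(0.8, 0.15, 0.15, 0.8))
        rec = run_ptde(
            ev.channels(), 7.95e-9, 5.35e-9, 8.48e-9, 4.67e-9, MOD10, literal_cos_reference=True
        )
        assert rec.residual_unwanted > 0.4  # unwanted DC survives at ~cos(0)/2

    def test_degenerate_lifetimes_rejected(self):
        ev = self._event(CrossoverMatrix.identity())
        with pytest.raises(ValueError, match="degenerate"):
            run_ptde(ev.channels(), 8e-9, 5e-9, 6e-9, 6e-9, MOD10)
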