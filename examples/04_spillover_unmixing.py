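"""Eliminate two-color spectral spillover with the digital lock-in chain.

Lifetimes map to carrier phase shifts phi = arctan(omega0*tau).  The mixed
channels are modulated at their measured phases, mixed with quadrature
references at the unwanted component's phase, and low-pass filtered: the
unwanted fluorophore's DC contribution vanishes and the surviving component
is rescaled by the decomposition coefficient.
"""

import numpy as np

from cytopulse import (
    CrossoverMatrix,
    ModulationConfig,
    SimConfig,
    estimate_delay,
    phase_from_lifetime,
    run_ptde,
    simulate_event,
)

TAU1, TAU2 = 8.48e-9, 4.67e-9

cfg = SimConfig(
    delay1=TAU1,
    delay2=TAU2,
    crossover=CrossoverMatrix(0.80, 0.15, 0.15, 0.80),
    snr_db=35.0,
)
ev = simulate_event(cfg, 4)
N = len(ev.fs)

# Spillover-biased lifetimes measured on the observed channels (no hardware
# delay in this configuration, so raw delays are lifetimes already).
tau_a = estimate_delay(ev.fs, ev.fla, 10 * N, 100 * N, refine=True).delay
tau_b = estimate_delay(ev.fs, ev.flb, 10 * N, 100 * N, refine=True).delay
print(f"mixed-channel lifetimes : tau_a = {tau_a*1e9:.2f} ns (true tau1 {TAU1*1e9:.2f}),"
      f" tau_b = {tau_b*1e9:.2f} ns (true tau2 {TAU2*1e9:.2f})")

mod = ModulationConfig.from_frequency_mhz(10.0)
phi1 = np.degrees(phase_from_lifetime(TAU1, mod))
phi2 = np.degrees(phase_from_lifetime(TAU2, mod))
print(f"phase shifts at 10 MHz  : phi1 = {phi1:.2f} deg, phi2 = {phi2:.2f} deg")

rec = run_ptde(ev.channels(), tau_a, tau_b, TAU1, TAU2, mod)
print(f"decomposition           : C3 = {rec.coeffs.C3:.3f}, C4 = {rec.coeffs.C4:.3f}, "
      f"D3 = {rec.coeffs.D3:.3f}, D4 = {rec.coeffs.D4:.3f}")
print(f"amplitude factor        : {rec.amplitude_factor:.4f}  "
      f"(= |sin(phi1-phi2)|/2); nullified-component residual {rec.residual_unwanted:.2e}")

r1 = estimate_delay(ev.fs, rec.fl1_hat, 10 * N, 100 * N, refine=True).delay
r2 = estimate_delay(ev.fs, rec.fl2_hat, 10 * N, 100 * N, refine=True).delay
print(f"recovered lifetimes     : {r1*1e9:.2f} / {r2*1e9:.2f} ns "
      f"(biased were {tau_a*1e9:.2f} / {tau_b*1e9:.2f})")
# The recovered pair sits on the true lifetimes while the mixed-channel pair
# is dragged toward each other by the spillover.
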