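# cytopulse

Fluorescence-lifetime signal processing for flow cytometry: simulate
cytometric pulse waveforms, estimate fluorescence–scatter time delays with
sub-sample resolution, calibrate out hardware delays, and eliminate
two-color spectral spillover with a digital lock-in chain.

## The problem

In multicolor flow cytometry the emission spectra of common fluorophores
overlap, so each detector channel sees a mixture of dyes ("spillover").
Intensity-based compensation is fragile because detection is nonlinear and
peak values vary widely between events.  The fluorescence *lifetime* — the
mean excited-state dwell time τ, typically a few nanoseconds — offers an
intensity-independent handle: a fluorescence pulse lags the forward-scatter
pulse by τ, and under a carrier at angular frequency ω₀ the lifetime maps to
a phase shift φ = arctan(ω₀τ).

`cytopulse` implements the full processing chain:

1. **Pulse model.**  A cell transiting the Gaussian laser profile produces
   Gaussian pulses: `fs = K·exp(−(t−t₀)²/2σ²)` for forward scatter and
   per-dye fluorescence pulses delayed by their lifetimes.  Detector
   channels observe spillover mixtures `fla = k₁₁·fl₁ + k₂₁·fl₂`,
   `flb = k₁₂·fl₁ + k₂₂·fl₂` plus per-channel hardware delays and noise
   (`cytopulse.pulsesim`).
2. **Sub-sample delay estimation.**  The zoomed spectrum
   `X(k) = Σₙ x[n]·exp(−j2πkn/N₁)` (a partial-band chirp Z-transform,
   N₁/N-times finer than the FFT) is computed for both pulses; the
   cross-spectrum is zero-padded to length N₂ and inverse transformed,
   yielding a correlation lag comb of spacing `T·N₁/N₂` — a resolution gain
   of N₂/N₁ over the ADC period T.  Only the first/last N fine lags are
   evaluated, in O(N log N) independent of N₂
   (`cytopulse.zoomspec`, `cytopulse.ficp`).
3. **Calibration.**  Synchronously pulsed LED pairs measure the constant
   delay contributed by the detection electronics; subtracting it turns raw
   delays into lifetimes (`cytopulse.calib`).
4. **Spillover elimination.**  Observed envelopes are digitally modulated at
   the phases of their measured lifetimes; since
   `cos(ω₀t−φₐ) = C₃·cos(ω₀t−φ₁) + C₄·cos(ω₀t−φ₂)` with
   `C₃ = sin(φₐ−φ₂)/sin(φ₁−φ₂)`, mixing with a quadrature reference at the
   unwanted dye's phase followed by zero-phase low-pass filtering nullifies
   that dye's DC contribution exactly, leaving the wanted component scaled
   by `|sin(φ₁−φ₂)|/2` (`cytopulse.ptde`).
5. **Metrics.**  Spillover peak/delay error reports, a Gauss-fit baseline
   estimator with RMSE/R², and cohort SD/RSD statistics
   (`cytopulse.evalmetrics`, `cytopulse.experiments`).

No external dataset is required: the simulator generates all inputs with
full ground truth.

## Worked example

`examples/` contains one narrative script per capability.  Running
`python examples/04_spillover_unmixing.py` simulates a two-color event with
strong spillover (k₁₁ = k₂₂ = 0.80, k₁₂ = k₂₁ = 0.15, lifetimes
8.48/4.67 ns, 35 dB SNR) and prints:

```
mixed-channel lifetimes : tau_a = 7.97 ns (true tau1 8.48), tau_b = 5.16 ns (true tau2 4.67)
phase shifts at 10 MHz  : phi1 = 28.05 deg, phi2 = 16.35 deg
decomposition           : C3 = 0.877, C4 = 0.125, D3 = 0.138, D4 = 0.865
amplitude factor        : 0.1014  (= |sin(phi1-phi2)|/2); nullified-component residual 2.08e-08
recovered lifetimes     : 8.48 / 4.67 ns (biased were 7.97 / 5.16)
```

Reading: spillover drags the two channels' apparent lifetimes toward each
other (7.97 < 8.48 ns, 5.16 > 4.67 ns).  The decomposition coefficients
C₃/C₄ express the observed phase carrier in the pure-dye basis; after
quadrature mixing and low-pass filtering the unwanted dye contributes less
than 10⁻⁷ of its amplitude, and the recovered lifetimes sit on the truth.

The delay estimator itself (`examples/02_subsample_delay_estimation.py`)
recovers a 758.6 ns shift sampled at 100 ns as 760.00 ns on the fine lag
grid (10 ns steps) and 758.6001 ns with parabolic peak refinement.

A thin CLI wraps the same calls
(`cytopulse simulate|delay|calibrate|ptde|report|experiment`, see
`cytopulse --help`).

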