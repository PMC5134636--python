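# Methods

This note documents the models, numerical choices and limitations behind
`cytopulse`: what the simulator emulates, how the estimators work, which
parameters matter, and what the tests do and do not demonstrate.

## Signal model

A cell transiting a focused laser beam with a Gaussian intensity profile
produces Gaussian time-intensity pulses.  The forward-scatter pulse

    fs(t) = K · exp(−(t − t₀)² / 2σ²)

is the lifetime-free timing reference.  Each fluorophore's emission follows
a single-exponential decay with lifetime τ, so the fluorescence pulse is the
convolution of the excitation pulse with the causal unit-area kernel
(1/τ)·e^(−t/τ).  Because the kernel's transfer function is 1/(1 + jωτ), the
fluorescence pulse is, to first order in τ/σ, the excitation pulse delayed
by τ with a phase response −arctan(ωτ).  For nanosecond lifetimes and
microsecond pulses the skew introduced by the convolution is O(τ²/σ) — of
order 10⁻⁴ ns here — which is why the delay of the correlation peak equals
τ to very high accuracy.

Detector channels a and b observe spillover mixtures through a 2×2
crossover matrix with entries k∈[0,1]:

    fla = k₁₁·fl₁ + k₂₁·fl₂,   flb = k₁₂·fl₁ + k₂₂·fl₂,

each further delayed by its detection chain (detector, amplifier, cabling,
ADC path), modelled as a pure per-channel group delay.  Mixing two Gaussian
pulses whose centres differ by much less than their width yields another
near-Gaussian whose peak sits at the amplitude-weighted mean of the
component centres; this is the mechanism by which spillover biases the
apparent lifetime of channel a toward τ₂ and of channel b toward τ₁, and
it also implies the peak-*value* distortion is first-order in the spillover
coefficients while the peak-*location* distortion is scaled by the small
lifetime difference — peak errors of tens of percent against delay errors
of a few percent in the bundled error-table experiment.

## Simulator (study conditions)

The generator's defaults define the conditions under which all bundled
experiments and tests run.  Values the underlying measurement scenario
fixes are used as given (two-color amplitudes 1.40/1.20 V, crossover rows
of the preset table, lifetimes 8.48/4.67 ns for the recovery study, LED
calibration pulses of 2 V peak with FWHM swept 1–5 µs in 0.5 µs steps).
Conditions the scenario leaves open were chosen once, as follows, and not
tuned:

- **Transit width** σ = 0.5 µs (FWHM ≈ 1.2 µs), consistent with the µs-scale
  calibration pulse widths; configurable.
- **Acquisition grid**: 10 MS/s (T = 100 ns), 2048 samples per event
  (~205 µs window), 0-based sample index, time = index·T.
- **Forward-scatter amplitude** 2.0 V — the half-scale working level the
  calibration bench also uses.
- **Noise**: additive white Gaussian per observed channel (fs, fla, flb),
  scaled to a requested signal-to-noise *power* ratio where signal power is
  the mean square over the event window; default 40 dB, 35 dB in the
  recovery study, `None`/∞ for noiseless runs.  Photon-counting (Poisson)
  statistics, PMT saturation and doublet events are not modelled, so test
  outcomes speak to additive-noise robustness only.
- **Hardware delays** 120/180 ns for channels a/b in the recovery study —
  arbitrary realistic electronics offsets whose exact values are irrelevant
  because calibration removes any constant offset (verified by a dedicated
  invariance test).
- **Delay realisation**: `"shift"` mode evaluates the fluorescence Gaussian
  analytically at a shifted centre (exact at any sub-sample delay and used
  wherever ns-scale delays matter at the 100 ns grid); `"decay"` mode runs
  the exponential-kernel recursion (the physical picture, accurate when
  T ≪ τ, i.e. on fine grids).  Both store full ground truth.

The decay recursion is y[n] = a·y[n−1] + (1−a)·x[n] with a = e^(−T/τ): unit
DC gain (integral preserved exactly) and first moment T/(e^(T/τ)−1) ≈
τ − T/2, so on coarse grids (T ≫ τ) it degenerates toward a pure gain —
the reason ns lifetimes on the 100 ns grid are realised in shift mode.

## Delay estimation: zoomed spectra and fine correlation lags

Cytometric pulses occupy ≲1 MHz of a 10 MS/s record, so the estimator works
on a zoomed frequency comb.  The zoom transform

    X(k) = Σ_{n=0}^{N−1} x[n]·exp(−j2πkn/N₁),  k = 0..N−1,  N₁ ≥ N

has bin spacing 1/(N₁T), N₁/N-times finer than the FFT, and is evaluated as
a partial-band chirp Z-transform (Bluestein) in O(N log N); an O(N²) direct
sum serves as the independent oracle in the tests.  A validation helper
warns when the covered band (N−1)/(N₁T) falls below the pulse bandwidth
3/(2πσ), since a too-aggressive zoom truncates the cross-spectrum and blurs
the correlation peak.  Default N₁/N = 10 keeps a 1 MHz band, comfortably
above the 0.32 MHz pulse bandwidth.

The cross-spectrum of reference and probe is zero-padded to length N₂ with
conjugate-symmetric mirroring; its inverse transform is the band-limited
cross-correlation on a lag comb of spacing T·N₁/N₂ — a lag-resolution gain
of N₂/N₁ (default 10, fine step 10 ns) obtained without resampling.  Delays
of interest are small compared with the record, so only the first and last
N fine lags are assembled.  For a head-plus-mirror spectrum the inverse at
index n reduces to (2·Re S(n) − R(0))/N₂ with S(n) = Σ_k R(k)e^(+j2πkn/N₂),
and each edge segment of S is itself a chirp Z-transform: cost O(N log N)
independent of N₂, while the full-length inverse FFT is retained as the
test oracle.  Orientation is chosen so that positive lag means the probe
lags the reference; the estimated delay is then simply the lag of the
correlation maximum.

Estimator contracts and numerical choices:

- Capture range |delay| < N·T·N₁/N₂; exact peak ties break toward zero lag.
- Noiseless continuous shifts are recovered within half a fine step
  (grid-argmax bound, verified over random sub-sample shifts).
- Optional three-point parabolic refinement of the peak (off by default)
  reaches well below the fine step: the correlation peak of 0.5 µs pulses
  is locally parabolic over ±10 ns to a relative error of ~2·10⁻⁴, and the
  refined estimate of a 758.6 ns shift is accurate to ≲0.1 ps noiselessly.
  Refinement is used wherever ns-scale lifetimes are the target.
- Zero-power inputs and flat correlations raise degenerate-input errors.

At 30 dB SNR the root-mean-square delay error over seeded cohorts falls as
N₂/N₁ grows through {1, 2, 5, 10} (from ~27 ns, dominated by the 100 ns lag
quantisation, to ~3 ns), which is the advertised point of the zero-padding:
finer lag grids harvest accuracy the correlation already contains.

## Hardware-delay calibration

The measured fluorescence–scatter delay is lifetime plus a constant
electronics offset.  Two synchronously pulsed LEDs (zero true inter-channel
phase shift) feed the scatter and fluorescence paths; the per-pair delay is
then pure hardware.  The calibration record stores the mean and sample SD
over pairs, pooled across the pulse-width sweep into one global per-channel
constant (dispersive, width-dependent electronics are out of scope — the
transfer functions are treated as pure group delays).  Subtracting the
record from a raw delay yields the lifetime; because the offset is
constant, the recovered lifetime is independent of the injected hardware
delay to within a fine step.  The bundled recovery study uses 200 pairs per
width group (1800 per channel, 40 dB bench SNR), giving a calibration
standard error near 0.01 ns; cohort sizes are configurable.

## Lock-in spillover elimination

Lifetimes map to carrier phases φ = arctan(ω₀τ).  Two unit conventions are
implemented: `"si"` (φ = arctan(2πf·τ), everything SI; the default and the
convention used by the processing chain) and `"mhz-ns"`
(φ = arctan(f[MHz]·τ[ns])), the numeric convention under which published
phase tables at tens of MHz read 89°+; the bundled phase-table experiment
reports both side by side.  Note 2πf·τ and f[MHz]·τ[ns] differ by 2π·10⁻³,
so the conventions are not numerically interchangeable.

The observed envelopes (Gaussian fits to fla/flb) are re-synthesised
analytically on a carrier-rate grid (default 20 samples per carrier period,
window spanning the fitted centres ±6 widths) and multiplied by
cos(ω₀t − φ).  The exact trigonometric identity

    cos(ω₀t − φₐ) = C₃·cos(ω₀t − φ₁) + C₄·cos(ω₀t − φ₂),
    C₃ = sin(φₐ − φ₂)/sin(φ₁ − φ₂),  C₄ = sin(φ₁ − φₐ)/sin(φ₁ − φ₂)

(obtained by matching cosine/sine coefficients; degenerate when φ₁ = φ₂ mod
π) expresses the mixed channel in the pure-dye phase basis.  For small
phases C₃ → (τₐ−τ₂)/(τ₁−τ₂), which is precisely the amplitude fraction of
dye 1 in the mixture — multiplying the observed peak by C₃ undoes the
spillover inflation.

Mixing with a reference carrier at phase q turns a component at phase p
into a DC term cos(p−q)/2 (cosine reference) or sin(p−q)/2 (quadrature
reference).  A cosine reference at the unwanted phase leaves that
component's DC at 1/2 — it does not nullify.  The package therefore
defaults to the **quadrature** reference (sine at the unwanted phase),
whose DC for the unwanted component is sin(0)/2 = 0 identically; the
surviving component is scaled by the amplitude factor |sin(φ₁−φ₂)|/2.  The
in-phase variant (amplitude factor cos(φ₁−φ₂)/2, no nullification) remains
available as `literal_cos_reference` for comparison, and its
non-nullification is itself under test.

Low-pass filtering is a zero-phase (forward–backward) 6th-order Butterworth
with cutoff f₀/2: ≈72 dB single-pass attenuation at the 2f₀ mixing product
(double that after the second pass), flat to ~10⁻¹⁴ over the envelope
bandwidth, and no peak-location shift — a hard contract because recovered
peak positions feed lifetime re-estimation.  Padding extends ten cutoff
periods past each record edge so start-up transients stay clear of the
envelope; the first/last samples of a record that is non-zero at its edges
(e.g. a pure test tone) still carry the initial-condition transient, which
is irrelevant for pulse envelopes that vanish there.  The reported
`residual_unwanted` is measured numerically per event: the nullified
component is modulated, mixed and filtered in isolation and its residual
quoted as a fraction of its pre-mix amplitude (~2·10⁻⁸ with the quadrature
reference; 0 exactly when the decomposition coefficient vanishes).

Recovered signals are reconstructed per the processing chain's stated form:
Gaussian envelopes at the forward-scatter centre plus τ₁/τ₂, widths from
the observed-channel fits, amplitudes from the numerically recovered
post-filter envelopes (decomposition coefficient × amplitude factor ×
observed peak).  How recovered lifetimes should be re-estimated is a
genuinely open design point; this package re-runs the correlation estimator
between the observed forward-scatter pulse and the reconstruction, which
keeps the re-estimate on the same footing as the direct measurements.  The
reconstruction inherits its centre from the supplied τ₁/τ₂ (the cohort-level
single-stain estimates), so per-event recovered lifetimes cluster tightly
around those values — the recovery study's "fraction improved" therefore
measures whether transferring the cohort's single-stain lifetime knowledge
through the lock-in chain beats the per-event spillover-biased estimate,
which is the operational question.

## Baseline fit and statistics

The Gauss-fit baseline fits a·e^(−((t−b)/c)²) (σ = c/√2) by bounded
least squares, initialised from the sampled maximum and half-width, with
parameter tolerances of 10⁻¹². RMSE is √(mean squared residual); R² is the
regression sum of squares over the total sum of squares, Σ(fit−ȳ)²/Σ(y−ȳ)²
— the printed variant of the regression sum that carries an extra 1/n
factor is not used, because it breaks the requirement R² ∈ [0, 1] that the
quantity is meant to satisfy.  On noiseless pulses the fitted-centre
difference and the correlation estimator agree to within a fine step;
under noise the correlation estimator has visibly smaller dispersion, which
is the argument for it.  Cohort statistics are mean, sample SD (n−1
denominator) and RSD = 100·SD/mean.

## End-to-end recovery study

The `recovery` experiment chains everything: per-channel LED calibration →
single-stain cohorts (identity crossover, 200 events each) estimating
τ̂₁/τ̂₂ → a 200-event mixed cohort (preset crossover row 1, 35 dB SNR,
τ₁ = 8.48 ns, τ₂ = 4.67 ns) measuring biased τ̂ₐ/τ̂_b → per-event lock-in
unmixing at 10 MHz → re-estimated recovered lifetimes.  An event counts as
improved when its recovered lifetime pair is strictly closer to the true
pair in Euclidean distance than its biased pair; per-channel fractions are
also reported.  Under the default conditions the mixed means come out near
7.97/5.43 ns (biased toward each other, as the mixture model predicts), the
recovered means within a few hundredths of a ns of truth, and essentially
all events improve.  The study takes ~25 s on one CPU; all cohort sizes are
arguments.

## Reproducibility

Every stochastic routine takes an explicit seed (integer or
`numpy.random.SeedSequence`); batches spawn independent child streams per
event and per channel, so cohorts are bit-reproducible event by event and
insensitive to cohort size changes upstream.  Event tables round-trip
through CSV at full float precision (reading uses round-trip float
parsing).

## Known limitations

- Single-exponential decay only; multi-exponential and autofluorescence
  decomposition are out of scope (autofluorescence is treated as part of
  the observed emission).
- Two fluorochromes; the phase-basis decomposition as implemented is 2×2.
- Additive Gaussian noise only (no photon statistics, saturation or
  coincidence events), so synthetic benchmarks bound performance under
  that noise model, not under shot-noise-limited detection.
- The electronics are pure group delays; frequency-dependent (dispersive)
  hardware would require per-frequency calibration that the model does not
  attempt.
- In decay mode the recursion under-delays when T is not ≪ τ (first moment
  τ − T/2 + …); shift mode exists for exactly that regime.
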