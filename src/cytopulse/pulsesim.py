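"""Synthetic cytometric event generation with full ground truth.

A cell crossing a Gaussian laser profile produces Gaussian time-intensity
pulses: a forward-scatter pulse ``fs`` (the timing reference, free of
fluorescence lifetime) and per-fluorochrome fluorescence pulses ``fl1``,
``fl2``.  The fluorescence excited state decays exponentially with lifetime
``tau``, which delays the fluorescence pulse relative to forward scatter by
``tau``; detection electronics add a further per-channel hardware delay.
Spectral spillover mixes the two fluorochromes into the observed detector
channels ``fla`` and ``flb`` through a 2x2 crossover matrix.

The simulator realises the fluorescence delay in one of two equivalent views:

``"shift"``
    the fluorescence pulse is an analytically evaluated Gaussian whose centre
    is shifted by the configured delay (exact at any sub-sample shift);
``"decay"``
    the pulse is convolved with a causal unit-area exponential kernel
    ``(1/tau) exp(-t/tau)``, which shifts the pulse by ``tau`` and skews it
    slightly -- the physical picture.

Both views store complete ground truth so estimators can be scored against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .waveform import TimeGrid, Waveform

__all__ = [
    "GaussianPulseParams",
    "DecaySpec",
    "CrossoverMatrix",
    "EventTruth",
    "EventRecord",
    "SimConfig",
    "DEFAULT_GRID",
    "gaussian_pulse",
    "apply_decay",
    "mix_crossover",
    "add_noise",
    "simulate_event",
    "simulate_batch",
    "simulate_led_pair",
]

#: Default acquisition grid: 10 MS/s (100 ns period), 2048 samples (~205 us).
DEFAULT_GRID = TimeGrid(sample_period=1e-7, n_samples=2048)

#: Default transit-pulse width (seconds).  Cytometric pulse widths are a few
#: microseconds; 0.5 us standard deviation gives a ~1.2 us FWHM pulse.
DEFAULT_SIGMA = 0.5e-6


@dataclass(frozen=True)
class GaussianPulseParams:
    """Amplitude (V), centre (s) and standard deviation (s) of a Gaussian pulse."""

    amplitude: float
    center: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class DecaySpec:
    """Single-exponential fluorescence decay: lifetime ``tau`` (s) and gain."""

    lifetime: float
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.lifetime < 0:
            raise ValueError(f"lifetime must be non-negative, got {self.lifetime}")
        if not self.gain > 0:
            raise ValueError(f"gain must be positive, got {self.gain}")


@dataclass(frozen=True)
class CrossoverMatrix:
    """Spectral spillover coefficients.

    ``fla = k11*fl1 + k21*fl2`` and ``flb = k12*fl1 + k22*fl2``: ``k11``/``k12``
    are the fractions of fluorochrome 1 reaching detectors a/b, ``k21``/``k22``
    the fractions of fluorochrome 2.
    """

    k11: float
    k12: float
    k21: float
    k22: float

    def __post_init__(self) -> None:
        for name in ("k11", "k12", "k21", "k22"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def identity(cls) -> "CrossoverMatrix":
        return cls(1.0, 0.0, 0.0, 1.0)


@dataclass(frozen=True)
class EventTruth:
    """Ground-truth parameters of a simulated event."""

    fs_params: GaussianPulseParams
    fl1_params: GaussianPulseParams
    fl2_params: GaussianPulseParams
    decay1: DecaySpec
    decay2: DecaySpec
    crossover: CrossoverMatrix
    hw_delay_a: float
    hw_delay_b: float
    delay1: float
    delay2: float
    snr_db: Optional[float]
    mode: str


@dataclass
class EventRecord:
    """The five linked waveforms of one event, sharing a single grid.

    ``fl1``/``fl2`` are the noiseless per-fluorochrome pulses before spillover
    and before the hardware delay of the detection channels; ``fs``, ``fla``
    and ``flb`` are the observed (noisy, delayed, mixed) channels.
    """

    fs: Waveform
    fl1: Waveform
    fl2: Waveform
    fla: Waveform
    flb: Waveform
    truth: Optional[EventTruth] = None
    event_id: int = 0

    def __post_init__(self) -> None:
        grid = self.fs.grid
        for name in ("fl1", "fl2", "fla", "flb"):
            if getattr(self, name).grid != grid:
                raise ValueError(f"channel {name} is not on the shared event grid")

    def channels(self) -> dict:
        return {"fs": self.fs, "fl1": self.fl1, "fl2": self.fl2, "fla": self.fla, "flb": self.flb}


def gaussian_pulse(params: GaussianPulseParams, grid: TimeGrid) -> Waveform:
    """Evaluate ``amplitude * exp(-(t - center)^2 / (2 sigma^2))`` on ``grid``.

    Warns if the grid does not span ``center +/- 5 sigma``, in which case the
    pulse is clipped at the window edges.
    """
    t0, t1 = grid.start_time, grid.start_time + grid.span
    if params.center - 5 * params.sigma < t0 or params.center + 5 * params.sigma > t1:
        warnings.warn(
            "grid does not span pulse center +/- 5 sigma; pulse will be clipped",
            stacklevel=2,
        )
    t = grid.times()
    values = params.amplitude * np.exp(-((t - params.center) ** 2) / (2.0 * params.sigma**2))
    return Waveform(grid, values)


def apply_decay(pulse: Waveform, spec: DecaySpec) -> Waveform:
    """Convolve a pulse with a causal unit-area exponential decay kernel.

    Discretised as the exact first-order recursion
    ``y[n] = a*y[n-1] + (1-a)*x[n]`` with ``a = exp(-T/tau)``, which has unit
    DC gain (the waveform integral is preserved) and first moment
    ``T / (exp(T/tau) - 1) ~= tau - T/2``; on grids with ``T << tau`` the
    output is the input delayed by ``tau`` to within half a sample period.
    ``lifetime = 0`` reduces to a pure gain.
    """
    if spec.lifetime == 0.0:
        return Waveform(pulse.grid, spec.gain * pulse.values)
    T = pulse.grid.sample_period
    a = float(np.exp(-T / spec.lifetime))
    y = lfilter([1.0 - a], [1.0, -a], pulse.values)
    return Waveform(pulse.grid, spec.gain * y)


def mix_crossover(
    fl1: Waveform, fl2: Waveform, k: CrossoverMatrix
) -> tuple[Waveform, Waveform]:
    """Apply spectral spillover: returns ``(fla, flb)`` sample-wise mixes."""
    if fl1.grid != fl2.grid:
        raise ValueError("fl1 and fl2 must share one grid")
    fla = Waveform(fl1.grid, k.k11 * fl1.values + k.k21 * fl2.values)
    flb = Waveform(fl1.grid, k.k12 * fl1.values + k.k22 * fl2.values)
    return fla, flb


def add_noise(w: Waveform, snr_db: Optional[float], rng_seed) -> Waveform:
    """Add white Gaussian noise at the requested signal-to-noise power ratio.

    The signal power is the mean squared value of ``w`` over its grid; the
    noise variance is ``power / 10^(snr_db/10)``.  ``snr_db`` of ``None`` or
    ``+inf`` returns the waveform unchanged.  ``rng_seed`` may be an integer
    seed or a ``numpy.random.Generator``.
    """
    if snr_db is None or np.isinf(snr_db):
        return w.copy()
    power = w.power()
    if power == 0.0:
        raise ValueError("waveform has zero power; SNR is undefined")
    rng = np.random.default_rng(rng_seed)
    noise_sd = float(np.sqrt(power / 10.0 ** (snr_db / 10.0)))
    return Waveform(w.grid, w.values + rng.normal(0.0, noise_sd, len(w)))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated event population.

    Amplitudes are in volts, times in seconds.  ``delay1``/``delay2`` are the
    fluorescence pulse delays relative to forward scatter; in ``"shift"`` mode
    they displace the pulse centres directly, while in ``"decay"`` mode the
    delays arise from exponential-decay convolution with ``lifetime1``/
    ``lifetime2`` (and ``delay1``/``delay2`` are ignored).  Hardware delays
    apply to the observed detector channels a and b.
    """

    grid: TimeGrid = DEFAULT_GRID
    fs_amplitude: float = 2.0
    fl1_amplitude: float = 1.40
    fl2_amplitude: float = 1.20
    sigma: float = DEFAULT_SIGMA
    t0: Optional[float] = None  # defaults to the grid midpoint
    delay1: float = 0.33e-6
    delay2: float = 0.35e-6
    lifetime1: float = 0.0
    lifetime2: float = 0.0
    crossover: CrossoverMatrix = field(default_factory=CrossoverMatrix.identity)
    hw_delay_a: float = 0.0
    hw_delay_b: float = 0.0
    snr_db: Optional[float] = 40.0
    mode: str = "shift"

    def __post_init__(self) -> None:
        if self.mode not in ("shift", "decay"):
            raise ValueError(f"mode must be 'shift' or 'decay', got {self.mode!r}")
        for name in ("fs_amplitude", "fl1_amplitude", "fl2_amplitude", "sigma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.lifetime1 < 0 or self.lifetime2 < 0:
            raise ValueError("lifetimes must be non-negative")

    @property
    def center(self) -> float:
        if self.t0 is not None:
            return self.t0
        return self.grid.start_time + 0.5 * self.grid.span

    def effective_delays(self) -> tuple[float, float]:
        """True fluorescence delays relative to forward scatter (seconds)."""
        if self.mode == "decay":
            return self.lifetime1, self.lifetime2
        return self.delay1, self.delay2


def _fluor_channel(
    cfg: SimConfig, amplitude: float, delay: float, lifetime: float, hw: float
) -> Waveform:
    """One fluorescence contribution, delayed by lifetime/shift plus hardware."""
    if cfg.mode == "shift":
        params = GaussianPulseParams(amplitude, cfg.center + delay + hw, cfg.sigma)
        return gaussian_pulse(params, cfg.grid)
    base = gaussian_pulse(GaussianPulseParams(amplitude, cfg.center + hw, cfg.sigma), cfg.grid)
    return apply_decay(base, DecaySpec(lifetime))


def simulate_event(config: SimConfig, rng_seed) -> EventRecord:
    """Generate one event: build fl1/fl2, mix spillover, add channel noise.

    The observed channels ``fs``, ``fla``, ``flb`` carry independent noise
    streams derived deterministically from ``rng_seed``; ``fl1``/``fl2`` are
    stored noiseless as ground-truth originals.
    """
    d1, d2 = config.effective_delays()
    c = config.center
    fs = gaussian_pulse(GaussianPulseParams(config.fs_amplitude, c, config.sigma), config.grid)
    # Originals: no hardware delay, no spillover.
    fl1 = _fluor_channel(config, config.fl1_amplitude, config.delay1, config.lifetime1, 0.0)
    fl2 = _fluor_channel(config, config.fl2_amplitude, config.delay2, config.lifetime2, 0.0)
    # Observed: each detector channel sees both fluorochromes through the
    # crossover matrix, delayed by its own electronics.
    fl1_a = _fluor_channel(config, config.fl1_amplitude, config.delay1, config.lifetime1, config.hw_delay_a)
    fl2_a = _fluor_channel(config, config.fl2_amplitude, config.delay2, config.lifetime2, config.hw_delay_a)
    fl1_b = _fluor_channel(config, config.fl1_amplitude, config.delay1, config.lifetime1, config.hw_delay_b)
    fl2_b = _fluor_channel(config, config.fl2_amplitude, config.delay2, config.lifetime2, config.hw_delay_b)
    fla, _ = mix_crossover(fl1_a, fl2_a, config.crossover)
    _, flb = mix_crossover(fl1_b, fl2_b, config.crossover)

    seq = rng_seed if isinstance(rng_seed, np.random.SeedSequence) else np.random.SeedSequence(rng_seed)
    seeds = seq.spawn(3)
    fs = add_noise(fs, config.snr_db, np.random.default_rng(seeds[0]))
    fla = add_noise(fla, config.snr_db, np.random.default_rng(seeds[1]))
    flb = add_noise(flb, config.snr_db, np.random.default_rng(seeds[2]))

    truth = EventTruth(
        fs_params=GaussianPulseParams(config.fs_amplitude, c, config.sigma),
        fl1_params=GaussianPulseParams(config.fl1_amplitude, c + d1, config.sigma),
        fl2_params=GaussianPulseParams(config.fl2_amplitude, c + d2, config.sigma),
        decay1=DecaySpec(config.lifetime1) if config.lifetime1 > 0 else DecaySpec(0.0),
        decay2=DecaySpec(config.lifetime2) if config.lifetime2 > 0 else DecaySpec(0.0),
        crossover=config.crossover,
        hw_delay_a=config.hw_delay_a,
        hw_delay_b=config.hw_delay_b,
        delay1=d1,
        delay2=d2,
        snr_db=config.snr_db,
        mode=config.mode,
    )
    return EventRecord(fs=fs, fl1=fl1, fl2=fl2, fla=fla, flb=flb, truth=truth)


def simulate_batch(config: SimConfig, n_events: int, seed) -> list[EventRecord]:
    """Generate ``n_events`` with independent, reproducible noise streams."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = seq.spawn(n_events)
    events = []
    for i, child in enumerate(children):
        ev = simulate_event(config, child)
        ev.event_id = i
        events.append(ev)
    return events


def simulate_led_pair(
    pulse_width: float,
    peak_v: float,
    hw_delay_ch0: float,
    hw_delay_ch1: float,
    grid: TimeGrid = DEFAULT_GRID,
) -> tuple[Waveform, Waveform]:
    """Two synchronous Gaussian LED pulses, each shifted by its channel delay.

    ``pulse_width`` is the full width at half maximum in seconds (the knob a
    function generator exposes); the Gaussian standard deviation is
    ``pulse_width / (2 sqrt(2 ln 2))``.  The true inter-channel delay is
    ``hw_delay_ch1 - hw_delay_ch0``: with equal delays the pair is exactly
    simultaneous, which is the zero-phase-shift calibration condition.
    """
    sigma = pulse_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    center = grid.start_time + 0.5 * grid.span
    w0 = gaussian_pulse(GaussianPulseParams(peak_v, center + hw_delay_ch0, sigma), grid)
    w1 = gaussian_pulse(GaussianPulseParams(peak_v, center + hw_delay_ch1, sigma), grid)
    return w0, w1
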