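"""Uniformly sampled waveforms on an explicit time grid.

Every signal handled by this package -- forward-scatter pulses, fluorescence
pulses, LED calibration pulses, modulated carriers -- is a real-valued voltage
trace sampled at a constant rate.  :class:`TimeGrid` carries the sampling
geometry and :class:`Waveform` couples it to the sample values so that delay
estimates can always be reported in seconds rather than sample counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeGrid", "Waveform"]


@dataclass(frozen=True)
class TimeGrid:
    """A uniform sampling grid: times are ``start_time + i * sample_period``.

    Parameters
    ----------
    sample_period : float
        Spacing between consecutive samples in seconds (must be positive).
    n_samples : int
        Number of samples (must be positive).
    start_time : float, optional
        Time of the first sample in seconds.  Default 0.
    """

    sample_period: float
    n_samples: int
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.sample_period > 0:
            raise ValueError(f"sample_period must be positive, got {self.sample_period}")
        if int(self.n_samples) != self.n_samples or self.n_samples <= 0:
            raise ValueError(f"n_samples must be a positive integer, got {self.n_samples}")
        object.__setattr__(self, "n_samples", int(self.n_samples))

    def times(self) -> np.ndarray:
        """Sample times in seconds, shape ``(n_samples,)``."""
        return self.start_time + self.sample_period * np.arange(self.n_samples)

    @property
    def span(self) -> float:
        """Total duration covered by the grid in seconds."""
        return self.sample_period * (self.n_samples - 1)

    @property
    def rate(self) -> float:
        """Sampling rate in samples per second."""
        return 1.0 / self.sample_period


@dataclass
class Waveform:
    """A sampled real voltage trace bound to a :class:`TimeGrid`."""

    grid: TimeGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError(f"values must be 1-D, got shape {values.shape}")
        if len(values) != self.grid.n_samples:
            raise ValueError(
                f"values length {len(values)} does not match grid.n_samples {self.grid.n_samples}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("waveform values must be finite")
        self.values = values

    def times(self) -> np.ndarray:
        return self.grid.times()

    def power(self) -> float:
        """Mean squared value over the grid."""
        return float(np.mean(self.values**2))

    def copy(self) -> "Waveform":
        return Waveform(self.grid, self.values.copy())

    def __len__(self) -> int:
        return self.grid.n_samples

    def same_grid(self, other: "Waveform") -> bool:
        return self.grid == other.grid
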