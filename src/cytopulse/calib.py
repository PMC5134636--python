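"""Hardware-delay calibration.

The delay measured between a fluorescence channel and forward scatter is the
fluorescence lifetime plus a fixed offset contributed by the detection chain
(detector, amplifier, cabling, ADC path).  The electronics are modelled as
pure group delays, so the offset is a constant per channel and can be
measured once with a pair of synchronously pulsed LEDs: any delay estimated
between the two channels under zero true inter-LED phase shift is purely the
hardware offset.  Subtracting the calibrated offset from a raw delay
estimate yields the lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ficp import DEFAULT_N2_RATIO, DelayEstimate, estimate_delay
from .waveform import Waveform
from .zoomspec import DEFAULT_N1_RATIO

__all__ = ["CalibrationRecord", "LifetimeEstimate", "estimate_hardware_delay", "calibrate"]


@dataclass
class CalibrationRecord:
    """Mean hardware delay of one fluorescence channel and its spread."""

    hardware_delay: float
    n_events: int
    sd: float

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class LifetimeEstimate:
    """A fluorescence lifetime in seconds with dispersion metadata.

    ``rsd`` is the relative standard deviation in percent (``100*sd/
    lifetime``), defined only for positive lifetimes.
    """

    lifetime: float
    sd: float = 0.0
    rsd: float = float("nan")

    @classmethod
    def with_rsd(cls, lifetime: float, sd: float) -> "LifetimeEstimate":
        rsd = 100.0 * sd / lifetime if lifetime > 0 else float("nan")
        return cls(lifetime=lifetime, sd=sd, rsd=rsd)


def estimate_hardware_delay(
    pairs: Sequence[tuple[Waveform, Waveform]],
    n1_ratio: int = DEFAULT_N1_RATIO,
    n2_ratio: int = DEFAULT_N2_RATIO,
    refine: bool = False,
) -> CalibrationRecord:
    """Mean FICP delay over LED pulse pairs recorded with zero true shift.

    Each pair is ``(reference channel, fluorescence channel)``; the per-pair
    delay estimates are averaged and their sample standard deviation (n-1
    denominator) recorded.  A single pair yields ``sd = 0``.
    """
    if len(pairs) == 0:
        raise ValueError("at least one LED pair is required for calibration")
    delays = np.empty(len(pairs))
    for i, (ref, sig) in enumerate(pairs):
        N = len(ref)
        est = estimate_delay(ref, sig, N1=n1_ratio * N, N2=n1_ratio * n2_ratio * N, refine=refine)
        delays[i] = est.delay
    sd = float(np.std(delays, ddof=1)) if len(delays) > 1 else 0.0
    return CalibrationRecord(hardware_delay=float(np.mean(delays)), n_events=len(delays), sd=sd)


def calibrate(raw_delay: DelayEstimate, cal: CalibrationRecord) -> LifetimeEstimate:
    """Remove the channel's hardware delay from a raw delay estimate.

    ``lifetime = raw_delay.delay - cal.hardware_delay``; the calibration
    spread is propagated as the estimate's ``sd``.
    """
    return LifetimeEstimate.with_rsd(raw_delay.delay - cal.hardware_delay, cal.sd)
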