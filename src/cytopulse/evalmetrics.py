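"""Error metrics, Gaussian peak fitting, and cohort summary statistics.

Spillover distorts both the peak value and the peak location of an observed
detector channel.  ``crossover_errors`` quantifies both relative to the
spillover-free expectation: for channel a the expected peak is ``k11 * P1``
(the own-fluorochrome contribution alone) and the expected delay is the
own-fluorochrome delay ``dt1``.

``gauss_fit`` is the classical baseline delay estimator: fit
``a * exp(-((t - b)/c)^2)`` to each pulse and difference the fitted centres.
Fit quality is reported as RMSE and R-squared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .pulsesim import CrossoverMatrix
from .waveform import Waveform

__all__ = [
    "ErrorReport",
    "FitResult",
    "SummaryStats",
    "crossover_errors",
    "gauss_fit",
    "gauss_fit_delay",
    "summary_stats",
]


@dataclass
class ErrorReport:
    """Peak-value and peak-location (delay) errors introduced by spillover.

    ``ep_a = (Pa - k11*P1)/Pa``, ``et_a = (dta - dt1)/dta`` and the channel-b
    analogues; all four are signed fractions.
    """

    ep_a: float
    ep_b: float
    et_a: float
    et_b: float
    peak_a: float
    peak_b: float
    peak_1: float
    peak_2: float
    delay_a: float
    delay_b: float
    delay_1: float
    delay_2: float
    expected_peak_a: float
    expected_peak_b: float


@dataclass
class FitResult:
    """Gaussian fit ``a * exp(-((t - b)/c)^2)`` with goodness-of-fit metrics.

    ``c`` relates to the standard deviation as ``sigma = c / sqrt(2)``.
    """

    a: float
    b: float
    c: float
    rmse: float
    r_squared: float

    @property
    def sigma(self) -> float:
        return self.c / np.sqrt(2.0)


@dataclass
class SummaryStats:
    """Cohort mean, sample standard deviation, and RSD in percent."""

    mean: float
    sd: float
    rsd: float


def crossover_errors(
    peak_1: float,
    peak_2: float,
    peak_a: float,
    peak_b: float,
    delay_1: float,
    delay_2: float,
    delay_a: float,
    delay_b: float,
    k: CrossoverMatrix,
) -> ErrorReport:
    """Relative peak-value and delay errors of observed channels a and b."""
    if peak_a == 0 or peak_b == 0:
        raise ValueError("observed peak values must be nonzero")
    if delay_a == 0 or delay_b == 0:
        raise ValueError("observed delays must be nonzero")
    return ErrorReport(
        ep_a=(peak_a - k.k11 * peak_1) / peak_a,
        ep_b=(peak_b - k.k22 * peak_2) / peak_b,
        et_a=(delay_a - delay_1) / delay_a,
        et_b=(delay_b - delay_2) / delay_b,
        peak_a=peak_a,
        peak_b=peak_b,
        peak_1=peak_1,
        peak_2=peak_2,
        delay_a=delay_a,
        delay_b=delay_b,
        delay_1=delay_1,
        delay_2=delay_2,
        expected_peak_a=k.k11 * peak_1,
        expected_peak_b=k.k22 * peak_2,
    )


def _gauss(t: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.exp(-(((t - b) / c) ** 2))


def gauss_fit(w: Waveform) -> FitResult:
    """Least-squares Gaussian fit to a single-peaked pulse.

    Initialisation: ``a`` from the maximum sample, ``b`` from its time,
    ``c`` from the half width at half maximum (``c = HWHM / sqrt(ln 2)``).
    RMSE is ``sqrt(mean((obs - fit)^2))``; R-squared is the regression sum
    of squares over the total sum of squares, which is 1 for a perfect fit.
    """
    t = w.times()
    y = w.values
    i_max = int(np.argmax(y))
    a0 = float(y[i_max])
    if a0 <= 0:
        raise ValueError("waveform has no positive peak to fit")
    b0 = float(t[i_max])
    above = np.flatnonzero(y >= 0.5 * a0)
    hwhm = max(0.5 * (t[above[-1]] - t[above[0]]), w.grid.sample_period)
    c0 = float(hwhm / np.sqrt(np.log(2.0)))
    try:
        popt, _ = curve_fit(
            _gauss,
            t,
            y,
            p0=(a0, b0, c0),
            bounds=([0.0, t[0] - w.grid.span, 0.0], [np.inf, t[-1] + w.grid.span, np.inf]),
            xtol=1e-12,
            ftol=1e-12,
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise RuntimeError(
            f"Gaussian fit failed to converge (init a={a0:.3g}, b={b0:.3g}, c={c0:.3g}): {exc}"
        ) from exc
    fit = _gauss(t, *popt)
    rmse = float(np.sqrt(np.mean((y - fit) ** 2)))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    ssr = float(np.sum((fit - np.mean(y)) ** 2))
    r_squared = ssr / sst if sst > 0 else float("nan")
    return FitResult(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]), rmse=rmse, r_squared=r_squared)


def gauss_fit_delay(ref: Waveform, sig: Waveform) -> float:
    """Delay of ``sig`` relative to ``ref`` via fitted peak-centre difference."""
    return gauss_fit(sig).b - gauss_fit(ref).b


def summary_stats(values) -> SummaryStats:
    """Mean, sample SD (n-1 denominator) and RSD (%) of a cohort of values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("summary statistics require at least two values")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    rsd = 100.0 * sd / mean if mean > 0 else float("nan")
    return SummaryStats(mean=mean, sd=sd, rsd=rsd)
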