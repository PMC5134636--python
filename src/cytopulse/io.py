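"""Event-table and configuration I/O.

Raw per-event pulse waveforms are exchanged as a long-format CSV with columns
``event_id, channel, sample_index, time_s, value_v`` (channels ``fs``,
``fl1``, ``fl2``, ``fla``, ``flb``); simulated ground truth travels in a
per-event sidecar CSV keyed by ``event_id``.  Run configuration is YAML.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .pulsesim import (
    CrossoverMatrix,
    EventRecord,
    EventTruth,
    GaussianPulseParams,
    DecaySpec,
    SimConfig,
)
from .waveform import TimeGrid, Waveform

__all__ = [
    "EVENT_CHANNELS",
    "read_events",
    "write_events",
    "read_truth",
    "RunConfig",
    "load_config",
]

logger = logging.getLogger("cytopulse")

EVENT_CHANNELS = ("fs", "fl1", "fl2", "fla", "flb")

_TABLE_COLUMNS = ["event_id", "channel", "sample_index", "time_s", "value_v"]


def _waveform_rows(event_id: int, channel: str, w: Waveform) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": event_id,
            "channel": channel,
            "sample_index": np.arange(len(w)),
            "time_s": w.times(),
            "value_v": w.values,
        }
    )


def write_events(
    events: Sequence[EventRecord], path, truth_path=None, channels: Sequence[str] = EVENT_CHANNELS
) -> None:
    """Write events to a long-format CSV at full precision.

    ``channels`` restricts which waveforms are written (LED calibration pairs
    only carry a reference and one fluorescence channel, for example).  If
    ``truth_path`` is given, a ground-truth sidecar CSV is written for the
    events that carry truth.
    """
    frames = []
    for ev in events:
        for ch in channels:
            frames.append(_waveform_rows(ev.event_id, ch, getattr(ev, ch)))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_TABLE_COLUMNS)
    table.to_csv(path, index=False)
    if truth_path is not None:
        rows = []
        for ev in events:
            t = ev.truth
            if t is None:
                continue
            rows.append(
                {
                    "event_id": ev.event_id,
                    "fs_amplitude": t.fs_params.amplitude,
                    "fl1_amplitude": t.fl1_params.amplitude,
                    "fl2_amplitude": t.fl2_params.amplitude,
                    "sigma": t.fs_params.sigma,
                    "t0": t.fs_params.center,
                    "delay1": t.delay1,
                    "delay2": t.delay2,
                    "lifetime1": t.decay1.lifetime,
                    "lifetime2": t.decay2.lifetime,
                    "k11": t.crossover.k11,
                    "k12": t.crossover.k12,
                    "k21": t.crossover.k21,
                    "k22": t.crossover.k22,
                    "hw_delay_a": t.hw_delay_a,
                    "hw_delay_b": t.hw_delay_b,
                    "snr_db": t.snr_db if t.snr_db is not None else np.inf,
                    "mode": t.mode,
                }
            )
        pd.DataFrame(rows).to_csv(truth_path, index=False)


def read_truth(path) -> dict[int, EventTruth]:
    """Read a ground-truth sidecar CSV into per-event truth records."""
    df = pd.read_csv(path, float_precision="round_trip")
    truths: dict[int, EventTruth] = {}
    for _, row in df.iterrows():
        snr = float(row["snr_db"])
        truths[int(row["event_id"])] = EventTruth(
            fs_params=GaussianPulseParams(row["fs_amplitude"], row["t0"], row["sigma"]),
            fl1_params=GaussianPulseParams(
                row["fl1_amplitude"], row["t0"] + row["delay1"], row["sigma"]
            ),
            fl2_params=GaussianPulseParams(
                row["fl2_amplitude"], row["t0"] + row["delay2"], row["sigma"]
            ),
            decay1=DecaySpec(row["lifetime1"]),
            decay2=DecaySpec(row["lifetime2"]),
            crossover=CrossoverMatrix(row["k11"], row["k12"], row["k21"], row["k22"]),
            hw_delay_a=row["hw_delay_a"],
            hw_delay_b=row["hw_delay_b"],
            delay1=row["delay1"],
            delay2=row["delay2"],
            snr_db=None if np.isinf(snr) else snr,
            mode=str(row["mode"]),
        )
    return truths


def _grid_from_times(times: np.ndarray, event_id, channel: str) -> TimeGrid:
    if len(times) < 2:
        raise ValueError(f"event {event_id} channel {channel}: fewer than two samples")
    periods = np.diff(times)
    if not np.allclose(periods, periods[0], rtol=1e-9, atol=0.0):
        raise ValueError(f"event {event_id} channel {channel}: non-uniform time grid")
    return TimeGrid(sample_period=float(periods[0]), n_samples=len(times), start_time=float(times[0]))


def read_channel_table(path) -> list[tuple[int, dict[str, Waveform]]]:
    """Read a long-format waveform CSV into per-event channel dictionaries.

    Validates the schema (columns, known channel labels, contiguous sample
    indices) and reports offending row numbers.  An empty file yields an
    empty list with a warning.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty event table", stacklevel=2)
        logger.warning("%s: empty event table", path)
        return []
    if df.empty:
        warnings.warn(f"{path}: empty event table", stacklevel=2)
        logger.warning("%s: empty event table", path)
        return []
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = ~df["channel"].isin(EVENT_CHANNELS)
    if bad.any():
        row = int(df.index[bad][0]) + 2  # header + 1-based
        raise ValueError(
            f"{path}: unknown channel {df.loc[df.index[bad][0], 'channel']!r} at row {row}"
        )
    out: list[tuple[int, dict[str, Waveform]]] = []
    for event_id, ev_df in df.groupby("event_id", sort=True):
        chans: dict[str, Waveform] = {}
        for channel, ch_df in ev_df.groupby("channel", sort=False):
            ch_df = ch_df.sort_values("sample_index")
            idx = ch_df["sample_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise ValueError(
                    f"{path}: event {event_id} channel {channel}: sample_index not contiguous from 0"
                )
            grid = _grid_from_times(ch_df["time_s"].to_numpy(), event_id, channel)
            chans[str(channel)] = Waveform(grid, ch_df["value_v"].to_numpy())
        out.append((int(event_id), chans))
    return out


def read_events(path, truth_path=None) -> list[EventRecord]:
    """Read a five-channel event table (and optional truth sidecar).

    Round-trips :func:`write_events` losslessly at full float precision.
    """
    truths = read_truth(truth_path) if truth_path is not None else {}
    events = []
    for event_id, chans in read_channel_table(path):
        missing = [c for c in EVENT_CHANNELS if c not in chans]
        if missing:
            raise ValueError(f"{path}: event {event_id} is missing channels {missing}")
        events.append(
            EventRecord(
                fs=chans["fs"],
                fl1=chans["fl1"],
                fl2=chans["fl2"],
                fla=chans["fla"],
                flb=chans["flb"],
                truth=truths.get(event_id),
                event_id=event_id,
            )
        )
    return events


@dataclass
class RunConfig:
    """Validated run configuration: simulation conditions plus estimator knobs."""

    sim: SimConfig = field(default_factory=SimConfig)
    n_events: int = 100
    n1_ratio: int = 10
    n2_ratio: int = 10
    refine: bool = False
    frequency_mhz: float = 10.0
    convention: str = "si"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.n1_ratio < 1 or self.n2_ratio < 2:
            raise ValueError("n1_ratio must be >= 1 and n2_ratio >= 2")
        if self.convention not in ("si", "mhz-ns"):
            raise ValueError(f"unknown convention {self.convention!r}")


_TOP_KEYS = {
    "grid",
    "pulses",
    "lifetimes_ns",
    "crossover",
    "hardware_delays_ns",
    "snr_db",
    "mode",
    "seed",
    "n_events",
    "zoom",
    "modulation",
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level of the config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")

    grid_spec = raw.get("grid", {})
    grid = TimeGrid(
        sample_period=float(grid_spec.get("sample_period", 1e-7)),
        n_samples=int(grid_spec.get("n_samples", 2048)),
        start_time=float(grid_spec.get("start_time", 0.0)),
    )
    pulses = raw.get("pulses", {})
    lifetimes = raw.get("lifetimes_ns", [0.0, 0.0])
    crossover = raw.get("crossover", {})
    hw = raw.get("hardware_delays_ns", {})
    sim = SimConfig(
        grid=grid,
        fs_amplitude=float(pulses.get("fs_amplitude", 2.0)),
        fl1_amplitude=float(pulses.get("fl1_amplitude", 1.40)),
        fl2_amplitude=float(pulses.get("fl2_amplitude", 1.20)),
        sigma=float(pulses.get("sigma", 0.5e-6)),
        t0=pulses.get("t0"),
        delay1=float(pulses.get("delay1", 0.33e-6)),
        delay2=float(pulses.get("delay2", 0.35e-6)),
        lifetime1=float(lifetimes[0]) * 1e-9,
        lifetime2=float(lifetimes[1]) * 1e-9,
        crossover=CrossoverMatrix(
            k11=float(crossover.get("k11", 1.0)),
            k12=float(crossover.get("k12", 0.0)),
            k21=float(crossover.get("k21", 0.0)),
            k22=float(crossover.get("k22", 1.0)),
        ),
        hw_delay_a=float(hw.get("a", 0.0)) * 1e-9,
        hw_delay_b=float(hw.get("b", 0.0)) * 1e-9,
        snr_db=(None if raw["snr_db"] is None else float(raw["snr_db"])) if "snr_db" in raw else 40.0,
        mode=str(raw.get("mode", "shift")),
    )
    zoom = raw.get("zoom", {})
    modulation = raw.get("modulation", {})
    return RunConfig(
        sim=sim,
        n_events=int(raw.get("n_events", 100)),
        n1_ratio=int(zoom.get("n1_ratio", 10)),
        n2_ratio=int(zoom.get("n2_ratio", 10)),
        refine=bool(zoom.get("refine", False)),
        frequency_mhz=float(modulation.get("frequency_mhz", 10.0)),
        convention=str(modulation.get("convention", "si")),
        seed=raw.get("seed"),
    )
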