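"""Ventilator waveform handling.

Recordings are uniformly sampled airway pressure (cmH2O) and flow (L/s)
time series, typically 50 Hz, taken during a recruitment manoeuvre in which
PEEP is raised in 2 cmH2O steps every ~10 breaths.  This module covers the
plumbing every downstream step relies on:

* volume by trapezoidal integration of flow, with per-breath drift
  compensation so end-expiratory volume is exactly zero;
* breath segmentation from flow zero-crossings with hysteresis;
* grouping breaths into PEEP steps and extracting each step's peak
  inspiratory pressure (PIP);
* a plain CSV dialect for round-tripping records.

Indexing is 0-based with half-open ``[start, end)`` intervals throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import InvalidInputError

#: hysteresis threshold for flow-crossing breath detection (L/s)
FLOW_THRESHOLD = 0.02

#: breaths join a PEEP step while their baseline is within this of the
#: step median (cmH2O); half the protocol's 2 cmH2O step size
PEEP_GROUP_TOL = 1.0

#: fraction of each breath (taken from its tail) used to estimate the
#: end-expiratory baseline pressure
_BASELINE_TAIL_FRAC = 0.1

CSV_COLUMNS = ("time_s", "pressure_cmH2O", "flow_Lps")
CSV_VOLUME_COLUMN = "volume_L"


@dataclass
class WaveformRecord:
    """A uniformly sampled pressure/flow(/volume) recording.

    Attributes
    ----------
    time : ndarray
        Seconds, uniform grid.
    pressure : ndarray
        Airway pressure, cmH2O.
    flow : ndarray
        Airway flow, L/s (positive = inspiration).
    volume : ndarray or None
        Litres above end-expiratory volume; absent until integrated.
    sample_rate : float
        Hz.
    """

    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    volume: np.ndarray | None = None
    sample_rate: float = 50.0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        n = self.time.size
        if n < 2:
            raise InvalidInputError("waveform record needs at least 2 samples")
        if self.pressure.size != n or self.flow.size != n:
            raise InvalidInputError("pressure/flow/time lengths differ")
        if not self.sample_rate > 0:
            raise InvalidInputError("sample_rate must be positive")
        dt = np.diff(self.time)
        if dt.size and (np.max(dt) - np.min(dt)) > 1e-9:
            raise InvalidInputError("time grid is not uniform (tolerance 1e-9 s)")
        if np.any(dt <= 0):
            raise InvalidInputError("time must be strictly increasing")
        if self.volume is not None:
            self.volume = np.asarray(self.volume, dtype=float)
            if self.volume.size != n:
                raise InvalidInputError("volume length differs from time")
            if not np.all(np.isfinite(self.volume)):
                raise InvalidInputError("volume contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def slice(self, start: int, stop: int) -> "WaveformRecord":
        """Sub-record over sample range ``[start, stop)``."""
        return WaveformRecord(
            time=self.time[start:stop],
            pressure=self.pressure[start:stop],
            flow=self.flow[start:stop],
            volume=None if self.volume is None else self.volume[start:stop],
            sample_rate=self.sample_rate,
        )


@dataclass(frozen=True)
class BreathSegment:
    """One breath: ``[start_index, end_index)`` with inspiration ending at
    ``insp_end_index`` (first expiratory flow crossing)."""

    start_index: int
    insp_end_index: int
    end_index: int
    peak_pressure: float
    baseline_pressure: float

    def __post_init__(self):
        if not (self.start_index < self.insp_end_index <= self.end_index):
            raise InvalidInputError(
                "breath indices must satisfy start < insp_end <= end"
            )


@dataclass
class PeepStep:
    """Consecutive breaths sharing one end-expiratory pressure level."""

    peep: float
    breaths: list[BreathSegment]
    step_pip: float

    @property
    def start_index(self) -> int:
        return self.breaths[0].start_index

    @property
    def end_index(self) -> int:
        return self.breaths[-1].end_index

    def summary(self) -> dict:
        return {
            "peep": float(self.peep),
            "n_breaths": len(self.breaths),
            "step_pip": float(self.step_pip),
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary())


def _baseline_pressure(pressure: np.ndarray, start: int, end: int) -> float:
    """End-expiratory pressure estimate: median over the breath's tail."""
    tail = max(3, int(round(_BASELINE_TAIL_FRAC * (end - start))))
    return float(np.median(pressure[max(start, end - tail):end]))


def segment_breaths(
    record: WaveformRecord, threshold: float = FLOW_THRESHOLD
) -> list[BreathSegment]:
    """Split a record into breaths from flow crossings with hysteresis.

    A breath starts at an upward crossing of ``+threshold`` (inspiration
    onset); an onset is only accepted once flow has dipped below
    ``-threshold`` since the previous onset, which rejects noise-induced
    double triggers.  Inspiration ends at the first crossing below
    ``-threshold``.  A trailing breath is kept when its expiration began
    before the record ended; otherwise it is discarded, as is any leading
    span before the first onset.  Returns an empty list when no breath is
    found.
    """
    flow = record.flow
    n = flow.size
    above = flow > threshold
    below = flow < -threshold
    # raw upward crossings of +threshold (sample 0 counts when already above)
    up = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    down = np.flatnonzero(below & ~np.concatenate(([False], below[:-1])))
    if up.size == 0 or down.size == 0:
        return []

    # hysteresis: keep an onset only if an expiratory crossing occurred
    # since the previously accepted onset
    onsets: list[int] = []
    for o in up:
        if not onsets:
            onsets.append(int(o))
            continue
        if np.any((down > onsets[-1]) & (down < o)):
            onsets.append(int(o))

    breaths: list[BreathSegment] = []
    for k, start in enumerate(onsets):
        end = onsets[k + 1] if k + 1 < len(onsets) else n
        d = down[(down > start) & (down < end)]
        if d.size == 0:
            continue  # inspiration never ended: incomplete trailing breath
        breaths.append(
            BreathSegment(
                start_index=start,
                insp_end_index=int(d[0]),
                end_index=int(end),
                peak_pressure=float(np.max(record.pressure[start:end])),
                baseline_pressure=_baseline_pressure(record.pressure, start, end),
            )
        )
    return breaths


def integrate_volume(
    record: WaveformRecord, breaths: list[BreathSegment]
) -> WaveformRecord:
    """Cumulative trapezoidal volume with per-breath drift compensation.

    Flow-sensor offset makes the raw integral drift; clinically volume is
    re-zeroed at PEEP.  Here a linear ramp is subtracted within each breath
    so that volume is exactly 0 at the breath's first and last sample.
    Samples not covered by any breath get volume 0.
    """
    if breaths:
        order = sorted(breaths, key=lambda b: b.start_index)
        for a, b in zip(order, order[1:]):
            if b.start_index < a.end_index:
                raise InvalidInputError("breath segments overlap")
    raw = cumulative_trapezoid(record.flow, dx=record.dt, initial=0.0)
    vol = np.zeros_like(raw)
    for b in breaths:
        s, e = b.start_index, b.end_index
        seg = raw[s:e] - raw[s]
        drift = seg[-1]
        ramp = np.linspace(0.0, drift, e - s)
        vol[s:e] = seg - ramp
    return WaveformRecord(
        time=record.time,
        pressure=record.pressure,
        flow=record.flow,
        volume=vol,
        sample_rate=record.sample_rate,
    )


def detect_peep_steps(
    record: WaveformRecord,
    breaths: list[BreathSegment],
    tolerance: float = PEEP_GROUP_TOL,
) -> list[PeepStep]:
    """Group consecutive breaths into PEEP steps by baseline pressure.

    A breath joins the current step while its baseline is within
    ``tolerance`` of the step's running median baseline; otherwise a new
    step begins.  Each step's ``peep`` is the median of its breath
    baselines and ``step_pip`` the median of its per-breath pressure
    maxima (robust to the transient breaths right after a PEEP change).
    """
    if not breaths:
        raise InvalidInputError("detect_peep_steps requires at least one breath")
    groups: list[list[BreathSegment]] = [[breaths[0]]]
    for b in breaths[1:]:
        current = groups[-1]
        med = float(np.median([x.baseline_pressure for x in current]))
        if abs(b.baseline_pressure - med) <= tolerance:
            current.append(b)
        else:
            groups.append([b])
    steps = []
    for g in groups:
        peep = float(np.median([b.baseline_pressure for b in g]))
        pip = float(np.median([b.peak_pressure for b in g]))
        steps.append(PeepStep(peep=peep, breaths=g, step_pip=pip))
    return steps


def extract_pip(step: PeepStep, record: WaveformRecord) -> float:
    """Measured PIP of a PEEP step: median of per-breath pressure maxima."""
    if not step.breaths:
        raise InvalidInputError("PEEP step has no breaths")
    peaks = [
        float(np.max(record.pressure[b.start_index:b.end_index]))
        for b in step.breaths
    ]
    return float(np.median(peaks))


def read_waveform_csv(path) -> WaveformRecord:
    """Read a record from CSV with columns time_s, pressure_cmH2O, flow_Lps
    (volume_L optional)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file / not CSV
        raise InvalidInputError(f"cannot parse CSV {path}: {exc}") from exc
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise InvalidInputError(f"{path}: missing required column '{col}'")
    use = list(CSV_COLUMNS) + (
        [CSV_VOLUME_COLUMN] if CSV_VOLUME_COLUMN in df.columns else []
    )
    for col in use:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise InvalidInputError(
                f"{path}: column '{col}' has missing or non-numeric cells"
            )
        df[col] = vals
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError(f"{path}: time_s is not strictly increasing")
    dts = np.diff(t)
    sample_rate = 1.0 / float(np.mean(dts))
    return WaveformRecord(
        time=t,
        pressure=df["pressure_cmH2O"].to_numpy(float),
        flow=df["flow_Lps"].to_numpy(float),
        volume=(
            df[CSV_VOLUME_COLUMN].to_numpy(float)
            if CSV_VOLUME_COLUMN in df.columns
            else None
        ),
        sample_rate=sample_rate,
    )


def write_waveform_csv(record: WaveformRecord, path) -> None:
    """Write a record to the CSV dialect read by :func:`read_waveform_csv`."""
    data = {
        "time_s": record.time,
        "pressure_cmH2O": record.pressure,
        "flow_Lps": record.flow,
    }
    if record.volume is not None:
        data[CSV_VOLUME_COLUMN] = record.volume
    pd.DataFrame(data).to_csv(path, index=False)
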