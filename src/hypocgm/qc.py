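"""Per-24-hour CGM data-quality control.

A recording is split into consecutive 24-h windows anchored at the
session start (sessions begin mid-day, so windows are not calendar
aligned; a trailing partial window is discarded, never evaluated).  A
window is retained only if ALL of the following hold:

* at least three paired SMBG calibrations fall inside it,
* no missing sensor samples,
* Pearson r between paired SMBG and sensor readings > 0.77 (strict;
  undefined r counts as failure),
* MAD% < 28 (strict), where MAD% averages |SMBG - sensor| / SMBG x 100
  over the window's pairs (SMBG is the reference, MARD-style).

A subject with less than 24 h of retained data is excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd

from .errors import InputError
from .types import GlucoseTrace, QCWindow, SMBGReading

logger = logging.getLogger(__name__)

#: SMBG-to-sensor pairing tolerance (minutes).
PAIRING_TOLERANCE_MIN = 5.0

MIN_CALIBRATIONS = 3
CORRELATION_THRESHOLD = 0.77  # pass requires r strictly greater
MAD_PCT_THRESHOLD = 28.0  # pass requires MAD% strictly smaller


@dataclass
class PairedReading:
    smbg: SMBGReading
    sensor_value: float
    sample_index: int


@dataclass
class QCReport:
    """Full QC outcome for one subject."""

    subject_id: str
    windows: list[QCWindow]
    segments: list[GlucoseTrace]  # retained data, contiguous runs of windows
    retained_hours: float
    excluded: bool

    @property
    def retained_days(self) -> float:
        return self.retained_hours / 24.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.windows:
            rows.append(
                {
                    "subject_id": w.subject_id,
                    "window_index": w.window_index,
                    "window_start": w.window_start,
                    "n_calibrations": w.n_calibrations,
                    "completeness": w.completeness,
                    "pearson_r": w.pearson_r,
                    "mad_pct": w.mad_pct,
                    "pass_calibrations": w.pass_calibrations,
                    "pass_completeness": w.pass_completeness,
                    "pass_correlation": w.pass_correlation,
                    "pass_mad": w.pass_mad,
                    "passed": w.passed,
                }
            )
        return pd.DataFrame(rows)


def pair_smbg_to_sensor(
    trace: GlucoseTrace, readings: list[SMBGReading]
) -> list[PairedReading]:
    """Pair each SMBG with the nearest-in-time sensor sample within +/-5 min.

    Equidistant readings pair to the earlier sample.  Readings outside the
    tolerance, beyond the trace, or co-timed with a missing sample are
    dropped with a logged warning.
    """
    pairs: list[PairedReading] = []
    n = trace.n_samples
    dt = trace.interval_min
    dropped = 0
    for r in readings:
        if r.subject_id != trace.subject_id:
            raise InputError(
                f"SMBG subject {r.subject_id!r} does not match trace subject "
                f"{trace.subject_id!r}"
            )
        off_min = (r.time - trace.start).total_seconds() / 60.0
        pos = off_min / dt
        idx = int(np.floor(pos + 0.5))
        if pos - np.floor(pos) == 0.5:  # exact midpoint: earlier sample wins
            idx = int(np.floor(pos))
        if idx < 0 or idx >= n or abs(off_min - idx * dt) > PAIRING_TOLERANCE_MIN:
            dropped += 1
            continue
        sensor = trace.values[idx]
        if not np.isfinite(sensor):
            dropped += 1
            continue
        pairs.append(PairedReading(r, float(sensor), idx))
    if dropped:
        logger.warning(
            "%s: dropped %d SMBG reading(s) with no sensor sample within "
            "%.0f min",
            trace.subject_id,
            dropped,
            PAIRING_TOLERANCE_MIN,
        )
    return pairs


def evaluate_window(
    trace: GlucoseTrace,
    pairs: list[PairedReading],
    window_index: int,
    samples_per_window: int,
    min_calibrations: int = MIN_CALIBRATIONS,
    r_threshold: float = CORRELATION_THRESHOLD,
    mad_threshold: float = MAD_PCT_THRESHOLD,
) -> QCWindow:
    """Evaluate the QC criteria on one 24-h window of the trace grid."""
    a = window_index * samples_per_window
    b = a + samples_per_window
    if b > trace.n_samples:
        raise InputError("window extends beyond the trace")
    vals = trace.values[a:b]
    if vals.size == 0:
        raise InputError("empty QC window")
    in_win = [p for p in pairs if a <= p.sample_index < b]

    n_cal = len(in_win)
    completeness = float(np.mean(np.isfinite(vals)))
    pass_complete = completeness == 1.0

    r: float | None = None
    if n_cal >= 2:
        s = np.array([p.smbg.glucose_mmol_l for p in in_win])
        g = np.array([p.sensor_value for p in in_win])
        if np.std(s) > 0 and np.std(g) > 0:
            r = float(np.corrcoef(s, g)[0, 1])
    pass_r = r is not None and r > r_threshold

    mad: float | None = None
    if n_cal >= 1:
        s = np.array([p.smbg.glucose_mmol_l for p in in_win])
        g = np.array([p.sensor_value for p in in_win])
        mad = float(np.mean(np.abs(s - g) / s) * 100.0)
    pass_mad = mad is not None and mad < mad_threshold

    return QCWindow(
        subject_id=trace.subject_id,
        window_index=window_index,
        window_start=trace.start + timedelta(hours=24.0 * window_index),
        n_calibrations=n_cal,
        completeness=completeness,
        pearson_r=r,
        mad_pct=mad,
        pass_calibrations=n_cal >= min_calibrations,
        pass_completeness=pass_complete,
        pass_correlation=pass_r,
        pass_mad=pass_mad,
    )


def apply_qc(
    trace: GlucoseTrace,
    readings: list[SMBGReading],
    min_calibrations: int = MIN_CALIBRATIONS,
    r_threshold: float = CORRELATION_THRESHOLD,
    mad_threshold: float = MAD_PCT_THRESHOLD,
) -> QCReport:
    """Partition the trace into 24-h windows, excise failures, and merge
    consecutive retained windows into contiguous segments."""
    samples_per_window = int(round(24 * 60 / trace.interval_min))
    n_windows = trace.n_samples // samples_per_window
    pairs = pair_smbg_to_sensor(trace, readings)

    windows = [
        evaluate_window(
            trace, pairs, i, samples_per_window,
            min_calibrations, r_threshold, mad_threshold,
        )
        for i in range(n_windows)
    ]

    segments: list[GlucoseTrace] = []
    run_start: int | None = None
    for i in range(n_windows + 1):
        passed = i < n_windows and windows[i].passed
        if passed and run_start is None:
            run_start = i
        elif not passed and run_start is not None:
            a = run_start * samples_per_window
            b = i * samples_per_window
            segments.append(
                GlucoseTrace(
                    trace.subject_id,
                    trace.start + timedelta(hours=24.0 * run_start),
                    trace.interval_min,
                    trace.values[a:b].copy(),
                )
            )
            run_start = None

    retained_hours = sum(s.duration_hours for s in segments)
    return QCReport(
        subject_id=trace.subject_id,
        windows=windows,
        segments=segments,
        retained_hours=retained_hours,
        excluded=retained_hours < 24.0,
    )
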