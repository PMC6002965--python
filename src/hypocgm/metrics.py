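"""Glycaemic-variability metrics: mean, SD, MAGE and LBGI.

Metrics are computed on the pooled QC-retained samples per subject (the
full series, not per-window averages), matching how the standard
EasyGV-style definitions operate.

MAGE follows Service's original rule: collapse monotone runs to turning
points, keep excursions whose peak-to-nadir amplitude exceeds 1 SD of
the whole series, and average the qualifying amplitudes measured in the
direction of the first qualifying excursion.

LBGI uses Kovatchev's log-power symmetrisation: with g in mg/dl,
f(g) = 1.509 ((ln g)^1.084 - 5.381); the low-side risk is 10 f^2 for
f < 0 (else 0) and LBGI is its mean over all samples.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .errors import InputError, InsufficientDataError
from .types import MMOL_TO_MGDL, GlucoseTrace, MetricSet


def _pool(segments: Sequence[GlucoseTrace] | GlucoseTrace) -> np.ndarray:
    if isinstance(segments, GlucoseTrace):
        segments = [segments]
    if not segments:
        return np.array([])
    vals = np.concatenate([np.asarray(s.values, dtype=float) for s in segments])
    return vals[np.isfinite(vals)]


def basic_stats(segments) -> tuple[float, float]:
    """Arithmetic mean and SD (n-1 denominator) of the pooled samples."""
    vals = _pool(segments)
    if vals.size < 2:
        raise InsufficientDataError("mean/SD need at least 2 samples")
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def _turning_points(values: np.ndarray) -> list[int]:
    """Indices of local extrema after collapsing monotone runs and
    plateaus; series endpoints are included."""
    # drop consecutive duplicates, remembering original indices
    idx = [0]
    for i in range(1, values.size):
        if values[i] != values[idx[-1]]:
            idx.append(i)
    if len(idx) == 1:
        return []
    tps = [idx[0]]
    for j in range(1, len(idx) - 1):
        prev, cur, nxt = values[idx[j - 1]], values[idx[j]], values[idx[j + 1]]
        if (cur - prev) * (nxt - cur) < 0:
            tps.append(idx[j])
    tps.append(idx[-1])
    return tps


def mage(segments, sd: Optional[float] = None) -> Optional[float]:
    """Mean amplitude of glycaemic excursions, or None if no excursion
    exceeds one SD of the series."""
    vals = _pool(segments)
    if vals.size < 2:
        raise InsufficientDataError("MAGE needs at least 2 samples")
    if sd is None:
        sd = float(np.std(vals, ddof=1))
    tps = _turning_points(vals)
    if len(tps) < 2:
        return None

    amplitudes = []  # signed swing between consecutive turning points
    for a, b in zip(tps[:-1], tps[1:]):
        amplitudes.append(vals[b] - vals[a])
    qualifying = [amp for amp in amplitudes if abs(amp) > sd]
    if not qualifying:
        return None
    direction = np.sign(qualifying[0])
    chosen = [abs(amp) for amp in qualifying if np.sign(amp) == direction]
    return float(np.mean(chosen))


def lbgi(segments) -> float:
    """Low blood glucose index over the pooled samples."""
    vals = _pool(segments)
    if vals.size < 1:
        raise InsufficientDataError("LBGI needs at least 1 sample")
    if np.any(vals <= 0):
        raise InputError("LBGI requires positive glucose values")
    mgdl = vals * MMOL_TO_MGDL
    f = 1.509 * (np.log(mgdl) ** 1.084 - 5.381)
    risk = np.where(f < 0, 10.0 * f * f, 0.0)
    return float(np.mean(risk))


def compute_metrics(subject_id: str, segments) -> MetricSet:
    """All four per-subject metrics on the QC-retained segments."""
    mean, sd = basic_stats(segments)
    vals = _pool(segments)
    if isinstance(segments, GlucoseTrace):
        interval = segments.interval_min
    else:
        interval = segments[0].interval_min
    return MetricSet(
        subject_id=subject_id,
        mean_glucose=mean,
        sd_glucose=sd,
        mage=mage(segments, sd=sd),
        lbgi=lbgi(segments),
        hours_of_data=vals.size * interval / 60.0,
    )
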