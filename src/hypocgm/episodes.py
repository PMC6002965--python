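"""Threshold/duration-based hypoglycaemia episode detection.

An episode at threshold L (4.0, 3.0 or 2.2 mmol/l) is >= 20 min of
glucose at or below L, and is only complete once readings have been
above L for more than 20 min: maximal runs of consecutive samples <= L
separated by an above-threshold gap of <= 20 min belong to the same
episode.  Each sample represents one sampling interval, so an episode's
duration is (number of at/below samples) x interval; merged-gap time is
excluded (the reported quantity is time at/below threshold).  Episodes
never span QC-excised windows because detection runs per retained
segment.

Episodes are assigned wholly to day (08:00-00:00) or night (00:00-08:00)
by the clock time of their first at/below sample.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import InputError
from .types import (
    Episode,
    GlucoseTrace,
    HypoSummary,
    ThresholdSummary,
    period_of,
)

#: Standard analysis thresholds, mmol/l.
THRESHOLDS = (4.0, 3.0, 2.2)

#: Minimum qualifying time at/below threshold, minutes.
MIN_EPISODE_MIN = 20.0

#: An episode completes only after strictly more than this above threshold.
COMPLETION_GAP_MIN = 20.0

HOURS_PER_WEEK = 168.0


def _detect_in_segment(seg: GlucoseTrace, threshold: float) -> list[Episode]:
    vals = np.asarray(seg.values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise InputError("episode detection requires gap-free segments")
    dt = seg.interval_min
    below = vals <= threshold
    if not below.any():
        return []

    # maximal runs of consecutive at/below samples
    padded = np.diff(np.concatenate(([0], below.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)  # exclusive

    # merge runs whose separating above-threshold gap is <= 20 min
    merged: list[list[int]] = []  # [first_start, last_end, below_samples]
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1]) * dt <= COMPLETION_GAP_MIN:
            merged[-1][1] = int(e)
            merged[-1][2] += int(e - s)
        else:
            merged.append([int(s), int(e), int(e - s)])

    times = seg.times()
    episodes = []
    for s, e, n_below in merged:
        duration = n_below * dt
        if duration < MIN_EPISODE_MIN:
            continue
        start_t = times[s].to_pydatetime()
        end_t = (times[e - 1] + times.freq).to_pydatetime()
        episodes.append(
            Episode(
                subject_id=seg.subject_id,
                threshold=threshold,
                start=start_t,
                end=end_t,
                duration_min=float(duration),
                nadir=float(vals[s:e].min()),
                period=period_of(start_t),
            )
        )
    return episodes


def detect_episodes(segments, threshold: float) -> list[Episode]:
    """Detect all qualifying episodes at one threshold across retained
    segments (each segment is processed independently)."""
    if threshold <= 0:
        raise InputError("threshold must be positive")
    if isinstance(segments, GlucoseTrace):
        segments = [segments]
    episodes: list[Episode] = []
    for seg in segments:
        episodes.extend(_detect_in_segment(seg, threshold))
    episodes.sort(key=lambda ep: ep.start)
    return episodes


def day_night_split(episodes: Sequence[Episode]) -> dict[str, int]:
    """Counts of episodes by the period containing their start time."""
    out = {"day": 0, "night": 0}
    for ep in episodes:
        out[ep.period] += 1
    return out


def summarize(
    subject_id: str,
    episodes_by_threshold: dict[float, Sequence[Episode]],
    exposure_hours: float,
) -> HypoSummary:
    """Exposure-normalised rates and durations per person per week."""
    if exposure_hours <= 0:
        raise InputError("exposure must be positive")
    scale = HOURS_PER_WEEK / exposure_hours
    summary = HypoSummary(
        subject_id=subject_id, exposure_weeks=exposure_hours / HOURS_PER_WEEK
    )
    for thr, eps in episodes_by_threshold.items():
        counts = day_night_split(eps)
        total_min = float(sum(ep.duration_min for ep in eps))
        summary.by_threshold[thr] = ThresholdSummary(
            threshold=thr,
            n_episodes=len(eps),
            rate_per_week=len(eps) * scale,
            duration_min_per_week=total_min * scale,
            day_count=counts["day"],
            night_count=counts["night"],
            day_rate_per_week=counts["day"] * scale,
            night_rate_per_week=counts["night"] * scale,
        )
    return summary


def analyze_subject(segments, exposure_hours: float | None = None) -> HypoSummary:
    """Detect at all standard thresholds and summarise one subject."""
    if isinstance(segments, GlucoseTrace):
        segments = [segments]
    if not segments:
        raise InputError("no retained segments")
    if exposure_hours is None:
        exposure_hours = sum(s.duration_hours for s in segments)
    by_thr = {thr: detect_episodes(segments, thr) for thr in THRESHOLDS}
    return summarize(segments[0].subject_id, by_thr, exposure_hours)
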