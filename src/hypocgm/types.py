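"""Core domain containers.

Glucose is carried in mmol/l throughout; timestamps are naive local
datetimes (recording sessions last a few days, so no DST handling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

#: mmol/l -> mg/dl conversion used everywhere glucose units change.
MMOL_TO_MGDL = 18.016

#: Clock window boundaries: day is 08:00-00:00, night is 00:00-08:00.
NIGHT_END_HOUR = 8.0

#: Sensor reporting range analogue (20-600 mg/dl) used for clamping.
GLUCOSE_CLAMP_MMOL = (1.1, 33.3)


@dataclass
class SubjectRecord:
    """One study participant with the covariates used by the adjusted models."""

    subject_id: str
    group: str
    cpeptide_pmol_l: float
    age_years: float
    sex: str  # "M" / "F"
    hba1c_mmol_mol: float
    prandial_insulin: bool
    insulin_dose_u_kg: float
    diabetes_type: str = "type2"

    def __post_init__(self) -> None:
        if self.cpeptide_pmol_l < 0:
            raise InputError(f"negative C-peptide for {self.subject_id}")
        if self.sex not in ("M", "F"):
            raise InputError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass
class GlucoseTrace:
    """A uniformly sampled interstitial glucose series.

    ``values`` may contain NaN for explicit gaps; the grid itself is
    always uniform at ``interval_min`` minutes starting at ``start``.
    """

    subject_id: str
    start: datetime
    interval_min: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.interval_min <= 0 or 60 % self.interval_min != 0:
            raise InputError(
                f"sampling interval must be a positive divisor of 60 min, "
                f"got {self.interval_min}"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() <= 0 or finite.max() >= 35.0):
            raise InputError("glucose values outside (0, 35) mmol/l")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration_hours(self) -> float:
        return self.n_samples * self.interval_min / 60.0

    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(
            start=self.start, periods=self.n_samples, freq=f"{int(self.interval_min)}min"
        )

    def clock_hours(self) -> np.ndarray:
        """Clock hour (0-24, fractional) of every sample."""
        t0 = self.start.hour + self.start.minute / 60.0 + self.start.second / 3600.0
        offs = np.arange(self.n_samples) * self.interval_min / 60.0
        return (t0 + offs) % 24.0


@dataclass
class SMBGReading:
    """One capillary fingerstick calibration reading."""

    subject_id: str
    time: datetime
    glucose_mmol_l: float

    def __post_init__(self) -> None:
        if self.glucose_mmol_l <= 0:
            raise InputError("SMBG glucose must be positive")


#: Closed vocabulary for the Clarke Q5/Q6 self-reported frequency categories.
FREQUENCY_CATEGORIES = (
    "none",
    "1-3 per month",
    "1 per week",
    "2-3 per week",
    "4-5 per week",
    "almost daily",
)


@dataclass
class ClarkeResponse:
    """Raw questionnaire response: seven 0/1 awareness items plus the
    frequency/severity questions kept as separate fields."""

    subject_id: str
    items: Sequence[int]  # seven 0 (aware) / 1 (reduced) item scores
    q3_assistance_per_year: int
    q4_unconscious_per_year: int
    q5_category: str
    q6_category: str

    def __post_init__(self) -> None:
        items = list(self.items)
        if len(items) != 7 or any(i not in (0, 1) for i in items):
            raise InputError("Clarke items must be seven 0/1 values")
        self.items = items
        for cat in (self.q5_category, self.q6_category):
            if cat not in FREQUENCY_CATEGORIES:
                raise InputError(f"unknown frequency category {cat!r}")
        if self.q3_assistance_per_year < 0 or self.q4_unconscious_per_year < 0:
            raise InputError("episode counts must be non-negative")


@dataclass
class QCWindow:
    """Quality-control verdict for one 24-h block of a CGM trace."""

    subject_id: str
    window_index: int
    window_start: datetime
    n_calibrations: int
    completeness: float
    pearson_r: Optional[float]
    mad_pct: Optional[float]
    pass_calibrations: bool
    pass_completeness: bool
    pass_correlation: bool
    pass_mad: bool

    @property
    def passed(self) -> bool:
        return (
            self.pass_calibrations
            and self.pass_completeness
            and self.pass_correlation
            and self.pass_mad
        )


@dataclass
class MetricSet:
    """Per-subject glycaemic-variability metrics on QC-retained data."""

    subject_id: str
    mean_glucose: float
    sd_glucose: float
    mage: Optional[float]  # None when no excursion exceeds 1 SD
    lbgi: float
    hours_of_data: float


@dataclass
class Episode:
    """One detected hypoglycaemia episode at a given threshold."""

    subject_id: str
    threshold: float
    start: datetime
    end: datetime
    duration_min: float  # time at/below threshold only
    nadir: float
    period: str  # "day" or "night", by start clock time

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError("episode start must precede end")
        if self.nadir > self.threshold:
            raise InputError("episode nadir above threshold")
        if self.period not in ("day", "night"):
            raise InputError("period must be 'day' or 'night'")


@dataclass
class ThresholdSummary:
    """Exposure-normalised hypoglycaemia summary at one threshold."""

    threshold: float
    n_episodes: int
    rate_per_week: float
    duration_min_per_week: float
    day_count: int
    night_count: int
    day_rate_per_week: float
    night_rate_per_week: float


@dataclass
class HypoSummary:
    """Per-subject hypoglycaemia summary across the standard thresholds."""

    subject_id: str
    exposure_weeks: float
    by_threshold: dict[float, ThresholdSummary] = field(default_factory=dict)


@dataclass
class ClarkeResult:
    """Scored questionnaire: awareness class plus recoded monthly rates."""

    subject_id: str
    score: int
    reduced_awareness: bool
    q5_rate_per_month: float
    q6_rate_per_month: float
    q3_any_assistance: bool
    q4_any_unconscious: bool

    def __post_init__(self) -> None:
        if not (0 <= self.score <= 7):
            raise InputError("Clarke score must lie in [0, 7]")
        if self.reduced_awareness != (self.score >= 4):
            raise InputError("reduced awareness must equal (score >= 4)")


@dataclass
class GroupComparison:
    """An estimate with CI and p-value for a low-vs-high C-peptide contrast."""

    outcome: str
    contrast: str
    effect_type: str  # mean difference | proportion difference | rate ratio | odds ratio
    estimate: float
    ci_low: float
    ci_high: float
    p_value: Optional[float]
    adjusted_for: tuple[str, ...] = ()
    method: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise InputError("p-value outside [0, 1]")
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not (self.ci_low <= self.estimate <= self.ci_high or
                    np.isnan(self.estimate)):
                raise InputError("estimate outside its own CI")


def period_of(time: datetime) -> str:
    """Day/night assignment of a clock instant.

    Night is 00:00-08:00; 08:00 itself belongs to day, 00:00 to night.
    """
    h = time.hour + time.minute / 60.0 + time.second / 3600.0
    return "night" if h < NIGHT_END_HOUR else "day"
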