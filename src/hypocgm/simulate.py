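"""Synthetic cohort generator.

Emulates the two C-peptide strata of an insulin-treated type 2 diabetes
cohort so every downstream stage (QC, variability metrics, episode
detection, questionnaire scoring, group statistics) is testable without
any real recordings, and so injected ground truth can be recovered.

A subject's interstitial glucose trace is built as

    g(t) = soft_floor( baseline + circadian(t) + OU(t) )  with excursions
           carved in, clamped to the sensor range 1.1-33.3 mmol/l.

* ``OU(t)`` is a stationary Ornstein-Uhlenbeck process discretised with
  the exact AR(1) transition, so its stationary SD is exactly the
  configured parameter.
* ``circadian(t)`` is a sinusoid peaking at the configured acrophase
  (late afternoon by default, so the trough - and with it most
  spontaneous lows - falls in the night window).
* ``soft_floor`` is a smooth softplus floor representing
  counter-regulation: background glycaemia does not drift below
  ~4.6 mmol/l on its own, which makes the marginal distribution
  right-skewed (as real CGM in poorly controlled type 2 diabetes is) and
  leaves all time below 4.0 mmol/l to the explicit excursion process.
* Hypoglycaemic excursions are a Poisson point process; each event is a
  trapezoidal dip (half-cosine descent, plateau at the drawn nadir,
  half-cosine recovery) sized so its time at/below 4.0 mmol/l equals the
  drawn duration, making injected rate and duration recoverable by the
  episode detector.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
from scipy import signal

from .clarke import RECODE_MAP
from .config import (
    ExcursionParams,
    GeneratorConfig,
    GroupConfig,
    default_cgm_config,
)
from .errors import ConfigError, InputError
from .types import (
    FREQUENCY_CATEGORIES,
    GLUCOSE_CLAMP_MMOL,
    ClarkeResponse,
    GlucoseTrace,
    SMBGReading,
    SubjectRecord,
)

logger = logging.getLogger(__name__)

#: Threshold (mmol/l) at which excursion durations are defined/booked.
DURATION_THRESHOLD = 4.0

#: Minimum separation (min) enforced between injected excursion spans; this
#: exceeds the detector's 20-min gap-merge rule so injected events can never
#: merge into one detected episode.
EVENT_SEPARATION_MIN = 30.0

_MEAL_HOURS = (7.5, 12.25, 17.75, 21.5)


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None or (isinstance(seed, (int, np.integer)) and seed < 0):
        raise InputError(f"seed must be a non-negative integer, got {seed!r}")
    return np.random.default_rng(seed)


def soft_floor(x: np.ndarray, floor: float, softness: float) -> np.ndarray:
    """Smooth one-sided floor: identity well above ``floor``, asymptoting to
    ``floor`` below it (softplus, numerically stable in both tails)."""
    z = (np.asarray(x, dtype=float) - floor) / softness
    out = np.where(
        z > 0,
        x + softness * np.log1p(np.exp(-np.abs(z))),
        floor + softness * np.log1p(np.exp(-np.abs(z))),
    )
    return out


@dataclass
class InjectedEvent:
    """Ground-truth record of one injected hypoglycaemic excursion."""

    subject_id: str
    start: datetime  # start of the dip span (descent onset)
    end: datetime  # end of the dip span (recovery complete)
    nadir: float
    target_below_min: float  # drawn time at/below 4.0 mmol/l
    realized_below_min: float  # realised on the sampling grid
    night_only: bool
    start_index: int
    end_index: int  # exclusive


def _ou_series(
    n: int, theta_per_h: float, sd: float, dt_h: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary OU sample path via the exact AR(1) discretisation."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    rho = math.exp(-theta_per_h * dt_h)
    innov = rng.standard_normal(n) * sd * math.sqrt(max(0.0, 1.0 - rho * rho))
    x0 = rng.standard_normal() * sd
    # x[i] = innov[i] + rho * x[i-1], seeded from the stationary draw x0
    x, _ = signal.lfilter([1.0], [1.0, -rho], innov, zi=np.array([rho * x0]))
    return x


def generate_trace(
    subject: SubjectRecord,
    cfg: GeneratorConfig,
    seed: int,
    with_events: bool = False,
):
    """Simulate one subject's CGM trace (excursions included).

    Identical ``(subject.group, cfg, seed)`` give bit-identical traces.
    With ``with_events=True`` also returns the injected ground truth.
    """
    cfg.validate()
    group = cfg.group(subject.group)
    tp = group.trace
    rng = _rng_from(seed)

    n = int(round(tp.recording_days * 24 * 60 / tp.interval_min))
    dt_h = tp.interval_min / 60.0
    start = datetime(2017, 1, 2) + timedelta(hours=cfg.session_start_hour)

    clock = (cfg.session_start_hour + np.arange(n) * dt_h) % 24.0
    circ = tp.circadian_amplitude_mmol * np.cos(
        2 * np.pi * (clock - tp.acrophase_hour) / 24.0
    )
    ou = _ou_series(n, tp.ou_theta_per_h, tp.ou_sd_mmol, dt_h, rng)
    values = soft_floor(tp.baseline_mmol + circ + ou, tp.floor_mmol,
                        tp.floor_softness_mmol)
    values = np.clip(values, *GLUCOSE_CLAMP_MMOL)

    trace = GlucoseTrace(subject.subject_id, start, tp.interval_min, values)
    # a child stream keeps the excursion draws independent of trace length
    exc_seed = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    trace, events = inject_excursions(trace, group.excursions, exc_seed)
    if with_events:
        return trace, events
    return trace


def inject_excursions(
    trace: GlucoseTrace, params: ExcursionParams, seed
) -> tuple[GlucoseTrace, list[InjectedEvent]]:
    """Carve Poisson-distributed hypoglycaemic dips into a gap-free trace.

    Returns the modified trace and the ground-truth event log.  Events are
    pairwise disjoint and separated by > 20 min; placement of an event is
    retried (bounded) until the separation/night constraints hold, and the
    event is dropped with a warning if no placement is found.
    """
    params.validate()
    rng = _rng_from(seed)
    v = np.asarray(trace.values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InputError("inject_excursions requires a gap-free trace")
    v = v.copy()

    n = v.size
    dt = trace.interval_min
    weeks = n * dt / (7 * 24 * 60)
    mean_span = params.duration_mean_min + 2 * params.ramp_min
    if params.rate_per_week * mean_span / (7 * 24 * 60) > 0.5:
        raise ConfigError(
            "requested excursion process would occupy > 50% of the trace"
        )

    k = int(rng.poisson(params.rate_per_week * weeks))
    events: list[InjectedEvent] = []
    if k == 0:
        return GlucoseTrace(trace.subject_id, trace.start, dt, v), events

    occupied = np.zeros(n, dtype=bool)
    sep = max(1, int(math.ceil(EVENT_SEPARATION_MIN / dt)))
    ramp_n = max(1, int(round(params.ramp_min / dt)))
    clock = trace.clock_hours()
    times = trace.times()

    sigma_ln = math.sqrt(math.log(1.0 + params.duration_cv**2))
    mu_ln = math.log(max(params.duration_mean_min, 1e-9)) - sigma_ln**2 / 2.0

    dropped = 0
    for _ in range(k):
        deep = rng.random() < params.deep_prob
        lo, hi = params.deep_nadir_range if deep else params.shallow_nadir_range
        nadir = float(rng.uniform(lo, hi))
        dur = 0.0
        for _try in range(100):
            dur = float(rng.lognormal(mu_ln, sigma_ln))
            if dur >= params.duration_min_min:
                break
        else:
            dur = params.duration_min_min
        night_only = deep and (rng.random() < params.night_prob_deep)

        placed = False
        for _attempt in range(200):
            flat_guess = max(1, int(round(dur / dt)))
            max_span = 2 * ramp_n + flat_guess + 2
            if n - max_span - 2 <= 1:
                break
            a = int(rng.integers(1, n - max_span - 1))
            level_in = v[a - 1]
            down = nadir + (level_in - nadir) * 0.5 * (
                1 + np.cos(np.pi * np.arange(1, ramp_n + 1) / ramp_n)
            )
            below_down = int(np.sum(down <= DURATION_THRESHOLD))
            # provisional up-ramp with the same edge level to size the plateau
            flat_n = max(1, int(round(dur / dt)) - below_down
                         - below_down)
            b = a + ramp_n + flat_n + ramp_n
            if b >= n:
                continue
            level_out = v[b]
            up = nadir + (level_out - nadir) * 0.5 * (
                1 - np.cos(np.pi * np.arange(1, ramp_n + 1) / ramp_n)
            )
            below_up = int(np.sum(up <= DURATION_THRESHOLD))
            # re-balance the plateau with the true up-ramp contribution
            flat_n = max(1, int(round(dur / dt)) - below_down - below_up)
            b = a + ramp_n + flat_n + ramp_n
            if b >= n:
                continue
            level_out = v[b]
            up = nadir + (level_out - nadir) * 0.5 * (
                1 - np.cos(np.pi * np.arange(1, ramp_n + 1) / ramp_n)
            )
            below_up = int(np.sum(up <= DURATION_THRESHOLD))

            lo_idx = max(0, a - sep)
            hi_idx = min(n, b + sep)
            if occupied[lo_idx:hi_idx].any():
                continue
            if night_only:
                span_h = (b - 1 - a) * dt / 60.0
                if not (
                    clock[a] < 8.0
                    and clock[b - 1] < 8.0
                    and clock[b - 1] >= clock[a]
                    and span_h <= 8.0
                ):
                    continue

            v[a : a + ramp_n] = down
            v[a + ramp_n : a + ramp_n + flat_n] = nadir
            v[a + ramp_n + flat_n : b] = up
            occupied[lo_idx:hi_idx] = True
            realized = (below_down + flat_n + below_up) * dt
            events.append(
                InjectedEvent(
                    subject_id=trace.subject_id,
                    start=times[a].to_pydatetime(),
                    end=(times[b - 1] + times.freq).to_pydatetime(),
                    nadir=nadir,
                    target_below_min=dur,
                    realized_below_min=realized,
                    night_only=night_only,
                    start_index=a,
                    end_index=b,
                )
            )
            placed = True
            break
        if not placed:
            dropped += 1
    if dropped:
        logger.warning(
            "dropped %d excursion(s) for %s: no admissible placement",
            dropped,
            trace.subject_id,
        )
    v = np.clip(v, *GLUCOSE_CLAMP_MMOL)
    events.sort(key=lambda e: e.start_index)
    return GlucoseTrace(trace.subject_id, trace.start, dt, v), events


def generate_smbg(
    trace: GlucoseTrace, cfg: GeneratorConfig, seed
) -> list[SMBGReading]:
    """Capillary calibration readings at jittered mealtime-like hours.

    Each reading is the nearest sensor sample times mean-one lognormal
    multiplicative noise with the configured CV; CV = 0 reproduces the
    sensor exactly.
    """
    cfg.smbg.validate()
    if trace.n_samples == 0:
        raise InputError("cannot generate SMBG for an empty trace")
    rng = _rng_from(seed)
    per_day = cfg.smbg.per_day
    if per_day == 0:
        return []
    cv = cfg.smbg.noise_cv
    sigma_ln = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    schedule = list(_MEAL_HOURS[:per_day])
    while len(schedule) < per_day:  # > 4/day: spread extras over the day
        schedule.append((schedule[-1] + 24.0 / per_day) % 24.0)

    dur_h = trace.duration_hours
    start_clock = trace.start.hour + trace.start.minute / 60.0
    n_days = int(dur_h // 24)
    dt_h = trace.interval_min / 60.0
    readings: list[SMBGReading] = []
    for day in range(n_days):
        for meal in schedule:
            t_h = day * 24.0 + (meal - start_clock) % 24.0 + rng.uniform(-0.5, 0.5)
            t_h = min(max(t_h, day * 24.0), min((day + 1) * 24.0, dur_h) - dt_h)
            idx = int(round(t_h / dt_h))
            idx = min(max(idx, 0), trace.n_samples - 1)
            sensor = trace.values[idx]
            if not np.isfinite(sensor):
                continue
            factor = 1.0 if sigma_ln == 0 else float(
                np.exp(rng.normal(-sigma_ln**2 / 2.0, sigma_ln))
            )
            readings.append(
                SMBGReading(
                    subject_id=trace.subject_id,
                    # whole seconds so the CSV round-trip is lossless
                    time=trace.start + timedelta(seconds=round(t_h * 3600.0)),
                    glucose_mmol_l=float(sensor * factor),
                )
            )
    readings.sort(key=lambda r: r.time)
    return readings


_RECODE_VALUES = [RECODE_MAP[c] for c in FREQUENCY_CATEGORIES]


def _nearest_category(count: int) -> str:
    """Coarsest Clarke category whose recoded monthly value is nearest the
    drawn count; ties break to the lower category."""
    best, best_err = FREQUENCY_CATEGORIES[0], abs(count - _RECODE_VALUES[0])
    for cat, val in zip(FREQUENCY_CATEGORIES[1:], _RECODE_VALUES[1:]):
        err = abs(count - val)
        if err < best_err:
            best, best_err = cat, err
    return best


def generate_questionnaire(
    subject: SubjectRecord, cfg: GeneratorConfig, seed
) -> ClarkeResponse:
    """Draw a Clarke response consistent with the subject's group rates."""
    cfg.validate()
    qp = cfg.group(subject.group).questionnaire
    rng = _rng_from(seed)
    k5 = int(rng.poisson(qp.q5_mean_per_month))
    k6 = int(rng.poisson(qp.q6_mean_per_month))
    items = (rng.random(7) < np.asarray(qp.item_probs)).astype(int)
    q3 = int(rng.poisson(qp.q3_rate_per_year))
    q4 = int(rng.poisson(qp.q4_rate_per_year))
    return ClarkeResponse(
        subject_id=subject.subject_id,
        items=list(items),
        q3_assistance_per_year=q3,
        q4_unconscious_per_year=q4,
        q5_category=_nearest_category(k5),
        q6_category=_nearest_category(k6),
    )


@dataclass
class Cohort:
    """A fully simulated dataset for one study."""

    config: GeneratorConfig
    subjects: list[SubjectRecord]
    traces: dict[str, GlucoseTrace]
    events: dict[str, list[InjectedEvent]]
    smbg: dict[str, list[SMBGReading]]
    clarke: list[ClarkeResponse]

    def write(self, out_dir) -> dict[str, str]:
        from . import io as _io

        return _io.write_cohort(self, out_dir)


def _subject_seed(master: int, index: int, stream: int) -> int:
    ss = np.random.SeedSequence([int(master), int(index), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31))


def _draw_subject(
    group: GroupConfig, idx: int, rng: np.random.Generator
) -> SubjectRecord:
    cov = group.covariates
    lo, hi = cov.cpeptide_range
    cp = float(
        np.clip(
            np.exp(rng.normal(math.log(cov.cpeptide_log_median),
                              cov.cpeptide_log_sd)),
            lo,
            hi,
        )
    )
    return SubjectRecord(
        subject_id=f"{group.label}{idx:03d}",
        group=group.label,
        cpeptide_pmol_l=cp,
        age_years=float(np.clip(rng.normal(cov.age_mean, cov.age_sd), 35, 95)),
        sex="M" if rng.random() < cov.male_frac else "F",
        hba1c_mmol_mol=float(
            np.clip(rng.normal(cov.hba1c_mean, cov.hba1c_sd), 40, 120)
        ),
        prandial_insulin=bool(rng.random() < cov.prandial_frac),
        insulin_dose_u_kg=float(
            np.clip(rng.normal(cov.dose_mean_u_kg, cov.dose_sd_u_kg), 0.1, 2.0)
        ),
    )


def generate_cohort(cfg: GeneratorConfig | None = None) -> Cohort:
    """Generate the full dataset for the configured study.

    Per-subject seeds derive deterministically from the master seed and the
    subject index, so the cohort is a pure function of the config.  For the
    CGM study with equally sized groups, subject ``i`` of each group forms a
    matched pair (sex copied, HbA1c drawn within the matching band), which
    is what the paired analyses downstream assume.
    """
    if cfg is None:
        cfg = default_cgm_config()
    cfg.validate()

    subjects: list[SubjectRecord] = []
    traces: dict[str, GlucoseTrace] = {}
    events: dict[str, list[InjectedEvent]] = {}
    smbg: dict[str, list[SMBGReading]] = {}
    clarke: list[ClarkeResponse] = []

    matched = (
        cfg.study == "cgm"
        and len(cfg.groups) == 2
        and cfg.groups[0].n_subjects == cfg.groups[1].n_subjects
    )
    per_group: list[list[SubjectRecord]] = []
    for g_i, group in enumerate(cfg.groups):
        rows = []
        for i in range(group.n_subjects):
            rng = np.random.default_rng(_subject_seed(cfg.seed, g_i * 100000 + i, 0))
            rows.append(_draw_subject(group, i, rng))
        per_group.append(rows)
    if matched:  # mirror the 1:1 sex / HbA1c matching of the CGM study
        rng_m = np.random.default_rng(_subject_seed(cfg.seed, 999999, 0))
        for s_low, s_high in zip(per_group[0], per_group[1]):
            s_high.sex = s_low.sex
            s_high.hba1c_mmol_mol = float(
                np.clip(s_low.hba1c_mmol_mol + rng_m.normal(0, 3), 40, 120)
            )

    sidx = 0
    for rows in per_group:
        for subj in rows:
            subjects.append(subj)
            if cfg.study == "cgm":
                tr, evs = generate_trace(
                    subj, cfg, _subject_seed(cfg.seed, sidx, 1), with_events=True
                )
                traces[subj.subject_id] = tr
                events[subj.subject_id] = evs
                smbg[subj.subject_id] = generate_smbg(
                    tr, cfg, _subject_seed(cfg.seed, sidx, 2)
                )
            clarke.append(
                generate_questionnaire(subj, cfg, _subject_seed(cfg.seed, sidx, 3))
            )
            sidx += 1
    return Cohort(cfg, subjects, traces, events, smbg, clarke)


# ---------------------------------------------------------------------------
# Pilot calibration of the background-process constants.
# ---------------------------------------------------------------------------

def calibrate_trace_params(
    group: GroupConfig,
    target_mean: float,
    target_sd: float,
    n_pilot: int = 400,
    pilot_days: float = 14.0,
    rounds: int = 4,
    seed: int = 20170,
) -> tuple[float, float]:
    """Calibrate (baseline, OU SD) so that with excursions injected the
    group mean glucose and mean per-subject SD hit the targets.

    One fixed-point pass per round: the baseline absorbs the mean error
    additively; the OU variance absorbs the variance error.  Returns the
    calibrated ``(baseline_mmol, ou_sd_mmol)``; the shipped defaults were
    produced by this routine.
    """
    import dataclasses as _dc

    tp = _dc.replace(group.trace, recording_days=pilot_days)
    g = _dc.replace(group, trace=tp)
    cfg = GeneratorConfig(study="cgm", groups=(g,), seed=seed)
    baseline, ou_sd = tp.baseline_mmol, tp.ou_sd_mmol
    for r in range(rounds):
        g = _dc.replace(
            g, trace=_dc.replace(g.trace, baseline_mmol=baseline, ou_sd_mmol=ou_sd)
        )
        cfg = GeneratorConfig(study="cgm", groups=(g,), seed=seed)
        means, sds = [], []
        for i in range(n_pilot):
            subj = SubjectRecord(
                f"pilot{i:04d}", g.label, 100.0, 70.0, "M", 70.0, True, 0.6
            )
            tr = generate_trace(subj, cfg, _subject_seed(seed + r, i, 1))
            means.append(float(np.mean(tr.values)))
            sds.append(float(np.std(tr.values, ddof=1)))
        m_hat, sd_hat = float(np.mean(means)), float(np.mean(sds))
        baseline += target_mean - m_hat
        var_new = max(0.01, ou_sd**2 + (target_sd**2 - sd_hat**2))
        ou_sd = math.sqrt(var_new)
    return baseline, ou_sd
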