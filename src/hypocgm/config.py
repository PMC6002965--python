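"""Generator and pipeline configuration.

A single :class:`GeneratorConfig` drives both the CGM study (two
C-peptide strata, 17 + 17 subjects with ~4 days of 5-min CGM) and the
questionnaire study (35 + 221 subjects with Clarke responses).  Defaults
encode the study conditions: matched mean glucose between strata but
higher within-subject variability and higher hypoglycaemic-excursion
rates in the severely insulin-deficient (< 200 pmol/l) group.

Configs round-trip through a flat ``key = value`` text file (see
:func:`save_config` / :func:`load_config`); keys are dotted paths such
as ``group.low.trace.baseline_mmol``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from .errors import ConfigError


@dataclass
class TraceParams:
    """Background glucose process: baseline + circadian sinusoid +
    mean-reverting (OU/AR(1)) noise, passed through a smooth
    counter-regulatory floor.

    ``baseline_mmol`` and ``ou_sd_mmol`` ship pre-calibrated (pilot
    simulation) so the post-QC group mean glucose and mean per-subject SD
    match the study targets once excursions are injected.
    """

    baseline_mmol: float = 10.2
    ou_theta_per_h: float = 0.5  # mean-reversion rate; 1/theta = 2 h memory
    ou_sd_mmol: float = 3.0  # stationary SD of the OU component
    circadian_amplitude_mmol: float = 2.0
    acrophase_hour: float = 16.0  # clock hour of the circadian peak
    interval_min: float = 5.0
    recording_days: float = 4.25
    floor_mmol: float = 4.6  # counter-regulatory soft floor
    floor_softness_mmol: float = 0.5

    def validate(self) -> None:
        if self.ou_sd_mmol < 0 or self.circadian_amplitude_mmol < 0:
            raise ConfigError("SDs and amplitudes must be >= 0")
        if self.ou_theta_per_h < 0:
            raise ConfigError("OU reversion rate must be >= 0")
        if self.interval_min <= 0 or 60 % self.interval_min != 0:
            raise ConfigError("sampling interval must divide 60 min")
        if self.recording_days < 1:
            raise ConfigError("recording days must be >= 1")
        if self.floor_mmol <= 0 or self.floor_softness_mmol <= 0:
            raise ConfigError("floor parameters must be positive")


@dataclass
class ExcursionParams:
    """Poisson process of discrete hypoglycaemic excursions.

    Durations are the target time at/below 4.0 mmol/l per event
    (lognormal, left-truncated so every event is detectable); nadirs are
    a two-component mixture with ``deep_prob`` giving the probability a
    nadir falls at/below 3.0 mmol/l.
    """

    rate_per_week: float = 5.5
    duration_mean_min: float = 115.0
    duration_cv: float = 0.5
    duration_min_min: float = 25.0
    deep_prob: float = 1.8 / 5.5
    deep_nadir_range: tuple[float, float] = (1.9, 3.0)
    shallow_nadir_range: tuple[float, float] = (3.1, 3.9)
    night_prob_deep: float = 0.3  # P(restricted to 00:00-08:00 | nadir <= 3)
    ramp_min: float = 35.0  # descent/recovery ramp length

    def validate(self) -> None:
        if self.rate_per_week < 0:
            raise ConfigError("excursion rate must be >= 0")
        if self.duration_mean_min < 0 or self.duration_min_min < 0:
            raise ConfigError("durations must be >= 0")
        if self.duration_cv < 0:
            raise ConfigError("duration CV must be >= 0")
        if not (0 <= self.deep_prob <= 1 and 0 <= self.night_prob_deep <= 1):
            raise ConfigError("probabilities must lie in [0, 1]")
        for lo, hi in (self.deep_nadir_range, self.shallow_nadir_range):
            if lo <= 0 or hi <= 0 or lo > hi:
                raise ConfigError("nadir ranges must be positive and ordered")
        if self.ramp_min <= 0:
            raise ConfigError("ramp length must be positive")


@dataclass
class QuestionnaireParams:
    """Clarke-response generator: true monthly symptomatic (Q5) and
    asymptomatic (Q6) episode counts are Poisson with the group mean; the
    seven awareness items are independent Bernoulli draws."""

    q5_mean_per_month: float = 1.8
    q6_mean_per_month: float = 0.69
    item_probs: tuple[float, ...] = (0.22,) * 7
    q3_rate_per_year: float = 0.4
    q4_rate_per_year: float = 0.05

    def validate(self) -> None:
        if self.q5_mean_per_month < 0 or self.q6_mean_per_month < 0:
            raise ConfigError("questionnaire rates must be >= 0")
        if len(self.item_probs) != 7 or any(
            not (0 <= p <= 1) for p in self.item_probs
        ):
            raise ConfigError("item_probs must be seven probabilities")
        if self.q3_rate_per_year < 0 or self.q4_rate_per_year < 0:
            raise ConfigError("severity rates must be >= 0")


@dataclass
class CovariateParams:
    """Distributions for the subject-metadata covariates."""

    cpeptide_log_median: float = 35.0
    cpeptide_log_sd: float = 0.8
    cpeptide_range: tuple[float, float] = (5.0, 199.0)
    age_mean: float = 72.0
    age_sd: float = 7.0
    male_frac: float = 0.65
    hba1c_mean: float = 72.0
    hba1c_sd: float = 12.0
    prandial_frac: float = 1.0
    dose_mean_u_kg: float = 0.71
    dose_sd_u_kg: float = 0.15

    def validate(self) -> None:
        lo, hi = self.cpeptide_range
        if lo < 0 or lo > hi:
            raise ConfigError("C-peptide range must be ordered and >= 0")
        if not (0 <= self.male_frac <= 1 and 0 <= self.prandial_frac <= 1):
            raise ConfigError("fractions must lie in [0, 1]")


@dataclass
class GroupConfig:
    label: str = "low"
    n_subjects: int = 17
    trace: TraceParams = field(default_factory=TraceParams)
    excursions: ExcursionParams = field(default_factory=ExcursionParams)
    questionnaire: QuestionnaireParams = field(default_factory=QuestionnaireParams)
    covariates: CovariateParams = field(default_factory=CovariateParams)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("each group needs at least one subject")
        self.trace.validate()
        self.excursions.validate()
        self.questionnaire.validate()
        self.covariates.validate()


@dataclass
class SmbgParams:
    per_day: int = 4
    noise_cv: float = 0.045

    def validate(self) -> None:
        if self.per_day < 0:
            raise ConfigError("SMBG readings/day must be >= 0")
        if self.noise_cv < 0:
            raise ConfigError("SMBG noise CV must be >= 0")


@dataclass
class GeneratorConfig:
    study: str = "cgm"  # "cgm" or "questionnaire"
    groups: tuple[GroupConfig, ...] = ()
    smbg: SmbgParams = field(default_factory=SmbgParams)
    seed: int = 0
    session_start_hour: float = 12.0  # sessions start mid-day at the clinic

    def validate(self) -> None:
        if self.study not in ("cgm", "questionnaire"):
            raise ConfigError(f"unknown study kind {self.study!r}")
        if not self.groups:
            raise ConfigError("config defines no groups")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigError("group labels must be unique")
        for g in self.groups:
            g.validate()
        self.smbg.validate()
        if not (0 <= self.session_start_hour < 24):
            raise ConfigError("session start hour must lie in [0, 24)")

    def group(self, label: str) -> GroupConfig:
        for g in self.groups:
            if g.label == label:
                return g
        raise ConfigError(f"group {label!r} not in config")


# ---------------------------------------------------------------------------
# Packaged default configurations.
#
# baseline_mmol / ou_sd_mmol below are the output of
# simulate.calibrate_trace_params() (pilot of 400 subjects, 14-day traces,
# seed 20170) so that, with the default excursion process injected, the group
# mean glucose and mean per-subject SD land on the study targets
# (low: 10.2 / 4.15 mmol/l, high: 9.9 / 3.01 mmol/l).
# ---------------------------------------------------------------------------

#: Calibrated background-process constants per CGM-study group.
CGM_CALIBRATED = {
    "low": {"baseline_mmol": 10.594, "ou_sd_mmol": 3.896},
    "high": {"baseline_mmol": 10.021, "ou_sd_mmol": 2.628},
}


def default_cgm_config(seed: int = 0) -> GeneratorConfig:
    """The CGM-study conditions: 17 + 17 subjects, ~4 days of 5-min CGM."""
    low = GroupConfig(
        label="low",
        n_subjects=17,
        trace=TraceParams(
            baseline_mmol=CGM_CALIBRATED["low"]["baseline_mmol"],
            ou_sd_mmol=CGM_CALIBRATED["low"]["ou_sd_mmol"],
        ),
        excursions=ExcursionParams(
            rate_per_week=5.5,
            duration_mean_min=115.0,
            deep_prob=1.8 / 5.5,
            night_prob_deep=0.3,
        ),
        questionnaire=QuestionnaireParams(
            q5_mean_per_month=3.5,
            q6_mean_per_month=1.4,
            item_probs=(0.29,) * 7,
            q4_rate_per_year=0.25,
        ),
        covariates=CovariateParams(),
    )
    high = GroupConfig(
        label="high",
        n_subjects=17,
        trace=TraceParams(
            baseline_mmol=CGM_CALIBRATED["high"]["baseline_mmol"],
            ou_sd_mmol=CGM_CALIBRATED["high"]["ou_sd_mmol"],
        ),
        excursions=ExcursionParams(
            rate_per_week=2.1,
            duration_mean_min=106.0,
            deep_prob=0.4 / 2.1,
            night_prob_deep=1.0,  # deep events confined to the night window
        ),
        questionnaire=QuestionnaireParams(
            q5_mean_per_month=1.8,
            q6_mean_per_month=0.69,
            item_probs=(0.22,) * 7,
            q4_rate_per_year=0.05,
        ),
        covariates=CovariateParams(
            cpeptide_log_median=1150.0,
            cpeptide_log_sd=0.3,
            cpeptide_range=(601.0, 3500.0),
            age_mean=71.8,
            prandial_frac=0.59,
            dose_mean_u_kg=0.52,
        ),
    )
    return GeneratorConfig(study="cgm", groups=(low, high), seed=seed)


def default_questionnaire_config(seed: int = 0) -> GeneratorConfig:
    """The questionnaire-study conditions: 35 low + 221 high C-peptide
    subjects with insulin-treated type 2 diabetes."""
    cgm = default_cgm_config(seed)
    low = dataclasses.replace(
        cgm.group("low"),
        n_subjects=35,
        covariates=dataclasses.replace(
            cgm.group("low").covariates,
            age_mean=68.2,
            prandial_frac=0.84,
            hba1c_mean=71.3,
            dose_mean_u_kg=0.73,
        ),
    )
    high = dataclasses.replace(
        cgm.group("high"),
        n_subjects=221,
        covariates=CovariateParams(
            cpeptide_log_median=650.0,
            cpeptide_log_sd=0.6,
            cpeptide_range=(200.0, 4000.0),
            age_mean=66.0,
            male_frac=0.63,
            hba1c_mean=66.9,
            prandial_frac=0.44,
            dose_mean_u_kg=0.63,
        ),
    )
    return GeneratorConfig(study="questionnaire", groups=(low, high), seed=seed)


# ---------------------------------------------------------------------------
# Flat key = value config file round-trip.
# ---------------------------------------------------------------------------

def _flatten(prefix: str, obj, out: dict[str, str]) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        for f in dataclasses.fields(obj):
            _flatten(f"{prefix}{f.name}.", getattr(obj, f.name), out)
    elif isinstance(obj, (tuple, list)):
        out[prefix[:-1]] = ", ".join(repr(x) if isinstance(x, str) else str(x)
                                     for x in obj)
    else:
        out[prefix[:-1]] = str(obj)


def config_to_flat(cfg: GeneratorConfig) -> dict[str, str]:
    out: dict[str, str] = {}
    out["study"] = cfg.study
    out["seed"] = str(cfg.seed)
    out["session_start_hour"] = str(cfg.session_start_hour)
    _flatten("smbg.", cfg.smbg, out)
    for g in cfg.groups:
        d: dict[str, str] = {}
        _flatten("", g, d)
        d.pop("label", None)
        for k, v in d.items():
            out[f"group.{g.label}.{k}"] = v
    return out


def save_config(cfg: GeneratorConfig, path) -> None:
    cfg.validate()
    lines = ["# hypocgm flat configuration (key = value)"]
    lines += [f"{k} = {v}" for k, v in config_to_flat(cfg).items()]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_scalar(text: str, typ):
    text = text.strip()
    if typ is bool:
        return text.lower() in ("true", "1", "yes")
    if typ is int:
        return int(text)
    if typ is float:
        return float(text)
    return text


def _build_dataclass(cls, flat: dict[str, str], prefix: str):
    kwargs = {}
    for f in dataclasses.fields(cls):
        key = f"{prefix}{f.name}"
        ftype = f.type if isinstance(f.type, type) else None
        if dataclasses.is_dataclass(_DC_FIELDS.get((cls, f.name))):
            kwargs[f.name] = _build_dataclass(
                _DC_FIELDS[(cls, f.name)], flat, f"{key}."
            )
        elif key in flat:
            raw = flat[key]
            if (cls, f.name) in _TUPLE_FIELDS:
                elem = _TUPLE_FIELDS[(cls, f.name)]
                kwargs[f.name] = tuple(
                    _parse_scalar(x, elem) for x in raw.split(",") if x.strip()
                )
            else:
                kwargs[f.name] = _parse_scalar(raw, ftype or _scalar_type(cls, f.name))
    return cls(**kwargs)


# Nested-dataclass and tuple-valued fields, made explicit so the flat-file
# loader needs no runtime type introspection tricks.
_DC_FIELDS = {
    (GroupConfig, "trace"): TraceParams,
    (GroupConfig, "excursions"): ExcursionParams,
    (GroupConfig, "questionnaire"): QuestionnaireParams,
    (GroupConfig, "covariates"): CovariateParams,
}
_TUPLE_FIELDS = {
    (ExcursionParams, "deep_nadir_range"): float,
    (ExcursionParams, "shallow_nadir_range"): float,
    (QuestionnaireParams, "item_probs"): float,
    (CovariateParams, "cpeptide_range"): float,
}
_SCALAR_TYPES = {
    (GroupConfig, "n_subjects"): int,
    (SmbgParams, "per_day"): int,
}


def _scalar_type(cls, name):
    return _SCALAR_TYPES.get((cls, name), float)


def load_config(path) -> GeneratorConfig:
    flat: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            k, v = line.split("=", 1)
            flat[k.strip()] = v.strip()

    labels: list[str] = []
    for k in flat:
        if k.startswith("group."):
            lab = k.split(".", 2)[1]
            if lab not in labels:
                labels.append(lab)
    groups = []
    for lab in labels:
        g = _build_dataclass(GroupConfig, flat, f"group.{lab}.")
        g.label = lab
        groups.append(g)
    cfg = GeneratorConfig(
        study=flat.get("study", "cgm"),
        groups=tuple(groups),
        smbg=_build_dataclass(SmbgParams, flat, "smbg."),
        seed=int(flat.get("seed", "0")),
        session_start_hour=float(flat.get("session_start_hour", "12.0")),
    )
    cfg.validate()
    return cfg
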