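"""CSV interchange formats with schema validation.

All glucose I/O is in mmol/l and all timestamps are ISO-8601 naive local
times.  Readers fail fast with row/column diagnostics; user-supplied
files in these schemas can drive the pipeline in place of the simulator.

Schemas
-------
subjects.csv   subject_id, group, cpeptide_pmol_l, age_years, sex,
               hba1c_mmol_mol, prandial_insulin, insulin_dose_u_kg,
               diabetes_type
cgm.csv        subject_id, timestamp, glucose_mmol_l  (uniform grid per
               subject; an empty glucose field is an explicit gap)
smbg.csv       subject_id, timestamp, glucose_mmol_l
clarke.csv     subject_id, item1..item7, q3_assistance_per_year,
               q4_unconscious_per_year, q5_category, q6_category
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .clarke import canonical_category
from .errors import SchemaError
from .types import ClarkeResponse, GlucoseTrace, SMBGReading, SubjectRecord

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import Cohort

SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "cpeptide_pmol_l",
    "age_years",
    "sex",
    "hba1c_mmol_mol",
    "prandial_insulin",
    "insulin_dose_u_kg",
    "diabetes_type",
]
CGM_COLUMNS = ["subject_id", "timestamp", "glucose_mmol_l"]
CLARKE_COLUMNS = (
    ["subject_id"]
    + [f"item{i}" for i in range(1, 8)]
    + [
        "q3_assistance_per_year",
        "q4_unconscious_per_year",
        "q5_category",
        "q6_category",
    ]
)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_subjects_csv(path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    _require_columns(df, SUBJECT_COLUMNS, path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    group=str(row["group"]),
                    cpeptide_pmol_l=float(row["cpeptide_pmol_l"]),
                    age_years=float(row["age_years"]),
                    sex=str(row["sex"]),
                    hba1c_mmol_mol=float(row["hba1c_mmol_mol"]),
                    prandial_insulin=bool(row["prandial_insulin"]),
                    insulin_dose_u_kg=float(row["insulin_dose_u_kg"]),
                    diabetes_type=str(row["diabetes_type"]),
                )
            )
        except Exception as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def write_subjects_csv(subjects, path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "cpeptide_pmol_l": round(s.cpeptide_pmol_l, 1),
                "age_years": round(s.age_years, 1),
                "sex": s.sex,
                "hba1c_mmol_mol": round(s.hba1c_mmol_mol, 1),
                "prandial_insulin": s.prandial_insulin,
                "insulin_dose_u_kg": round(s.insulin_dose_u_kg, 3),
                "diabetes_type": s.diabetes_type,
            }
            for s in subjects
        ],
        columns=SUBJECT_COLUMNS,
    ).to_csv(path, index=False)


def read_cgm_csv(path) -> dict[str, GlucoseTrace]:
    df = pd.read_csv(path)
    _require_columns(df, CGM_COLUMNS, path)
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: column 'timestamp': {exc}") from exc
    traces: dict[str, GlucoseTrace] = {}
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("timestamp")
        ts = sub["timestamp"].to_numpy()
        if len(ts) < 2:
            raise SchemaError(f"{path}: subject {sid}: fewer than 2 samples")
        diffs = np.diff(ts).astype("timedelta64[s]").astype(float)
        dt = diffs[0]
        if not np.allclose(diffs, dt):
            bad = int(np.argmax(~np.isclose(diffs, dt)))
            raise SchemaError(
                f"{path}: subject {sid}: non-uniform sampling near row "
                f"{sub.index[bad] + 2}"
            )
        traces[str(sid)] = GlucoseTrace(
            subject_id=str(sid),
            start=pd.Timestamp(ts[0]).to_pydatetime(),
            interval_min=dt / 60.0,
            values=sub["glucose_mmol_l"].to_numpy(dtype=float),
        )
    return traces


def write_cgm_csv(traces: dict[str, GlucoseTrace], path) -> None:
    frames = []
    for sid, tr in traces.items():
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "timestamp": tr.times().strftime("%Y-%m-%dT%H:%M:%S"),
                    "glucose_mmol_l": np.round(tr.values, 4),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_smbg_csv(path) -> dict[str, list[SMBGReading]]:
    df = pd.read_csv(path)
    _require_columns(df, CGM_COLUMNS, path)
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: column 'timestamp': {exc}") from exc
    out: dict[str, list[SMBGReading]] = {}
    for i, row in df.iterrows():
        try:
            reading = SMBGReading(
                subject_id=str(row["subject_id"]),
                time=row["timestamp"].to_pydatetime(),
                glucose_mmol_l=float(row["glucose_mmol_l"]),
            )
        except Exception as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
        out.setdefault(reading.subject_id, []).append(reading)
    return out


def write_smbg_csv(smbg: dict[str, list[SMBGReading]], path) -> None:
    rows = [
        {
            "subject_id": sid,
            "timestamp": r.time.strftime("%Y-%m-%dT%H:%M:%S"),
            "glucose_mmol_l": round(r.glucose_mmol_l, 4),
        }
        for sid, readings in smbg.items()
        for r in readings
    ]
    pd.DataFrame(rows, columns=CGM_COLUMNS).to_csv(path, index=False)


def read_clarke_csv(path) -> list[ClarkeResponse]:
    df = pd.read_csv(path)
    _require_columns(df, CLARKE_COLUMNS, path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                ClarkeResponse(
                    subject_id=str(row["subject_id"]),
                    items=[int(row[f"item{j}"]) for j in range(1, 8)],
                    q3_assistance_per_year=int(row["q3_assistance_per_year"]),
                    q4_unconscious_per_year=int(row["q4_unconscious_per_year"]),
                    q5_category=canonical_category(str(row["q5_category"])),
                    q6_category=canonical_category(str(row["q6_category"])),
                )
            )
        except Exception as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def write_clarke_csv(responses, path) -> None:
    rows = []
    for r in responses:
        row = {"subject_id": r.subject_id}
        for j, item in enumerate(r.items, 1):
            row[f"item{j}"] = item
        row.update(
            q3_assistance_per_year=r.q3_assistance_per_year,
            q4_unconscious_per_year=r.q4_unconscious_per_year,
            q5_category=r.q5_category,
            q6_category=r.q6_category,
        )
        rows.append(row)
    pd.DataFrame(rows, columns=CLARKE_COLUMNS).to_csv(path, index=False)


def write_cohort(cohort: "Cohort", out_dir) -> dict[str, str]:
    """Write a simulated cohort to the CSV interchange formats; returns a
    name -> path manifest.  Ground-truth injected events are written too
    so parameter-recovery checks can run on file round-trips."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = {}

    path = os.path.join(out_dir, "subjects.csv")
    write_subjects_csv(cohort.subjects, path)
    manifest["subjects.csv"] = path

    if cohort.traces:
        path = os.path.join(out_dir, "cgm.csv")
        write_cgm_csv(cohort.traces, path)
        manifest["cgm.csv"] = path

        path = os.path.join(out_dir, "smbg.csv")
        write_smbg_csv(cohort.smbg, path)
        manifest["smbg.csv"] = path

        rows = [
            {
                "subject_id": ev.subject_id,
                "start": ev.start.strftime("%Y-%m-%dT%H:%M:%S"),
                "end": ev.end.strftime("%Y-%m-%dT%H:%M:%S"),
                "nadir": round(ev.nadir, 4),
                "target_below_min": round(ev.target_below_min, 2),
                "realized_below_min": round(ev.realized_below_min, 2),
                "night_only": ev.night_only,
            }
            for evs in cohort.events.values()
            for ev in evs
        ]
        path = os.path.join(out_dir, "injected_events.csv")
        pd.DataFrame(
            rows,
            columns=[
                "subject_id",
                "start",
                "end",
                "nadir",
                "target_below_min",
                "realized_below_min",
                "night_only",
            ],
        ).to_csv(path, index=False)
        manifest["injected_events.csv"] = path

    path = os.path.join(out_dir, "clarke.csv")
    write_clarke_csv(cohort.clarke, path)
    manifest["clarke.csv"] = path
    return manifest
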