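"""Readers/writers for cohort tables and model persistence.

Interchange format is plain CSV (UTF-8, header row, "." decimal):

* patient table: patient_id, age, weight_kg, tbsa_pct, full_thickness_pct,
  start_hour
* hourly table: patient_id, hour, infusion_ml_hr, uop_ml_hr

Hours are integers; rates and UOP are mL/hr floats. Models persist as
versioned JSON at full float precision. Every artifact written by the CLI
carries the run configuration and seed, as a "provenance" key in JSON
outputs and as a ``<name>.meta.json`` sidecar next to CSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .base_rate import BaseRateResults
from .cohort import HourlyRecord, PatientProfile, PatientSeries, cohort_to_frames
from .uop import UrineOutputResults

__all__ = [
    "PATIENT_COLUMNS",
    "HOURLY_COLUMNS",
    "LoadReport",
    "read_cohort",
    "write_cohort",
    "cohort_from_frames",
    "persist_models",
    "load_models",
    "write_provenance",
]

logger = logging.getLogger(__name__)

PATIENT_COLUMNS = ["patient_id", "age", "weight_kg", "tbsa_pct", "full_thickness_pct", "start_hour"]
HOURLY_COLUMNS = ["patient_id", "hour", "infusion_ml_hr", "uop_ml_hr"]
MODEL_FORMAT = "burnfluid-models/1"


@dataclass
class LoadReport:
    """Row accounting for a cohort load."""

    patients_read: int = 0
    hours_read: int = 0
    rejected: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def cohort_from_frames(
    patients: pd.DataFrame,
    hourly: pd.DataFrame,
    lenient: bool = False,
    report: LoadReport | None = None,
) -> list[PatientSeries]:
    """Validate and assemble PatientSeries from the two tables.

    Schema violations are collected with row context; by default any
    rejected row is a hard failure, with ``lenient`` they are dropped and
    logged in the report.
    """
    report = report if report is not None else LoadReport()
    missing = [c for c in PATIENT_COLUMNS if c not in patients.columns]
    missing += [c for c in HOURLY_COLUMNS if c not in hourly.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    series: dict[str, PatientSeries] = {}
    for i, row in patients.iterrows():
        try:
            profile = PatientProfile(
                patient_id=str(row["patient_id"]),
                weight=float(row["weight_kg"]),
                tbsa=float(row["tbsa_pct"]),
                age=float(row["age"]),
                full_thickness_tbsa=float(row["full_thickness_pct"]),
                start_hour=float(row["start_hour"]),
            )
        except (ValueError, TypeError) as exc:
            report.rejected.append(f"patient row {i}: {exc}")
            continue
        if profile.patient_id in series:
            report.rejected.append(f"patient row {i}: duplicate patient_id {profile.patient_id}")
            continue
        series[profile.patient_id] = PatientSeries(profile=profile, records=[])
        report.patients_read += 1

    seen: set[tuple[str, int]] = set()
    records: dict[str, list[HourlyRecord]] = {pid: [] for pid in series}
    for i, row in hourly.iterrows():
        pid = str(row["patient_id"])
        if pid not in series:
            report.rejected.append(f"hourly row {i}: unknown patient_id {pid}")
            continue
        try:
            hour = int(row["hour"])
            if hour != float(row["hour"]):
                raise ValueError(f"non-integer hour {row['hour']}")
            rec = HourlyRecord(
                hour=hour,
                infusion_rate=float(row["infusion_ml_hr"]),
                uop=float(row["uop_ml_hr"]),
            )
        except (ValueError, TypeError) as exc:
            report.rejected.append(f"hourly row {i}: {exc}")
            continue
        key = (pid, rec.hour)
        if key in seen:
            report.rejected.append(f"hourly row {i}: duplicate hour {rec.hour} for {pid}")
            continue
        seen.add(key)
        records[pid].append(rec)
        report.hours_read += 1

    if report.rejected and not lenient:
        detail = "; ".join(report.rejected[:10])
        raise ValueError(f"{report.n_rejected} rejected rows (use lenient to drop them): {detail}")
    out = []
    for pid, s in series.items():
        out.append(s.with_records(sorted(records[pid], key=lambda r: r.hour)))
    return out


def read_cohort(patient_path, hourly_path, lenient: bool = False) -> tuple[list[PatientSeries], LoadReport]:
    """Load a cohort from the two CSV files; returns (cohort, load report)."""
    report = LoadReport()
    patients = pd.read_csv(patient_path, comment="#")
    hourly = pd.read_csv(hourly_path, comment="#")
    cohort = cohort_from_frames(patients, hourly, lenient=lenient, report=report)
    if report.rejected:
        logger.warning("dropped %d malformed rows", report.n_rejected)
    return cohort, report


def write_cohort(cohort: list[PatientSeries], patient_path, hourly_path) -> None:
    patients, hourly = cohort_to_frames(cohort)
    patients.to_csv(patient_path, index=False)
    hourly.to_csv(hourly_path, index=False)


def write_provenance(path, provenance: dict) -> None:
    """Sidecar metadata for a CSV artifact."""
    meta = Path(str(path) + ".meta.json")
    with open(meta, "w") as fh:
        json.dump(provenance, fh, indent=2)


def persist_models(
    path,
    base: BaseRateResults | None = None,
    uop: UrineOutputResults | None = None,
    provenance: dict | None = None,
) -> None:
    """Write fitted models as versioned JSON (full float precision)."""
    payload = {"format": MODEL_FORMAT}
    if base is not None:
        payload["base_rate"] = base.to_dict()
    if uop is not None:
        payload["uop"] = uop.to_dict()
    if provenance is not None:
        payload["provenance"] = provenance
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_models(path) -> tuple[BaseRateResults | None, UrineOutputResults | None]:
    """Load models; refuses files with a different format stamp."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != MODEL_FORMAT:
        raise ValueError(
            f"model file {path} has format {payload.get('format')!r}, expected {MODEL_FORMAT!r}"
        )
    base = BaseRateResults.from_dict(payload["base_rate"]) if "base_rate" in payload else None
    uop = UrineOutputResults.from_dict(payload["uop"]) if "uop" in payload else None
    if uop is not None and uop.c2 == 0:
        logger.warning("loaded UOP model has c2 = 0; controller inversion unavailable")
    return base, uop
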