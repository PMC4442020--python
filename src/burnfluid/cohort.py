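"""Patient-level containers: static covariates and hourly infusion/urine records.

Hours are integer hours post-burn, starting at 1 for the first complete hour
after injury. A patient admitted ``start_hour`` hours after the burn simply
lacks the early hours; records within one patient must be strictly
increasing (contiguity is checked where an operation needs it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["PatientProfile", "HourlyRecord", "PatientSeries", "cohort_to_frames"]


@dataclass(frozen=True)
class PatientProfile:
    """Static covariates of one burn patient.

    Parameters
    ----------
    patient_id : str
        Opaque label.
    weight : float
        Body weight in kg; must be positive.
    tbsa : float
        Percent of total body surface area burned, in [0, 100].
    age : float, optional
        Age in years.
    full_thickness_tbsa : float
        Percent full-thickness burn; cannot exceed ``tbsa``.
    start_hour : float
        Hours post-burn at admission (>= 0).
    """

    patient_id: str
    weight: float
    tbsa: float
    age: float = float("nan")
    full_thickness_tbsa: float = 0.0
    start_hour: float = 0.0

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if not 0.0 <= self.tbsa <= 100.0:
            raise ValueError(f"tbsa must be within [0, 100], got {self.tbsa}")
        if self.full_thickness_tbsa > self.tbsa:
            raise ValueError("full_thickness_tbsa cannot exceed tbsa")
        if self.full_thickness_tbsa < 0:
            raise ValueError("full_thickness_tbsa must be >= 0")
        if self.start_hour < 0:
            raise ValueError("start_hour must be >= 0")


@dataclass(frozen=True)
class HourlyRecord:
    """One hour of observation: infusion actually given and urine measured."""

    hour: int  # hours post-burn, t >= 1
    infusion_rate: float  # mL/hr administered during hour t
    uop: float  # mL/hr urine output measured at the end of hour t

    def __post_init__(self) -> None:
        if self.hour < 1:
            raise ValueError(f"hour must be >= 1, got {self.hour}")
        if self.infusion_rate < 0:
            raise ValueError("infusion_rate must be >= 0")
        if self.uop < 0:
            raise ValueError("uop must be >= 0")


@dataclass
class PatientSeries:
    """A patient profile plus their ordered hourly trajectory (hours <= 48)."""

    profile: PatientProfile
    records: list[HourlyRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        hours = [r.hour for r in self.records]
        if len(set(hours)) != len(hours):
            raise ValueError(f"duplicate hours in series {self.profile.patient_id}")
        if hours != sorted(hours):
            self.records = sorted(self.records, key=lambda r: r.hour)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def hours(self) -> np.ndarray:
        return np.array([r.hour for r in self.records], dtype=int)

    @property
    def infusion_rates(self) -> np.ndarray:
        return np.array([r.infusion_rate for r in self.records], dtype=float)

    @property
    def uops(self) -> np.ndarray:
        return np.array([r.uop for r in self.records], dtype=float)

    def segments(self) -> list[list[HourlyRecord]]:
        """Split the record list at hour gaps into contiguous runs."""
        segs: list[list[HourlyRecord]] = []
        current: list[HourlyRecord] = []
        for rec in self.records:
            if current and rec.hour != current[-1].hour + 1:
                segs.append(current)
                current = []
            current.append(rec)
        if current:
            segs.append(current)
        return segs

    def block_volume(self, lo: int, hi: int) -> float:
        """Total infused volume (mL) over post-burn hours lo..hi inclusive."""
        return float(sum(r.infusion_rate for r in self.records if lo <= r.hour <= hi))

    def block_urine(self, lo: int, hi: int) -> float:
        return float(sum(r.uop for r in self.records if lo <= r.hour <= hi))

    def mean_rate(self, lo: int = 1, hi: int = 48) -> float:
        rates = [r.infusion_rate for r in self.records if lo <= r.hour <= hi]
        if not rates:
            raise ValueError(f"no records in hours {lo}..{hi}")
        return float(np.mean(rates))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.profile.patient_id,
                "hour": self.hours,
                "infusion_ml_hr": self.infusion_rates,
                "uop_ml_hr": self.uops,
            }
        )

    def with_records(self, records: list[HourlyRecord]) -> "PatientSeries":
        return replace(self, records=records)


def cohort_to_frames(cohort: list[PatientSeries]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (patient table, hourly table) DataFrames for a cohort."""
    patients = pd.DataFrame(
        {
            "patient_id": [s.profile.patient_id for s in cohort],
            "age": [s.profile.age for s in cohort],
            "weight_kg": [s.profile.weight for s in cohort],
            "tbsa_pct": [s.profile.tbsa for s in cohort],
            "full_thickness_pct": [s.profile.full_thickness_tbsa for s in cohort],
            "start_hour": [s.profile.start_hour for s in cohort],
        }
    )
    hourly = pd.concat([s.to_frame() for s in cohort], ignore_index=True)
    return patients, hourly
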