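"""Core domain records: one hospital encounter and its raw event streams."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import NamedTuple

from .features import TIME_VARYING

#: Hard inclusion bounds on length of stay.
MIN_STAY_HOURS = 2.0
MAX_STAY_DAYS = 90.0


class DiagnosisCategory(str, Enum):
    """Closed set of diagnosis-event categories.

    Site-specific ICD code lists are abstracted away: ingest maps whatever
    coding a source system uses onto these categories before anything
    downstream sees the record.
    """

    ARDS = "ARDS"
    SEPSIS_OR_SEPTIC_SHOCK = "SEPSIS_OR_SEPTIC_SHOCK"
    HEART_FAILURE = "HEART_FAILURE"
    COVID19 = "COVID19"
    OTHER = "OTHER"


class ObservationEvent(NamedTuple):
    """One time-stamped vital-sign or laboratory measurement."""

    feature_name: str
    value: float
    unit: str
    timestamp: datetime


class DiagnosisEvent(NamedTuple):
    """One time-stamped diagnosis entry (category already mapped)."""

    category: DiagnosisCategory
    timestamp: datetime


class PcrResult(NamedTuple):
    """One COVID-19 PCR test result."""

    timestamp: datetime
    positive: bool


@dataclass
class PatientRecord:
    """One encounter: demographics, observations, diagnoses, disposition."""

    patient_id: str
    age: float
    sex: str  # "male" | "female"
    admission_time: datetime
    discharge_time: datetime
    died_in_hospital: bool
    covid_pcr_results: list[PcrResult] = field(default_factory=list)
    observations: list[ObservationEvent] = field(default_factory=list)
    diagnoses: list[DiagnosisEvent] = field(default_factory=list)

    @property
    def length_of_stay_hours(self) -> float:
        return (self.discharge_time - self.admission_time).total_seconds() / 3600.0

    @property
    def disposition(self) -> str:
        return "expired" if self.died_in_hospital else "discharged"

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated encounter invariant."""
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if not self.admission_time < self.discharge_time:
            raise ValueError("admission_time must precede discharge_time")
        los_h = self.length_of_stay_hours
        if not (MIN_STAY_HOURS <= los_h <= MAX_STAY_DAYS * 24.0):
            raise ValueError(
                f"length of stay {los_h:.2f} h outside "
                f"[{MIN_STAY_HOURS} h, {MAX_STAY_DAYS} d]"
            )
        for obs in self.observations:
            if obs.feature_name not in TIME_VARYING or obs.feature_name == "sirs":
                raise ValueError(f"unexpected observed feature {obs.feature_name!r}")
            if not math.isfinite(obs.value):
                raise ValueError(f"non-finite value for {obs.feature_name!r}")
            if not (self.admission_time <= obs.timestamp <= self.discharge_time):
                raise ValueError("observation timestamp outside the stay")
        for dx in self.diagnoses:
            DiagnosisCategory(dx.category)  # membership check

    def first_diagnosis_time(self, category: DiagnosisCategory) -> datetime | None:
        times = [d.timestamp for d in self.diagnoses if d.category == category]
        return min(times) if times else None
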