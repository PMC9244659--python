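"""Shared fixtures: hand-built records and a reusable synthetic cohort."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from ardsmtl.features import NormalRangeTable
from ardsmtl.outcome_labels import derive_labels
from ardsmtl.preprocessing import determine_algotime
from ardsmtl.records import (
    DiagnosisCategory,
    DiagnosisEvent,
    ObservationEvent,
    PatientRecord,
    PcrResult,
)
from ardsmtl.synthetic_ehr import CohortConfig, generate_cohort

ADMIT = datetime(2021, 3, 1, 8, 0)


def make_record(
    observations: list[tuple[str, float, float]] | None = None,
    diagnoses: list[tuple[DiagnosisCategory, float]] | None = None,
    los_hours: float = 72.0,
    died: bool = False,
    pcr: list[tuple[float, bool]] | None = None,
    patient_id: str = "T0001",
    age: float = 55.0,
    sex: str = "female",
) -> PatientRecord:
    """Build an encounter from (feature, value, minutes-after-admission) rows."""
    obs = [
        ObservationEvent(f, v, "unit", ADMIT + timedelta(minutes=m))
        for f, v, m in (observations or [])
    ]
    dxs = [
        DiagnosisEvent(cat, ADMIT + timedelta(hours=h)) for cat, h in (diagnoses or [])
    ]
    pcr_events = [
        PcrResult(ADMIT + timedelta(hours=h), pos) for h, pos in (pcr or [])
    ]
    return PatientRecord(
        patient_id=patient_id,
        age=age,
        sex=sex,
        admission_time=ADMIT,
        discharge_time=ADMIT + timedelta(hours=los_hours),
        died_in_hospital=died,
        covid_pcr_results=pcr_events,
        observations=obs,
        diagnoses=dxs,
    )


#: a triage battery covering every required time-varying feature at t=10 min
REQUIRED_PANEL = [
    ("systolic_bp", 118.0, 10.0),
    ("diastolic_bp", 76.0, 10.0),
    ("heart_rate", 82.0, 10.0),
    ("respiratory_rate", 16.0, 10.0),
    ("spo2", 97.0, 10.0),
    ("temperature", 37.0, 10.0),
    ("wbc", 8.0, 10.0),
    ("lymphocytes", 30.0, 10.0),
    ("creatinine", 0.9, 10.0),
    ("neutrophils", 55.0, 10.0),
]


@pytest.fixture(scope="session")
def norm_table() -> NormalRangeTable:
    return NormalRangeTable.default()


@pytest.fixture(scope="session")
def small_cohort():
    """400 synthetic encounters with their latent severities (seed fixed)."""
    config = CohortConfig(n_patients=400, seed=42)
    records, severities = generate_cohort(config, return_severity=True)
    return records, severities


@pytest.fixture(scope="session")
def labeled_small_cohort(small_cohort):
    """Label sets + algotimes for the 400-patient cohort (train/val rules)."""
    records, _ = small_cohort
    algotimes = [determine_algotime(r, split="train_val").algotime for r in records]
    labels = [derive_labels(r, at) for r, at in zip(records, algotimes)]
    return records, algotimes, labels
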