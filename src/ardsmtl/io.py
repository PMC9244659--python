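"""Cohort CSV serialization: patients, observations, diagnoses.

A cohort round-trips losslessly through three CSV files with ISO-8601
datetimes:

* ``patients.csv`` — patient_id, age, sex, admission_time, discharge_time,
  died_in_hospital, disposition, covid_pcr_results (JSON-encoded list of
  [timestamp, "positive"/"negative"] pairs);
* ``observations.csv`` — patient_id, feature, value, unit, datetime;
* ``diagnoses.csv`` — patient_id, category, datetime.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .outcome_labels import LABEL_NAMES, LabelSet
from .records import (
    DiagnosisCategory,
    DiagnosisEvent,
    ObservationEvent,
    PatientRecord,
    PcrResult,
)

_ISO = "%Y-%m-%dT%H:%M:%S"


def write_cohort(records: list[PatientRecord], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    patients = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "admission_time": [r.admission_time.strftime(_ISO) for r in records],
            "discharge_time": [r.discharge_time.strftime(_ISO) for r in records],
            "died_in_hospital": [r.died_in_hospital for r in records],
            "disposition": [r.disposition for r in records],
            "covid_pcr_results": [
                json.dumps(
                    [
                        [t.strftime(_ISO), "positive" if pos else "negative"]
                        for t, pos in r.covid_pcr_results
                    ]
                )
                for r in records
            ],
        }
    )
    patients.to_csv(directory / "patients.csv", index=False)
    obs_rows = [
        (r.patient_id, o.feature_name, o.value, o.unit, o.timestamp.strftime(_ISO))
        for r in records
        for o in r.observations
    ]
    pd.DataFrame(
        obs_rows, columns=["patient_id", "feature", "value", "unit", "datetime"]
    ).to_csv(directory / "observations.csv", index=False)
    dx_rows = [
        (r.patient_id, d.category.value, d.timestamp.strftime(_ISO))
        for r in records
        for d in r.diagnoses
    ]
    pd.DataFrame(dx_rows, columns=["patient_id", "category", "datetime"]).to_csv(
        directory / "diagnoses.csv", index=False
    )


def read_cohort(directory: str | Path) -> list[PatientRecord]:
    directory = Path(directory)
    # round_trip float parsing: values must survive the CSV cycle bit-exactly
    patients = pd.read_csv(
        directory / "patients.csv", dtype={"patient_id": str},
        float_precision="round_trip",
    )
    observations = pd.read_csv(
        directory / "observations.csv", dtype={"patient_id": str},
        float_precision="round_trip",
    )
    diagnoses = pd.read_csv(directory / "diagnoses.csv", dtype={"patient_id": str})

    obs_by_pid: dict[str, list[ObservationEvent]] = {}
    for row in observations.itertuples(index=False):
        obs_by_pid.setdefault(row.patient_id, []).append(
            ObservationEvent(
                row.feature,
                float(row.value),
                str(row.unit),
                datetime.strptime(row.datetime, _ISO),
            )
        )
    dx_by_pid: dict[str, list[DiagnosisEvent]] = {}
    for row in diagnoses.itertuples(index=False):
        dx_by_pid.setdefault(row.patient_id, []).append(
            DiagnosisEvent(
                DiagnosisCategory(row.category), datetime.strptime(row.datetime, _ISO)
            )
        )
    records = []
    for row in patients.itertuples(index=False):
        pcr = [
            PcrResult(datetime.strptime(t, _ISO), res == "positive")
            for t, res in json.loads(row.covid_pcr_results)
        ]
        records.append(
            PatientRecord(
                patient_id=row.patient_id,
                age=float(row.age),
                sex=str(row.sex),
                admission_time=datetime.strptime(row.admission_time, _ISO),
                discharge_time=datetime.strptime(row.discharge_time, _ISO),
                died_in_hospital=bool(row.died_in_hospital),
                covid_pcr_results=pcr,
                observations=obs_by_pid.get(row.patient_id, []),
                diagnoses=dx_by_pid.get(row.patient_id, []),
            )
        )
    return records


def write_labels(
    patient_ids: list[str], label_sets: list[LabelSet], path: str | Path
) -> None:
    """Labels CSV: patient_id, the 13 binary columns, diagnosis_timing."""
    rows = []
    for pid, ls in zip(patient_ids, label_sets):
        row = {"patient_id": pid}
        row.update(dict(zip(LABEL_NAMES, ls.as_vector())))
        row["diagnosis_timing"] = ls.diagnosis_timing
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str})


def write_tensors(
    tensors: np.ndarray,
    patient_ids: list[str],
    algotimes: list,
    path_prefix: str | Path,
) -> None:
    """Portable array archive plus a JSON sidecar of per-patient metadata."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(prefix.with_suffix(".npz"), tensors=tensors)
    meta = [
        {
            "patient_id": pid,
            "algotime": at.algotime.strftime(_ISO),
            "source": at.source.value,
        }
        for pid, at in zip(patient_ids, algotimes)
    ]
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_tensors(path_prefix: str | Path) -> tuple[np.ndarray, list[dict]]:
    prefix = Path(path_prefix)
    with np.load(prefix.with_suffix(".npz")) as npz:
        tensors = npz["tensors"]
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return tensors, meta
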