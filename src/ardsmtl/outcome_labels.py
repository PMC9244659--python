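"""Derivation of the 13 binary outcome labels and the diagnosis-timing class.

The label family deliberately mixes narrow and broad definitions of the same
clinical events so a shared model can exploit their dependencies:

* five ARDS variants built from the ARDS diagnosis code, SpO2 nadirs below
  91% / 96%, and the absence of a prior heart-failure code;
* two sepsis variants (code alone, or code plus a SIRS score above 2);
* four hypoxemia variants (SpO2 below 91% / 96%, any time during the stay or
  strictly after the prediction time);
* in-hospital death and COVID-19 positivity.

Thresholds read literally: "below 91%" means strictly less than 91.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

from .preprocessing import chronologize, compute_sirs
from .records import DiagnosisCategory, PatientRecord

LABEL_NAMES = [
    "ards_1",
    "ards_2",
    "ards_3",
    "ards_4",
    "ards_5",
    "sepsis_6",
    "sepsis_7",
    "hypox_8",
    "hypox_9",
    "hypox_10",
    "hypox_11",
    "death_12",
    "covid_13",
]

SPO2_SEVERE = 91.0
SPO2_MILD = 96.0
SIRS_SEPSIS_THRESHOLD = 2  # sepsis requires SIRS score > 2
COVID_WINDOW = timedelta(days=7)


class DataIntegrityError(ValueError):
    """Label state contradicts the raw record (e.g. ARDS label without a code)."""


@dataclass(frozen=True)
class LabelSet:
    """The 13 binary outcomes plus the early/late diagnosis-timing class."""

    ards_1: bool
    ards_2: bool
    ards_3: bool
    ards_4: bool
    ards_5: bool
    sepsis_6: bool
    sepsis_7: bool
    hypox_8: bool
    hypox_9: bool
    hypox_10: bool
    hypox_11: bool
    death_12: bool
    covid_13: bool
    diagnosis_timing: str  # "early" | "late" | "none"

    def as_vector(self) -> list[int]:
        return [int(getattr(self, name)) for name in LABEL_NAMES]

    def check_implications(self) -> None:
        """Raise AssertionError if any structural implication is violated."""
        implications = [
            ("ards_1", "ards_2"),
            ("ards_3", "ards_1"),
            ("ards_4", "ards_2"),
            ("ards_1", "ards_5"),
            ("hypox_8", "hypox_9"),
            ("hypox_10", "hypox_8"),
            ("hypox_11", "hypox_9"),
            ("sepsis_6", "sepsis_7"),
        ]
        for a, b in implications:
            if getattr(self, a) and not getattr(self, b):
                raise AssertionError(f"{a} does not imply {b}")


def max_sirs_over_stay(record: PatientRecord) -> int:
    """Maximum SIRS score over the stay from forward-filled components."""
    series, _ = chronologize(record)
    events: list[tuple[datetime, str, float]] = []
    for feature in ("heart_rate", "respiratory_rate", "temperature", "wbc"):
        fs = series.get(feature)
        if fs is None:
            continue
        for t, v in zip(fs.times, fs.values):
            events.append((t.astype("datetime64[s]").item(), feature, float(v)))
    events.sort(key=lambda e: e[0])
    current = {"heart_rate": None, "respiratory_rate": None, "temperature": None, "wbc": None}
    best = 0
    for _, feature, v in events:
        current[feature] = v
        best = max(
            best,
            compute_sirs(
                current["heart_rate"],
                current["respiratory_rate"],
                current["temperature"],
                current["wbc"],
            ),
        )
    return best


def _spo2_minima(record: PatientRecord, algotime: datetime) -> tuple[float, float]:
    """(min SpO2 over the whole stay, min SpO2 strictly after algotime)."""
    series, _ = chronologize(record)
    fs = series.get("spo2")
    if fs is None or len(fs.values) == 0:
        return float("inf"), float("inf")
    overall = float(fs.values.min())
    after_mask = fs.times.astype("datetime64[s]") > np.datetime64(algotime, "s")
    after = float(fs.values[after_mask].min()) if after_mask.any() else float("inf")
    return overall, after


def derive_labels(record: PatientRecord, algotime: datetime) -> LabelSet:
    """Derive the full label set for one encounter at its prediction time."""
    ards_code_time = record.first_diagnosis_time(DiagnosisCategory.ARDS)
    hf_time = record.first_diagnosis_time(DiagnosisCategory.HEART_FAILURE)
    sepsis_code = (
        record.first_diagnosis_time(DiagnosisCategory.SEPSIS_OR_SEPTIC_SHOCK) is not None
    )
    min_spo2, min_spo2_after = _spo2_minima(record, algotime)

    ards_5 = ards_code_time is not None
    ards_1 = ards_5 and min_spo2 < SPO2_SEVERE
    ards_2 = ards_5 and min_spo2 < SPO2_MILD
    # "prior diagnoses": a heart-failure code time-stamped before the first
    # ARDS code
    no_prior_hf = not (
        ards_code_time is not None and hf_time is not None and hf_time < ards_code_time
    )
    ards_3 = ards_1 and no_prior_hf
    ards_4 = ards_2 and no_prior_hf

    sepsis_7 = sepsis_code
    sepsis_6 = sepsis_7 and max_sirs_over_stay(record) > SIRS_SEPSIS_THRESHOLD

    hypox_8 = min_spo2 < SPO2_SEVERE
    hypox_9 = min_spo2 < SPO2_MILD
    hypox_10 = min_spo2_after < SPO2_SEVERE
    hypox_11 = min_spo2_after < SPO2_MILD

    death_12 = record.died_in_hospital

    pcr_positive = any(
        r.positive and record.admission_time <= r.timestamp <= record.discharge_time
        for r in record.covid_pcr_results
    )
    covid_dx_time = record.first_diagnosis_time(DiagnosisCategory.COVID19)
    covid_dx_near_admission = covid_dx_time is not None and (
        abs(covid_dx_time - record.admission_time) <= COVID_WINDOW
    )
    covid_13 = pcr_positive or covid_dx_near_admission

    if ards_1:
        timing = classify_diagnosis_timing_from_times(ards_code_time, algotime)
    else:
        timing = "none"

    return LabelSet(
        ards_1=ards_1,
        ards_2=ards_2,
        ards_3=ards_3,
        ards_4=ards_4,
        ards_5=ards_5,
        sepsis_6=sepsis_6,
        sepsis_7=sepsis_7,
        hypox_8=hypox_8,
        hypox_9=hypox_9,
        hypox_10=hypox_10,
        hypox_11=hypox_11,
        death_12=death_12,
        covid_13=covid_13,
        diagnosis_timing=timing,
    )


def classify_diagnosis_timing_from_times(
    ards_code_time: datetime | None, algotime: datetime
) -> str:
    if ards_code_time is None:
        raise DataIntegrityError("ARDS label set without an ARDS diagnosis event")
    # a code entered exactly at algotime cannot have preceded the prediction
    return "early" if ards_code_time < algotime else "late"


def classify_diagnosis_timing(record: PatientRecord, algotime: datetime) -> str:
    """Early/late/none timing of the clinical ARDS diagnosis vs prediction."""
    labels = derive_labels(record, algotime)
    return labels.diagnosis_timing
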