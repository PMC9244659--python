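"""Label rules: worked examples, implications, invariances, timing."""

from __future__ import annotations

import random
from datetime import timedelta

import numpy as np
import pytest

from ardsmtl.outcome_labels import (
    LABEL_NAMES,
    DataIntegrityError,
    classify_diagnosis_timing_from_times,
    derive_labels,
    max_sirs_over_stay,
)
from ardsmtl.preprocessing import determine_algotime
from ardsmtl.records import DiagnosisCategory
from conftest import ADMIT, REQUIRED_PANEL, make_record

ALGOTIME = ADMIT + timedelta(minutes=50)


def _labels(record):
    return derive_labels(record, ALGOTIME)


def test_ards_code_with_deep_desaturation_sets_all_ards_labels():
    record = make_record(
        REQUIRED_PANEL + [("spo2", 89.0, 200.0)],
        diagnoses=[(DiagnosisCategory.ARDS, 50.0)],
    )
    ls = _labels(record)
    assert (ls.ards_1, ls.ards_2, ls.ards_3, ls.ards_4, ls.ards_5) == (
        True,
        True,
        True,
        True,
        True,
    )


def test_prior_heart_failure_clears_only_hf_conditioned_variants():
    record = make_record(
        REQUIRED_PANEL + [("spo2", 89.0, 200.0)],
        diagnoses=[
            (DiagnosisCategory.ARDS, 50.0),
            (DiagnosisCategory.HEART_FAILURE, 10.0),
        ],
    )
    ls = _labels(record)
    assert (ls.ards_1, ls.ards_2, ls.ards_5) == (True, True, True)
    assert (ls.ards_3, ls.ards_4) == (False, False)


def test_heart_failure_after_ards_code_does_not_count_as_prior():
    record = make_record(
        REQUIRED_PANEL + [("spo2", 89.0, 200.0)],
        diagnoses=[
            (DiagnosisCategory.ARDS, 50.0),
            (DiagnosisCategory.HEART_FAILURE, 60.0),
        ],
    )
    ls = _labels(record)
    assert ls.ards_3 and ls.ards_4


def test_hypoxemia_only_before_algotime():
    """A dip to 88% before the prediction time sets the any-time labels but
    not the after-prediction ones; a brute-force scan agrees."""
    rows = REQUIRED_PANEL + [("spo2", 88.0, 20.0), ("spo2", 97.5, 120.0)]
    record = make_record(rows)
    ls = _labels(record)
    assert (ls.hypox_8, ls.hypox_9) == (True, True)
    assert (ls.hypox_10, ls.hypox_11) == (False, False)
    assert not any([ls.ards_1, ls.ards_2, ls.ards_3, ls.ards_4, ls.ards_5])
    # brute-force oracle over the raw series and both thresholds
    spo2 = [(m, v) for f, v, m in rows if f == "spo2"]
    after = [v for m, v in spo2 if m > 50.0]
    assert ls.hypox_8 == any(v < 91 for _, v in spo2)
    assert ls.hypox_10 == any(v < 91 for v in after)


def test_no_spo2_measurements_yield_false_hypoxemia():
    rows = [r for r in REQUIRED_PANEL if r[0] != "spo2"]
    ls = derive_labels(make_record(rows), ADMIT + timedelta(hours=8))
    assert not (ls.hypox_8 or ls.hypox_9 or ls.hypox_10 or ls.hypox_11)


def test_sepsis_requires_sirs_above_two():
    quiet = make_record(
        REQUIRED_PANEL, diagnoses=[(DiagnosisCategory.SEPSIS_OR_SEPTIC_SHOCK, 5.0)]
    )
    ls = _labels(quiet)
    assert ls.sepsis_7 and not ls.sepsis_6
    florid = make_record(
        REQUIRED_PANEL
        + [
            ("heart_rate", 110.0, 240.0),
            ("respiratory_rate", 26.0, 240.0),
            ("temperature", 38.8, 240.0),
        ],
        diagnoses=[(DiagnosisCategory.SEPSIS_OR_SEPTIC_SHOCK, 5.0)],
    )
    assert max_sirs_over_stay(florid) == 3
    ls2 = _labels(florid)
    assert ls2.sepsis_6 and ls2.sepsis_7


def test_covid_label_from_pcr_or_admission_window_code():
    by_pcr = make_record(REQUIRED_PANEL, pcr=[(4.0, True)])
    assert _labels(by_pcr).covid_13
    negative = make_record(REQUIRED_PANEL, pcr=[(4.0, False)])
    assert not _labels(negative).covid_13
    by_code = make_record(
        REQUIRED_PANEL, diagnoses=[(DiagnosisCategory.COVID19, -6 * 24.0)]
    )
    assert _labels(by_code).covid_13
    too_old = make_record(
        REQUIRED_PANEL, diagnoses=[(DiagnosisCategory.COVID19, -8 * 24.0)]
    )
    assert not _labels(too_old).covid_13


def test_diagnosis_timing_straddles_algotime():
    near = ALGOTIME - timedelta(minutes=1)
    assert classify_diagnosis_timing_from_times(near, ALGOTIME) == "early"
    after = ALGOTIME + timedelta(minutes=1)
    assert classify_diagnosis_timing_from_times(after, ALGOTIME) == "late"
    # a code entered exactly at the prediction time cannot precede it
    assert classify_diagnosis_timing_from_times(ALGOTIME, ALGOTIME) == "late"
    with pytest.raises(DataIntegrityError):
        classify_diagnosis_timing_from_times(None, ALGOTIME)


def test_timing_none_without_strict_ards():
    ls = _labels(make_record(REQUIRED_PANEL))
    assert ls.diagnosis_timing == "none"


def test_implications_hold_on_synthetic_cohort(labeled_small_cohort):
    _, _, labels = labeled_small_cohort
    for ls in labels:
        ls.check_implications()
        if ls.ards_1:
            assert ls.diagnosis_timing in ("early", "late")


def test_labels_invariant_to_observation_shuffling(labeled_small_cohort):
    records, algotimes, labels = labeled_small_cohort
    rng = random.Random(0)
    for record, algotime, expected in zip(records[:40], algotimes[:40], labels[:40]):
        shuffled = rng.sample(record.observations, len(record.observations))
        clone = type(record)(
            patient_id=record.patient_id,
            age=record.age,
            sex=record.sex,
            admission_time=record.admission_time,
            discharge_time=record.discharge_time,
            died_in_hospital=record.died_in_hospital,
            covid_pcr_results=record.covid_pcr_results,
            observations=shuffled,
            diagnoses=record.diagnoses,
        )
        assert derive_labels(clone, algotime) == expected


def test_lowering_spo2_is_monotone_for_hypoxemia_and_ards(labeled_small_cohort):
    """Lowering every SpO2 value can only flip the SpO2-conditioned labels
    from False to True, never the reverse."""
    records, algotimes, labels = labeled_small_cohort
    affected = ["ards_1", "ards_2", "ards_3", "ards_4",
                "hypox_8", "hypox_9", "hypox_10", "hypox_11"]
    for record, algotime, before in zip(records[:40], algotimes[:40], labels[:40]):
        lowered = [
            o._replace(value=o.value - 5.0) if o.feature_name == "spo2" else o
            for o in record.observations
        ]
        clone = type(record)(
            patient_id=record.patient_id,
            age=record.age,
            sex=record.sex,
            admission_time=record.admission_time,
            discharge_time=record.discharge_time,
            died_in_hospital=record.died_in_hospital,
            covid_pcr_results=record.covid_pcr_results,
            observations=lowered,
            diagnoses=record.diagnoses,
        )
        after = derive_labels(clone, algotime)
        for name in affected:
            assert getattr(before, name) <= getattr(after, name), name
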