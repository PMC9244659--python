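"""Feature-matrix construction: ordering, SIRS, algotime, binning, masks."""

from __future__ import annotations

from datetime import timedelta

import numpy as np
import pytest

from ardsmtl.features import (
    N_ROWS,
    N_TIMESTEPS,
    ROW_MASK_START,
    ROW_VALUE_START,
    TIME_VARYING,
    normalize_value,
)
from ardsmtl.preprocessing import (
    AlgotimeSource,
    NoObservationsError,
    RecordExcluded,
    build_feature_tensor,
    chronologize,
    compute_sirs,
    determine_algotime,
)
from conftest import ADMIT, REQUIRED_PANEL, make_record

SPO2_ROW = ROW_VALUE_START + TIME_VARYING.index("spo2")
SPO2_MASK = ROW_MASK_START + TIME_VARYING.index("spo2")
HR_ROW = ROW_VALUE_START + TIME_VARYING.index("heart_rate")
HR_MASK = ROW_MASK_START + TIME_VARYING.index("heart_rate")


# --- chronologize ----------------------------------------------------------


def test_chronologize_sorts_two_events():
    record = make_record([("heart_rate", 80.0, 10.0), ("heart_rate", 90.0, 5.0)])
    series, start = chronologize(record)
    np.testing.assert_array_equal(series["heart_rate"].values, [90.0, 80.0])
    assert start == ADMIT + timedelta(minutes=5)


def test_chronologize_empty_record_flags_no_data():
    series, start = chronologize(make_record([]))
    assert series == {} and start is None


def test_chronologize_matches_filter_and_sort_oracle():
    """Feature streams mix arbitrarily; per-feature arrays must match a
    brute-force filter-then-sort and conserve the event count."""
    rng = np.random.default_rng(0)
    feats = ["heart_rate", "spo2", "wbc", "lactate"]
    for _ in range(100):
        rows = [
            (feats[rng.integers(len(feats))], float(rng.uniform(1, 99)),
             float(rng.integers(0, 600)))
            for _ in range(rng.integers(1, 30))
        ]
        record = make_record(rows, los_hours=12.0)
        series, _ = chronologize(record)
        total = 0
        for f in feats:
            expected = sorted(
                [(m, v) for name, v, m in rows if name == f], key=lambda t: t[0]
            )
            got = series.get(f)
            n = 0 if got is None else len(got.values)
            assert n == len(expected)
            total += n
            if expected:
                # equal timestamps: order within the tie is irrelevant, compare sorted
                np.testing.assert_allclose(
                    np.sort(got.values), np.sort([v for _, v in expected])
                )
                assert list(got.times) == sorted(got.times)
        assert total == len(rows)


# --- SIRS -------------------------------------------------------------------


@pytest.mark.parametrize(
    "hr,rr,temp,wbc,expected",
    [
        (95.0, 22.0, 38.5, 13.0, 4),  # all four criteria met
        (70.0, 14.0, 37.0, 7.0, 0),  # all normal
        (None, None, None, None, 0),  # vacuous
        (91.0, None, 35.9, 3.9, 3),  # low-side temperature and WBC count
        (90.0, 20.0, 38.0, 12.0, 0),  # thresholds are strict inequalities
    ],
)
def test_sirs_consensus_criteria(hr, rr, temp, wbc, expected):
    assert compute_sirs(hr, rr, temp, wbc) == expected


# --- normalization ----------------------------------------------------------


def test_normalize_center_and_bounds(norm_table):
    rng = norm_table["heart_rate"]
    assert normalize_value("heart_rate", rng.mean, norm_table) == 0.0
    assert normalize_value("heart_rate", rng.high, norm_table) == pytest.approx(1.0)
    assert normalize_value("heart_rate", rng.low, norm_table) == pytest.approx(-1.0)


def test_normalize_missing_maps_to_zero(norm_table):
    assert normalize_value("spo2", None, norm_table) == 0.0
    assert normalize_value("spo2", float("nan"), norm_table) == 0.0


def test_normalize_unknown_feature_raises(norm_table):
    from ardsmtl.features import UnknownFeatureError

    with pytest.raises(UnknownFeatureError):
        normalize_value("not_a_feature", 1.0, norm_table)


# --- algotime -----------------------------------------------------------------


def test_algotime_is_40min_after_required_complete():
    rows = list(REQUIRED_PANEL)
    # move the last required feature to 100 minutes after admission
    rows[-1] = ("neutrophils", 55.0, 100.0)
    record = make_record(rows)
    result = determine_algotime(record, split="train_val")
    assert result.source == AlgotimeSource.REQUIRED_FEATURES_RULE
    assert result.algotime == ADMIT + timedelta(minutes=140)


def test_algotime_defaults_to_8h_in_training():
    rows = [r for r in REQUIRED_PANEL if r[0] != "creatinine"]
    result = determine_algotime(make_record(rows), split="train_val")
    assert result.source == AlgotimeSource.DEFAULT_8H
    assert result.algotime == ADMIT + timedelta(hours=8)


def test_test_split_excludes_incomplete_records():
    rows = [r for r in REQUIRED_PANEL if r[0] != "creatinine"]
    with pytest.raises(RecordExcluded):
        determine_algotime(make_record(rows), split="test")


# --- tensor construction -------------------------------------------------------


def _tensor(rows, algotime_min=None, **kwargs):
    record = make_record(rows, **kwargs)
    if algotime_min is None:
        algotime = determine_algotime(record, split="train_val").algotime
    else:
        algotime = ADMIT + timedelta(minutes=algotime_min)
    return build_feature_tensor(record, algotime), record, algotime


def test_tensor_shape_and_left_padding():
    """10 bins of history leave columns 0-53 all-zero."""
    ft, _, _ = _tensor(REQUIRED_PANEL, algotime_min=205.0)
    assert ft.values.shape == (N_ROWS, N_TIMESTEPS)
    assert np.all(ft.values[:, :54] == 0.0)  # padding columns, all rows
    assert ft.values[SPO2_MASK, 54] == 1.0  # start of care lands in column 54
    assert ft.values[SPO2_MASK, :].sum() == 1.0


def test_truncation_keeps_most_recent_64_bins(norm_table):
    """200 bins of history: only the latest 64 appear; the windowing must
    match a brute-force per-bin group-by oracle."""
    rows = [("heart_rate", 60.0 + (i % 40), 5.0 + 20.0 * i) for i in range(200)]
    rows += [(f, v, m) for f, v, m in REQUIRED_PANEL if f != "heart_rate"]
    algotime_min = 5.0 + 20.0 * 199 + 40.0
    ft, record, algotime = _tensor(rows, algotime_min=algotime_min)
    # oracle: explicit bin edges, take last value in each of the final 64 bins
    expected = np.zeros(N_TIMESTEPS)
    mask = np.zeros(N_TIMESTEPS)
    for b in range(N_TIMESTEPS):
        lo = algotime_min - (N_TIMESTEPS - b) * 20.0
        hi = algotime_min - (N_TIMESTEPS - 1 - b) * 20.0
        in_bin = [(m, v) for f, v, m in rows if f == "heart_rate" and lo < m <= hi]
        if in_bin:
            expected[b] = normalize_value(
                "heart_rate", max(in_bin)[1], norm_table
            )
            mask[b] = 1.0
    np.testing.assert_allclose(ft.values[HR_ROW], expected)
    np.testing.assert_array_equal(ft.values[HR_MASK], mask)
    assert mask.sum() > 0


def test_last_measurement_wins_within_bin():
    rows = list(REQUIRED_PANEL)
    rows += [("heart_rate", 100.0, 205.0), ("heart_rate", 120.0, 215.0)]
    ft, _, _ = _tensor(rows, algotime_min=220.0)
    assert ft.values[HR_ROW, -1] == pytest.approx(
        normalize_value("heart_rate", 120.0, _table())
    )


def _table():
    from ardsmtl.features import NormalRangeTable

    return NormalRangeTable.default()


def test_observations_after_algotime_are_invisible():
    rows = list(REQUIRED_PANEL) + [("spo2", 70.0, 300.0)]
    ft, _, _ = _tensor(rows, algotime_min=200.0)
    spo2_vals = ft.values[SPO2_ROW][ft.values[SPO2_MASK] == 1.0]
    assert normalize_value("spo2", 70.0, _table()) not in spo2_vals


def test_mask_value_consistency(small_cohort):
    """Nonzero time-varying values imply mask 1 on generated encounters."""
    records, _ = small_cohort
    for record in records[:80]:
        at = determine_algotime(record, split="train_val")
        ft = build_feature_tensor(record, at.algotime)
        values = ft.values[ROW_VALUE_START : ROW_VALUE_START + 24, :]
        masks = ft.values[ROW_MASK_START : ROW_MASK_START + 24, :]
        assert set(np.unique(masks)) <= {0.0, 1.0}
        assert np.all(values[masks == 0.0] == 0.0)


def test_tensor_build_is_idempotent(small_cohort):
    records, _ = small_cohort
    record = records[0]
    at = determine_algotime(record, split="train_val")
    a = build_feature_tensor(record, at.algotime)
    b = build_feature_tensor(record, at.algotime)
    np.testing.assert_array_equal(a.values, b.values)


def test_sirs_row_recomputed_per_bin():
    """SIRS row forward-fills components and re-scores every bin."""
    rows = list(REQUIRED_PANEL)  # normal vitals at 10 min -> SIRS 0
    rows += [("heart_rate", 120.0, 50.0), ("respiratory_rate", 28.0, 70.0)]
    ft, _, _ = _tensor(rows, algotime_min=90.0)
    sirs_row = ROW_VALUE_START + TIME_VARYING.index("sirs")
    sirs_mask = ROW_MASK_START + TIME_VARYING.index("sirs")
    table = _table()
    # bins: 20-min wide ending at 90 -> bin 63 covers (70, 90], bin 61 (30, 50]
    assert ft.values[sirs_mask, 63] == 1.0
    assert ft.values[sirs_row, 63] == pytest.approx(
        normalize_value("sirs", 2.0, table)
    )  # HR>90 and RR>20 both active
    assert ft.values[sirs_row, 61] == pytest.approx(
        normalize_value("sirs", 1.0, table)
    )  # only the tachycardia criterion yet


def test_algotime_before_start_of_care_rejected():
    record = make_record(REQUIRED_PANEL)
    with pytest.raises(ValueError):
        build_feature_tensor(record, ADMIT + timedelta(minutes=5))


def test_empty_record_raises_no_observations():
    record = make_record([])
    with pytest.raises(NoObservationsError):
        build_feature_tensor(record, ADMIT + timedelta(hours=8))
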