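"""From raw encounter records to the fixed 51 x 64 model input matrix.

The pipeline per encounter is:

1. chronologize the unordered observation stream into per-feature arrays;
2. determine the single prediction time ("algotime"): 40 minutes after the
   first moment every required feature has been measured at least once,
   falling back to 8 hours after admission in training data and to outright
   exclusion in test data;
3. bin the history into 64 consecutive 20-minute intervals whose right edge
   is the algotime, last-measurement-wins within a bin, recompute the SIRS
   score per bin from forward-filled components, normalize against the
   clinical normal ranges, zero-fill with availability masks, and left-pad
   or truncate to exactly 64 columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from enum import Enum

import numpy as np

from .features import (
    BIN_MINUTES,
    N_ROWS,
    N_TIME_VARYING,
    N_TIMESTEPS,
    REQUIRED_TIME_VARYING,
    ROW_AGE,
    ROW_FEMALE,
    ROW_MALE,
    ROW_MASK_START,
    ROW_VALUE_START,
    TIME_VARYING,
    NormalRangeTable,
    normalize_age,
    normalize_value,
)
from .records import PatientRecord

ALGOTIME_OFFSET = timedelta(minutes=2 * BIN_MINUTES)  # two timesteps
DEFAULT_ALGOTIME_OFFSET = timedelta(hours=8)

_SIRS_ROW = TIME_VARYING.index("sirs")  # relative index among time-varying rows


class AlgotimeSource(str, Enum):
    REQUIRED_FEATURES_RULE = "required-features-rule"
    DEFAULT_8H = "default-8h"


@dataclass(frozen=True)
class AlgotimeResult:
    algotime: datetime
    source: AlgotimeSource


class RecordExcluded(Exception):
    """Test-split record lacking a required feature; excluded, not defaulted."""


class NoObservationsError(ValueError):
    """Record carries no vital-sign or laboratory observations."""


@dataclass(frozen=True)
class FeatureSeries:
    """Chronologically ordered measurements of one feature."""

    values: np.ndarray  # float
    units: np.ndarray  # str
    times: np.ndarray  # datetime64[s]


@dataclass
class FeatureTensor:
    """The 51 x 64 normalized input matrix with availability masks."""

    values: np.ndarray  # (51, 64) float
    algotime: datetime
    patient_id: str

    def __post_init__(self) -> None:
        if self.values.shape != (N_ROWS, N_TIMESTEPS):
            raise ValueError(f"feature tensor must be {N_ROWS}x{N_TIMESTEPS}")

    @property
    def masks(self) -> np.ndarray:
        return self.values[ROW_MASK_START:, :]


def chronologize(record: PatientRecord) -> tuple[dict[str, FeatureSeries], datetime | None]:
    """Sort the observation stream into per-feature (values, units, times).

    Returns the mapping and the start of care — the earliest vital-sign or
    laboratory timestamp, ``None`` when the record has no observations.
    """
    buckets: dict[str, list] = {}
    for obs in record.observations:
        buckets.setdefault(obs.feature_name, []).append(obs)
    series: dict[str, FeatureSeries] = {}
    start_of_care: datetime | None = None
    for feature, events in buckets.items():
        events.sort(key=lambda o: o.timestamp)
        series[feature] = FeatureSeries(
            values=np.array([e.value for e in events], dtype=float),
            units=np.array([e.unit for e in events], dtype=object),
            times=np.array([np.datetime64(e.timestamp, "s") for e in events]),
        )
        first = events[0].timestamp
        if start_of_care is None or first < start_of_care:
            start_of_care = first
    return series, start_of_care


def compute_sirs(
    heart_rate: float | None,
    respiratory_rate: float | None,
    temperature: float | None,
    wbc: float | None,
) -> int:
    """SIRS score 0-4 from the most recent component values.

    Consensus criteria: temperature >38 or <36 degC; heart rate >90/min;
    respiratory rate >20/min; WBC >12 or <4 x10^9/L. A missing component
    contributes nothing. (The PaCO2 and immature-band alternatives are not
    inputs here and are omitted.)
    """
    score = 0
    if temperature is not None and (temperature > 38.0 or temperature < 36.0):
        score += 1
    if heart_rate is not None and heart_rate > 90.0:
        score += 1
    if respiratory_rate is not None and respiratory_rate > 20.0:
        score += 1
    if wbc is not None and (wbc > 12.0 or wbc < 4.0):
        score += 1
    return score


def determine_algotime(
    record: PatientRecord,
    required_features: list[str] | None = None,
    split: str = "train_val",
) -> AlgotimeResult:
    """Single prediction time for the encounter.

    If every required feature has at least one measurement, algotime is the
    first time they are all available plus 40 minutes. Otherwise training and
    validation records default to admission + 8 h, while test records raise
    :class:`RecordExcluded` (the held-out evaluation only admits complete
    encounters).
    """
    if split not in ("train_val", "test"):
        raise ValueError(f"split must be train_val or test, got {split!r}")
    required = (
        list(required_features) if required_features is not None else list(REQUIRED_TIME_VARYING)
    )
    series, _ = chronologize(record)
    first_times = []
    missing = False
    for feature in required:
        if feature in series and len(series[feature].values) > 0:
            first_times.append(series[feature].times[0])
        else:
            missing = True
            break
    if not missing and first_times:
        complete_at = max(first_times).astype("datetime64[s]").item()
        return AlgotimeResult(complete_at + ALGOTIME_OFFSET, AlgotimeSource.REQUIRED_FEATURES_RULE)
    if split == "test":
        raise RecordExcluded(record.patient_id)
    return AlgotimeResult(
        record.admission_time + DEFAULT_ALGOTIME_OFFSET, AlgotimeSource.DEFAULT_8H
    )


def build_feature_tensor(
    record: PatientRecord,
    algotime: datetime,
    table: NormalRangeTable | None = None,
) -> FeatureTensor:
    """Build the 51 x 64 normalized, masked input matrix for one encounter.

    Columns are the 64 consecutive 20-minute bins whose right edge is the
    algotime; the last measurement within a bin wins; SIRS is recomputed per
    bin from forward-filled components; history shorter than 64 bins is
    left-padded with zeros (mask 0), longer history is truncated to the most
    recent 64 bins.
    """
    if table is None:
        table = _DEFAULT_TABLE
    series, start_of_care = chronologize(record)
    if start_of_care is None:
        raise NoObservationsError(record.patient_id)
    if algotime < start_of_care:
        raise ValueError("algotime precedes start of care")

    algotime64 = np.datetime64(algotime, "s")
    out = np.zeros((N_ROWS, N_TIMESTEPS), dtype=float)
    out[ROW_AGE, :] = normalize_age(record.age)
    out[ROW_MALE, :] = 1.0 if record.sex == "male" else 0.0
    out[ROW_FEMALE, :] = 1.0 if record.sex == "female" else 0.0

    bin_s = BIN_MINUTES * 60.0
    window_start = algotime64 - np.timedelta64(int(N_TIMESTEPS * bin_s), "s")

    # last observed value per (feature, bin) for the raw time-varying features
    per_bin_value: dict[str, dict[int, float]] = {}
    for feature, fs in series.items():
        if feature not in TIME_VARYING:
            continue
        delta_s = (algotime64 - fs.times.astype("datetime64[s]")) / np.timedelta64(1, "s")
        per_bin: dict[int, float] = {}
        for t_s, v in zip(delta_s, fs.values):
            if t_s < 0:
                continue  # after algotime: never visible to the model
            # right-closed bins counted back from the right edge at algotime
            b = N_TIMESTEPS - 1 - int(t_s // bin_s)
            if b < 0:
                continue  # older than the 64-bin window
            per_bin[b] = float(v)  # inputs are time-sorted: last write wins
        per_bin_value[feature] = per_bin

    # fill value + mask rows
    for j, feature in enumerate(TIME_VARYING):
        if feature == "sirs":
            continue
        per_bin = per_bin_value.get(feature, {})
        for b, raw in per_bin.items():
            out[ROW_VALUE_START + j, b] = normalize_value(feature, raw, table)
            out[ROW_MASK_START + j, b] = 1.0

    # SIRS per bin from forward-filled most recent component values
    comp = {"heart_rate": None, "respiratory_rate": None, "temperature": None, "wbc": None}
    comp_events: list[tuple[np.datetime64, str, float]] = []
    for feature in comp:
        fs = series.get(feature)
        if fs is None:
            continue
        for t, v in zip(fs.times, fs.values):
            comp_events.append((t.astype("datetime64[s]"), feature, float(v)))
    comp_events.sort(key=lambda e: e[0])
    idx = 0
    any_component_seen = False
    for b in range(N_TIMESTEPS):
        bin_end = algotime64 - np.timedelta64(int((N_TIMESTEPS - 1 - b) * bin_s), "s")
        while idx < len(comp_events) and comp_events[idx][0] <= bin_end:
            _, feature, v = comp_events[idx]
            comp[feature] = v
            any_component_seen = True
            idx += 1
        if any_component_seen:
            score = compute_sirs(
                comp["heart_rate"], comp["respiratory_rate"], comp["temperature"], comp["wbc"]
            )
            out[ROW_VALUE_START + _SIRS_ROW, b] = normalize_value("sirs", float(score), table)
            out[ROW_MASK_START + _SIRS_ROW, b] = 1.0

    # left padding: bins that end before the start of care are all-zero
    soc64 = np.datetime64(start_of_care, "s")
    for b in range(N_TIMESTEPS):
        bin_end = algotime64 - np.timedelta64(int((N_TIMESTEPS - 1 - b) * bin_s), "s")
        if bin_end < soc64:
            out[:, b] = 0.0
        else:
            break

    return FeatureTensor(values=out, algotime=algotime, patient_id=record.patient_id)


_DEFAULT_TABLE = NormalRangeTable.default()


def tensors_for_cohort(
    records: list[PatientRecord],
    split: str = "train_val",
    table: NormalRangeTable | None = None,
) -> tuple[np.ndarray, list[str], list[AlgotimeResult], list[str]]:
    """Vectorize a cohort: stacked (n, 51, 64) array plus bookkeeping.

    Returns (tensor stack, kept patient ids, algotime results, excluded ids).
    Test-split records lacking required features are excluded; records with
    no observations at all are likewise excluded and reported.
    """
    stack, kept, results, excluded = [], [], [], []
    for record in records:
        try:
            at = determine_algotime(record, split=split)
            ft = build_feature_tensor(record, at.algotime, table=table)
        except (RecordExcluded, NoObservationsError):
            excluded.append(record.patient_id)
            continue
        stack.append(ft.values)
        kept.append(record.patient_id)
        results.append(at)
    arr = np.stack(stack) if stack else np.zeros((0, N_ROWS, N_TIMESTEPS))
    return arr, kept, results, excluded
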