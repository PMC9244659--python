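"""Input-feature registry and normal-range normalization table.

The models consume a fixed matrix layout: one row of normalized age, two
binary sex-indicator rows, 24 time-varying rows (7 vital signs, 16 laboratory
values and the computed SIRS score) and, appended below, one availability-mask
row per time-varying feature — 51 rows in total over 64 twenty-minute
timesteps.

Normalization of the time-varying rows is deliberately coarse: the center of
the clinical normal range approximates the mean and half the range width
approximates the SD, so normalized values read as z-scores against the
healthy reference rather than against the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import yaml

#: Time-varying vital signs, in row order.
VITALS = [
    "systolic_bp",
    "diastolic_bp",
    "heart_rate",
    "pao2",
    "respiratory_rate",
    "spo2",
    "temperature",
]

#: Time-varying laboratory features, in row order.
LABS = [
    "glucose",
    "bilirubin",
    "wbc",
    "rbc",
    "lymphocytes",
    "alt",
    "inr",
    "ph",
    "bun",
    "creatinine",
    "platelets",
    "neutrophils",
    "monocytes",
    "hematocrit",
    "lactate",
    "ast",
]

#: All 24 time-varying rows; SIRS is computed downstream, never observed raw.
TIME_VARYING = VITALS + LABS + ["sirs"]

#: Features whose first availability determines the prediction time
#: (age and sex are demographic and always known at admission).
REQUIRED_TIME_VARYING = [
    "systolic_bp",
    "diastolic_bp",
    "heart_rate",
    "respiratory_rate",
    "spo2",
    "temperature",
    "wbc",
    "lymphocytes",
    "creatinine",
    "neutrophils",
]

N_TIME_VARYING = len(TIME_VARYING)  # 24
N_ROWS = 3 + 2 * N_TIME_VARYING  # 51
N_TIMESTEPS = 64
BIN_MINUTES = 20

#: Row indices within the feature tensor.
ROW_AGE = 0
ROW_MALE = 1
ROW_FEMALE = 2
ROW_VALUE_START = 3  # rows 3..26: time-varying values
ROW_MASK_START = 3 + N_TIME_VARYING  # rows 27..50: availability masks

#: Demographic normalization constants (no laboratory normal range exists).
AGE_MEAN = 50.0
AGE_SD = 20.0


@dataclass(frozen=True)
class NormalRange:
    """Clinical normal range of one feature with derived moments."""

    low: float
    high: float
    unit: str

    @property
    def mean(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def sd(self) -> float:
        return 0.5 * (self.high - self.low)


class UnknownFeatureError(KeyError):
    """Raised when a feature is absent from the normal-range table."""


class NormalRangeTable:
    """Normal ranges for every time-varying feature.

    Loaded from the versioned ``data/normal_ranges.yaml`` shipped with the
    package; every feature in :data:`TIME_VARYING` must have an entry with
    ``low < high``.
    """

    def __init__(self, ranges: Mapping[str, NormalRange]):
        for name in TIME_VARYING:
            if name not in ranges:
                raise ValueError(f"normal-range table lacks feature {name!r}")
        for name, rng in ranges.items():
            if not rng.low < rng.high:
                raise ValueError(f"normal range for {name!r} has low >= high")
        self._ranges = dict(ranges)

    def __getitem__(self, feature: str) -> NormalRange:
        try:
            return self._ranges[feature]
        except KeyError:
            raise UnknownFeatureError(feature) from None

    def __contains__(self, feature: str) -> bool:
        return feature in self._ranges

    def features(self) -> list[str]:
        return list(self._ranges)

    @classmethod
    def default(cls) -> "NormalRangeTable":
        text = (
            resources.files("ardsmtl").joinpath("data/normal_ranges.yaml").read_text()
        )
        raw = yaml.safe_load(text)
        return cls(
            {
                name: NormalRange(float(v["low"]), float(v["high"]), str(v["unit"]))
                for name, v in raw.items()
            }
        )


def normalize_value(feature: str, raw_value: float | None, table: NormalRangeTable) -> float:
    """Normalize one raw measurement against its clinical normal range.

    Returns ``(raw - mean) / sd``; a missing value (``None`` or NaN) maps to
    0.0 — the caller is responsible for clearing the paired availability mask.
    """
    rng = table[feature]
    if raw_value is None or (isinstance(raw_value, float) and math.isnan(raw_value)):
        return 0.0
    return (float(raw_value) - rng.mean) / rng.sd


def normalize_age(age_years: float) -> float:
    return (float(age_years) - AGE_MEAN) / AGE_SD


_CANONICAL_UNITS: dict[str, str] | None = None


def canonical_unit(feature: str) -> str:
    """Documented canonical unit string for a time-varying feature."""
    global _CANONICAL_UNITS
    if _CANONICAL_UNITS is None:
        table = NormalRangeTable.default()
        _CANONICAL_UNITS = {name: table[name].unit for name in table.features()}
    return _CANONICAL_UNITS[feature]
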