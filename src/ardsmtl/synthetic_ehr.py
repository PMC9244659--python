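"""Synthetic EHR cohort generator.

Real hospital feeds of this shape are private, so every downstream stage is
exercised on simulated encounters that reproduce the statistical structure
the analysis assumes:

* one scalar latent severity per patient (standard Gaussian, clipped to
  ±4) that simultaneously raises the probability of ARDS coding, sepsis,
  death and COVID-19 and deepens the hypoxemic nadir — the shared process
  that makes multitask learning worthwhile;
* irregularly sampled vitals and labs with feature-specific observation
  rates, so availability masks carry signal;
* outcome prevalences calibrated to the reference prevalence column of the
  source cohort (ARDS-with-code 5.5%, sepsis code 2.3%, death 2.6%,
  COVID-19 23.8%, hypoxemia below 96% 79.9%, ...);
* ARDS diagnosis-entry delays with mean around 139 h and a minority of
  immediate entries, so both early- and late-diagnosis groups are populated.

Generation is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
from scipy.optimize import brentq

from .features import (
    LABS,
    REQUIRED_TIME_VARYING,
    VITALS,
    NormalRangeTable,
    canonical_unit,
)
from .records import (
    DiagnosisCategory,
    DiagnosisEvent,
    ObservationEvent,
    PatientRecord,
    PcrResult,
)

SEVERITY_MIN = -4.0
SEVERITY_MAX = 4.0

#: Reference outcome prevalences (fraction of encounters), used as the
#: default calibration targets for the generator.
DEFAULT_PREVALENCE_TARGETS: dict[str, float] = {
    "ards_1": 0.046,
    "ards_2": 0.054,
    "ards_3": 0.044,
    "ards_4": 0.051,
    "ards_5": 0.055,
    "sepsis_6": 0.023,
    "sepsis_7": 0.023,
    "hypox_8": 0.268,
    "hypox_9": 0.799,
    "hypox_10": 0.182,
    "hypox_11": 0.38,
    "death_12": 0.026,
    "covid_13": 0.238,
}

#: Per-20-minute-bin probability that a feature is observed.
DEFAULT_MISSINGNESS_RATES: dict[str, float] = {
    **{v: 0.06 for v in VITALS},
    "spo2": 0.08,
    "pao2": 0.004,
    **{lab: 0.006 for lab in LABS},
}

#: Loading of each primary event channel on the latent severity (logit slope).
DEFAULT_LATENT_COUPLING: dict[str, float] = {
    "ards_5": 1.4,
    "sepsis_7": 1.3,
    "death_12": 1.5,
    "covid_13": 0.35,
}

#: Severity loading of each observed feature, in normal-range SD units.
FEATURE_LOADINGS: dict[str, float] = {
    "systolic_bp": -0.5,
    "diastolic_bp": -0.4,
    "heart_rate": 0.8,
    "pao2": -0.8,
    "respiratory_rate": 0.9,
    "temperature": 0.4,
    "glucose": 0.3,
    "bilirubin": 0.3,
    "wbc": 0.7,
    "rbc": -0.2,
    "lymphocytes": -0.7,
    "alt": 0.3,
    "inr": 0.3,
    "ph": -0.5,
    "bun": 0.5,
    "creatinine": 0.6,
    "platelets": -0.4,
    "neutrophils": 0.7,
    "monocytes": 0.0,
    "hematocrit": -0.2,
    "lactate": 0.9,
    "ast": 0.3,
}

OBS_NOISE_SD = 1.3  # per-observation noise, in normal-range SD units

# --- hypoxemia nadir model (calibrated once against the default targets) ---
# nadir = NADIR_BASE - NADIR_SLOPE * severity + NADIR_JITTER * U(-1, 1); at
# the maximum severity of +4 the nadir is below 91% for every jitter draw.
NADIR_BASE = 93.3
NADIR_SLOPE = 3.38
NADIR_JITTER = 1.2
# ARDS-coded patients additionally draw a deeper nadir channel in most
# cases (a minority are coded without a charted desaturation).
ARDS_NADIR_BASE = 91.0
ARDS_NADIR_SLOPE = 1.2
ARDS_NADIR_JITTER = 1.5
ARDS_DIP_PROB = 0.80
SPO2_DIP_WIDTH_H = 2.5
SPO2_BASE = 97.6
SPO2_BASE_SEVERITY_DROP = 0.6
SPO2_OBS_NOISE = 0.4
# Desaturation timing depends on depth: mild dips cluster at presentation
# (triage hypoxemia that resolves), deep dips occur later in the stay.
EARLY_DIP_PROB_MILD = 0.76
EARLY_DIP_PROB_DEEP = 0.25

# --- diagnosis timing ---
ARDS_DELAY_EARLY_PROB = 0.20  # code entered almost immediately
ARDS_DELAY_EARLY_MEAN_H = 3.0
ARDS_DELAY_GAMMA_SHAPE = 2.0
ARDS_DELAY_GAMMA_SCALE_H = 85.0  # mixture mean ~ 139 h
HEART_FAILURE_PROB = 0.10
HEART_FAILURE_COUPLING = 0.2
OTHER_DX_PROB = 0.30

# --- supporting event probabilities ---
SIRS_EPISODE_PROB = 0.97  # septic patients with a florid SIRS episode
PCR_TESTED_PROB = 0.70
COVID_DX_PROB = 0.80
DIFFERENTIAL_MISSING_PROB = 0.03  # stays with no CBC differential at all
DIFFERENTIAL_DELAY_SHAPE = 2.0
DIFFERENTIAL_DELAY_SCALE_H = 6.0  # first differential ~12 h after admission

# Mortality shift for ARDS patients by diagnosis-entry delay (late entry is
# a marker of a deteriorating course).
ARDS_LATE_DX_LOGIT = 0.45
ARDS_LATE_DX_CUTOFF_H = 12.0

_BASE_ADMISSION = datetime(2020, 1, 15, 0, 0)


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort.

    ``prevalence_targets`` calibrates the four primary event channels
    (ARDS code, sepsis code, in-hospital death, COVID-19); the compound
    labels (SpO2-conditioned ARDS variants, SIRS-conditioned sepsis, the
    hypoxemia family) emerge from the fixed conditional mechanics above,
    which were calibrated once against the default targets.
    """

    n_patients: int
    prevalence_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE_TARGETS)
    )
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS_RATES)
    )
    latent_coupling: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_COUPLING)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name, p in self.prevalence_targets.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence target {name}={p} outside [0, 1]")
        for name, p in self.missingness_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"observation rate {name}={p} outside [0, 1]")


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _event_prob(logit: float) -> float:
    """Sigmoid with the numerically negligible tail truncated to exactly 0.

    Keeps limit behavior clean: a patient at the minimum allowed severity has
    probability exactly zero for the severity-coupled events.
    """
    return 0.0 if logit < -7.0 else _sigmoid(logit)


def _solve_intercept(target: float, slope: float) -> float:
    """Intercept a with E[sigmoid(a + slope * z)] = target, z ~ clipped N(0,1)."""
    grid = np.linspace(SEVERITY_MIN, SEVERITY_MAX, 4001)
    w = np.exp(-0.5 * grid**2)
    w /= w.sum()

    def f(a: float) -> float:
        return float(np.sum(w / (1.0 + np.exp(-(a + slope * grid))))) - target

    if target <= 0.0:
        return -math.inf
    if target >= 1.0:
        return math.inf
    return brentq(f, -30.0, 30.0, xtol=1e-10)


def _event_intercepts(config: CohortConfig) -> dict[str, float]:
    out = {}
    for channel, slope in config.latent_coupling.items():
        target = config.prevalence_targets.get(
            channel, DEFAULT_PREVALENCE_TARGETS[channel]
        )
        if channel == "covid_13":
            # label = status AND (tested, or a diagnosis entry was made)
            observed = 1.0 - (1.0 - PCR_TESTED_PROB) * (1.0 - COVID_DX_PROB)
            target = min(1.0, target / observed)
        out[channel] = _solve_intercept(target, slope)
    return out


def _minutes(td_minutes: float) -> timedelta:
    return timedelta(minutes=float(round(td_minutes)))


def _clip_value(feature: str, value: float) -> float:
    rng = _RANGES[feature]
    lo = rng.mean - 3.5 * rng.sd
    hi = rng.mean + 8.0 * rng.sd
    if rng.low >= 0:
        lo = max(lo, 0.01)
    if feature == "spo2":
        lo, hi = 60.0, 100.0
    if feature == "ph":
        lo, hi = 6.8, 7.8
    return float(min(max(value, lo), hi))


_TABLE = NormalRangeTable.default()
_RANGES = {name: _TABLE[name] for name in _TABLE.features()}


def _spo2_at(t_h: np.ndarray, base: float, nadir: float, t_nadir_h: float) -> np.ndarray:
    dip = (base - nadir) * np.exp(-0.5 * ((t_h - t_nadir_h) / SPO2_DIP_WIDTH_H) ** 2)
    return base - dip


def generate_patient(
    latent_severity: float,
    config: CohortConfig,
    stream_seed: int,
    patient_id: str | None = None,
    intercepts: dict[str, float] | None = None,
) -> PatientRecord:
    """Generate one encounter at the given latent severity.

    Deterministic in ``(latent_severity, config, stream_seed)``.
    """
    if not math.isfinite(latent_severity):
        raise ValueError("latent_severity must be finite")
    config.validate()
    z = float(np.clip(latent_severity, SEVERITY_MIN, SEVERITY_MAX))
    if intercepts is None:
        intercepts = _event_intercepts(config)
    rng = np.random.default_rng(stream_seed)
    pid = patient_id if patient_id is not None else f"P{stream_seed:010d}"

    age = float(np.clip(rng.normal(58.0, 18.0), 18.0, 100.0))
    sex = "male" if rng.random() < 0.5 else "female"

    cpl = config.latent_coupling
    has_ards = rng.random() < _event_prob(intercepts["ards_5"] + cpl["ards_5"] * z)
    has_sepsis = rng.random() < _event_prob(intercepts["sepsis_7"] + cpl["sepsis_7"] * z)
    covid_status = rng.random() < _event_prob(intercepts["covid_13"] + cpl["covid_13"] * z)

    if has_ards:
        los_h = float(np.clip(rng.lognormal(math.log(300.0), 0.6), 48.0, 2159.0))
    else:
        los_h = float(np.clip(rng.lognormal(math.log(60.0), 0.9), 2.1, 2159.0))
    admission = _BASE_ADMISSION + timedelta(
        minutes=int(rng.integers(0, 365 * 24 * 60))
    )
    discharge = admission + _minutes(los_h * 60.0)

    diagnoses: list[DiagnosisEvent] = []
    ards_delay_h: float | None = None
    if has_ards:
        if rng.random() < ARDS_DELAY_EARLY_PROB:
            ards_delay_h = float(rng.exponential(ARDS_DELAY_EARLY_MEAN_H))
        else:
            ards_delay_h = float(
                rng.gamma(ARDS_DELAY_GAMMA_SHAPE, ARDS_DELAY_GAMMA_SCALE_H)
            )
        ards_delay_h = float(np.clip(ards_delay_h, 2.0 / 60.0, los_h - 1.0 / 60.0))
        diagnoses.append(
            DiagnosisEvent(DiagnosisCategory.ARDS, admission + _minutes(ards_delay_h * 60))
        )
    if rng.random() < _sigmoid(
        math.log(HEART_FAILURE_PROB / (1 - HEART_FAILURE_PROB))
        + HEART_FAILURE_COUPLING * z
    ):
        t_hf = rng.uniform(0.0, los_h)
        diagnoses.append(
            DiagnosisEvent(
                DiagnosisCategory.HEART_FAILURE, admission + _minutes(t_hf * 60)
            )
        )
    if has_sepsis:
        t_sep = rng.uniform(0.05, 0.8) * los_h
        diagnoses.append(
            DiagnosisEvent(
                DiagnosisCategory.SEPSIS_OR_SEPTIC_SHOCK,
                admission + _minutes(t_sep * 60),
            )
        )
    covid_dx = covid_status and rng.random() < COVID_DX_PROB
    if covid_dx:
        t_cov_h = rng.uniform(-6.0 * 24, 6.0 * 24)
        diagnoses.append(
            DiagnosisEvent(DiagnosisCategory.COVID19, admission + _minutes(t_cov_h * 60))
        )
    if rng.random() < OTHER_DX_PROB:
        diagnoses.append(
            DiagnosisEvent(
                DiagnosisCategory.OTHER,
                admission + _minutes(rng.uniform(0.0, los_h) * 60),
            )
        )

    death_logit = intercepts["death_12"] + cpl["death_12"] * z
    if has_ards and ards_delay_h is not None:
        # late code entry marks a deteriorating course; recentred so the
        # population death rate stays at its calibrated target
        shift = (
            ARDS_LATE_DX_LOGIT
            if ards_delay_h > ARDS_LATE_DX_CUTOFF_H
            else -ARDS_LATE_DX_LOGIT
        )
        death_logit += shift - ARDS_LATE_DX_LOGIT * (1.0 - 2.0 * ARDS_DELAY_EARLY_PROB)
    died = rng.random() < _event_prob(death_logit)

    pcr: list[PcrResult] = []
    if rng.random() < PCR_TESTED_PROB:
        t_pcr = rng.uniform(0.0, min(los_h, 48.0))
        pcr.append(PcrResult(admission + _minutes(t_pcr * 60), bool(covid_status)))

    # --- hypoxemia trajectory ---
    nadir = NADIR_BASE - NADIR_SLOPE * z + NADIR_JITTER * rng.uniform(-1.0, 1.0)
    if has_ards:
        deep = (
            ARDS_NADIR_BASE
            - ARDS_NADIR_SLOPE * max(z, 0.0)
            + ARDS_NADIR_JITTER * rng.uniform(-1.0, 1.0)
        )
        if rng.random() < ARDS_DIP_PROB:
            nadir = min(nadir, deep)
    spo2_base = SPO2_BASE - SPO2_BASE_SEVERITY_DROP * max(z, 0.0)
    nadir = min(nadir, spo2_base)
    early_dip_prob = EARLY_DIP_PROB_DEEP if nadir < 91.0 else EARLY_DIP_PROB_MILD
    if has_ards:
        t_nadir_h = rng.uniform(0.25, 0.85) * los_h
    elif rng.random() < early_dip_prob:
        t_nadir_h = rng.uniform(0.0, min(6.0, los_h))
    else:
        t_nadir_h = rng.uniform(0.1, 0.9) * los_h
    t_nadir_h = float(np.clip(t_nadir_h, 1.0 / 60.0, los_h - 1.0 / 60.0))

    observations: list[ObservationEvent] = []

    def emit(feature: str, value: float, t_h: float) -> None:
        t_h = float(np.clip(t_h, 0.0, los_h))
        observations.append(
            ObservationEvent(
                feature,
                _clip_value(feature, value),
                canonical_unit(feature),
                admission + _minutes(t_h * 60.0),
            )
        )

    def draw_value(feature: str) -> float:
        rng_f = _RANGES[feature]
        return (
            rng_f.mean
            + FEATURE_LOADINGS[feature] * z * rng_f.sd
            + OBS_NOISE_SD * rng_f.sd * rng.standard_normal()
        )

    # admission panel: triage vitals plus a basic lab draw within the first hour
    t_panel_h = rng.uniform(5.0, 45.0) / 60.0
    panel = [f for f in REQUIRED_TIME_VARYING if f not in ("lymphocytes", "neutrophils")]
    extras = [
        f
        for f in FEATURE_LOADINGS
        if f not in panel and f not in ("lymphocytes", "neutrophils", "spo2", "pao2")
    ]
    for feature in panel:
        if feature == "spo2":
            v = _spo2_at(np.array([t_panel_h]), spo2_base, nadir, t_nadir_h)[0]
            emit("spo2", v + SPO2_OBS_NOISE * rng.standard_normal(), t_panel_h)
        else:
            emit(feature, draw_value(feature), t_panel_h)
    for feature in extras:
        if rng.random() < 0.7:
            emit(feature, draw_value(feature), t_panel_h)

    # CBC differential arrives later than the basic panel (send-out timing)
    if rng.random() >= DIFFERENTIAL_MISSING_PROB:
        t_diff_h = float(
            rng.gamma(DIFFERENTIAL_DELAY_SHAPE, DIFFERENTIAL_DELAY_SCALE_H)
        )
        if t_diff_h < los_h:
            emit("lymphocytes", draw_value("lymphocytes"), t_diff_h)
            emit("neutrophils", draw_value("neutrophils"), t_diff_h)

    # recurring observations at feature-specific per-bin rates
    n_bins = max(1, int(math.ceil(los_h * 3.0)))
    for feature, rate in config.missingness_rates.items():
        n_obs = int(rng.poisson(rate * n_bins))
        if n_obs == 0:
            continue
        times_h = np.sort(rng.uniform(0.0, los_h, size=n_obs))
        if feature == "spo2":
            vals = _spo2_at(times_h, spo2_base, nadir, t_nadir_h)
            vals = vals + SPO2_OBS_NOISE * rng.standard_normal(n_obs)
            for t_h, v in zip(times_h, vals):
                emit("spo2", float(v), float(t_h))
        else:
            for t_h in times_h:
                emit(feature, draw_value(feature), float(t_h))
    # the nadir itself is always charted (critical desaturations get recorded)
    emit("spo2", float(nadir), t_nadir_h)

    # florid SIRS episode for septic patients: all four criteria at one time
    if has_sepsis and rng.random() < SIRS_EPISODE_PROB:
        t_s = rng.uniform(0.05, 0.8) * los_h
        emit("heart_rate", 95.0 + 25.0 * rng.random(), t_s)
        emit("respiratory_rate", 21.0 + 9.0 * rng.random(), t_s)
        emit("temperature", 38.1 + 1.2 * rng.random(), t_s)
        emit("wbc", 12.5 + 5.0 * rng.random(), t_s)

    observations.sort(key=lambda o: (o.timestamp, o.feature_name))
    diagnoses.sort(key=lambda d: (d.timestamp, d.category.value))

    record = PatientRecord(
        patient_id=pid,
        age=age,
        sex=sex,
        admission_time=admission,
        discharge_time=discharge,
        died_in_hospital=bool(died),
        covid_pcr_results=pcr,
        observations=observations,
        diagnoses=diagnoses,
    )
    record.validate()
    return record


def generate_cohort(
    config: CohortConfig, return_severity: bool = False
) -> list[PatientRecord] | tuple[list[PatientRecord], np.ndarray]:
    """Generate ``config.n_patients`` encounters; pure function of the config."""
    config.validate()
    master = np.random.default_rng(config.seed)
    n = config.n_patients
    severities = np.clip(master.standard_normal(n), SEVERITY_MIN, SEVERITY_MAX)
    stream_seeds = master.integers(0, 2**31 - 1, size=n)
    intercepts = _event_intercepts(config)
    records = [
        generate_patient(
            float(severities[i]),
            config,
            int(stream_seeds[i]),
            patient_id=f"P{i:06d}",
            intercepts=intercepts,
        )
        for i in range(n)
    ]
    if return_severity:
        return records, severities
    return records
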