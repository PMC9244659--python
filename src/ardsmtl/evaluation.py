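"""Discrimination metrics: AUROC, bootstrap CIs, operating points, reports.

AUROC is computed as the Mann-Whitney pairwise probability (ties counted as
one half), confidence intervals by the percentile bootstrap over patients,
and the sensitivity/specificity pair at the smallest threshold reaching a
target sensitivity (defaulting to 0.65, the convention of the reference
comparison tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_BOOTSTRAP_RESAMPLES = 1000
DEFAULT_TARGET_SENSITIVITY = 0.65


class UndefinedMetricError(ValueError):
    """Metric undefined because only one class is present."""


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via rank statistics.

    Equals the probability that a random positive outscores a random
    negative, counting ties as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("both classes required for AUROC")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bootstrap_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_resamples: int = DEFAULT_BOOTSTRAP_RESAMPLES,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% CI for the AUROC over patient resamples.

    Resamples that draw a single class are redrawn.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auroc(scores, labels)  # raises if undefined
    rng = np.random.default_rng(seed)
    n = scores.size
    stats = np.empty(n_resamples)
    for i in range(n_resamples):
        while True:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if 0 < lab.sum() < n:
                break
        stats[i] = auroc(scores[idx], lab)
    low, high = np.percentile(stats, [2.5, 97.5])
    return float(low), float(high)


def operating_point(
    scores: np.ndarray,
    labels: np.ndarray,
    target_sensitivity: float = DEFAULT_TARGET_SENSITIVITY,
) -> tuple[float, float, float]:
    """Smallest threshold whose sensitivity meets the target.

    Returns (threshold, sensitivity, specificity) with score >= threshold
    called positive. An unreachable target degrades to calling everything
    positive (sensitivity 1).
    """
    if not 0.0 < target_sensitivity < 1.0:
        raise ValueError("target_sensitivity must lie in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auroc(scores, labels)  # class-presence check
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # candidate thresholds: observed scores, scanned from the top
    candidates = np.unique(scores)[::-1]
    for thr in candidates:
        sens = float((pos >= thr).mean())
        if sens >= target_sensitivity:
            spec = float((neg < thr).mean())
            return float(thr), sens, spec
    return float("-inf"), 1.0, 0.0


@dataclass
class EvalReport:
    """Per-target discrimination metrics for one model."""

    model_name: str
    n_targets: int
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)  # indexed by target


def evaluate_model(
    probabilities: dict[str, np.ndarray],
    labels: dict[str, np.ndarray],
    model_name: str,
    n_resamples: int = DEFAULT_BOOTSTRAP_RESAMPLES,
    target_sensitivity: float = DEFAULT_TARGET_SENSITIVITY,
    seed: int = 0,
) -> EvalReport:
    """Tabulate AUROC with bootstrap CI and an operating point per target."""
    records = []
    for target, probs in probabilities.items():
        y = np.asarray(labels[target]).astype(int)
        try:
            point = auroc(probs, y)
            low, high = bootstrap_ci(probs, y, n_resamples=n_resamples, seed=seed)
            thr, sens, spec = operating_point(probs, y, target_sensitivity)
        except UndefinedMetricError:
            point = low = high = thr = sens = spec = float("nan")
        records.append(
            {
                "target": target,
                "auroc": point,
                "ci_low": low,
                "ci_high": high,
                "threshold": thr,
                "sensitivity": sens,
                "specificity": spec,
                "prevalence": float(y.mean()),
            }
        )
    rows = pd.DataFrame.from_records(records).set_index("target")
    return EvalReport(model_name=model_name, n_targets=len(probabilities), rows=rows)


def compare_models(network: EvalReport, baseline: EvalReport) -> pd.DataFrame:
    """Side-by-side AUROC comparison with per-target deltas."""
    if set(network.rows.index) != set(baseline.rows.index):
        raise ValueError("reports cover different target sets")
    df = pd.DataFrame(
        {
            f"auroc_{network.model_name}": network.rows["auroc"],
            f"auroc_{baseline.model_name}": baseline.rows["auroc"],
        }
    )
    df["delta"] = df.iloc[:, 0] - df.iloc[:, 1]
    return df


def ablation_curve(stages: list[tuple[int, dict[str, float]]]) -> pd.DataFrame:
    """Long-form (n_targets, target, auroc) rows from an ablation series."""
    rows = [
        {"n_targets": n, "target": target, "auroc": value}
        for n, per_target in stages
        for target, value in per_target.items()
    ]
    return pd.DataFrame.from_records(rows)
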