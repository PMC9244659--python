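"""One-vs-all gradient-boosted-tree comparator on the identical feature matrix.

Each of the 13 targets gets its own XGBoost classifier trained on the
flattened (51 x 64 = 3264) feature vector. Cells whose availability mask is
zero are passed as native missing values rather than zeros, so the trees can
route unmeasured values separately — the main appeal of boosted trees on EHR
snapshots. Grid points are chosen per target by validation AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xgboost as xgb

from .features import N_ROWS, N_TIMESTEPS, N_TIME_VARYING, ROW_MASK_START, ROW_VALUE_START
from .evaluation import UndefinedMetricError, auroc


@dataclass
class BaselineConfig:
    """Per-target hyperparameter grid for the boosted-tree comparator."""

    max_depths: list[int] = field(default_factory=lambda: [3, 5])
    learning_rates: list[float] = field(default_factory=lambda: [0.1, 0.3])
    n_rounds: int = 60
    seed: int = 0

    def validate(self) -> None:
        if not self.max_depths or not self.learning_rates:
            raise ValueError("hyperparameter grid must be non-empty")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")

    def grid(self) -> list[tuple[int, float]]:
        return [(d, lr) for d in self.max_depths for lr in self.learning_rates]


@dataclass
class FittedScorer:
    """One per-target scorer: a booster, or a prevalence constant fallback."""

    target: str
    booster: xgb.XGBClassifier | None
    constant: float | None
    chosen_depth: int | None
    chosen_lr: float | None

    def predict_proba(self, flat_x: np.ndarray) -> np.ndarray:
        if self.booster is None:
            return np.full(len(flat_x), self.constant)
        return self.booster.predict_proba(flat_x)[:, 1]


def flatten_tensors(x: np.ndarray) -> np.ndarray:
    """Row-major flatten of (n, 51, 64) stacks with masked cells as NaN.

    The value cell of every time-varying feature whose mask is 0 becomes NaN
    so the learner's missing-value handling sees true missingness; mask rows
    themselves are kept (they still carry sampling-intensity signal).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3 or x.shape[1:] != (N_ROWS, N_TIMESTEPS):
        raise ValueError(f"expected (n, {N_ROWS}, {N_TIMESTEPS}) input")
    out = x.copy()
    values = out[:, ROW_VALUE_START : ROW_VALUE_START + N_TIME_VARYING, :]
    masks = out[:, ROW_MASK_START : ROW_MASK_START + N_TIME_VARYING, :]
    values[masks == 0] = np.nan
    return out.reshape(len(out), N_ROWS * N_TIMESTEPS)


def train_one_vs_all(
    train_x: np.ndarray,
    train_labels: dict[str, np.ndarray],
    val_x: np.ndarray,
    val_labels: dict[str, np.ndarray],
    config: BaselineConfig | None = None,
) -> dict[str, FittedScorer]:
    """Fit one scorer per target; single-class targets fall back to a constant."""
    if config is None:
        config = BaselineConfig()
    config.validate()
    flat_train = flatten_tensors(train_x)
    flat_val = flatten_tensors(val_x)
    scorers: dict[str, FittedScorer] = {}
    for target, y in train_labels.items():
        y = np.asarray(y).astype(int)
        if y.min() == y.max():
            scorers[target] = FittedScorer(
                target=target,
                booster=None,
                constant=float(y.mean()),
                chosen_depth=None,
                chosen_lr=None,
            )
            continue
        y_val = np.asarray(val_labels[target]).astype(int)
        best = None
        for depth, lr in config.grid():
            clf = xgb.XGBClassifier(
                max_depth=depth,
                learning_rate=lr,
                n_estimators=config.n_rounds,
                tree_method="hist",
                n_jobs=1,
                random_state=config.seed,
                eval_metric="logloss",
                verbosity=0,
            )
            clf.fit(flat_train, y)
            try:
                score = auroc(clf.predict_proba(flat_val)[:, 1], y_val)
            except UndefinedMetricError:
                score = float("nan")
            key = -np.inf if np.isnan(score) else score
            if best is None or key > best[0]:
                best = (key, clf, depth, lr)
        _, clf, depth, lr = best
        scorers[target] = FittedScorer(
            target=target, booster=clf, constant=None, chosen_depth=depth, chosen_lr=lr
        )
    return scorers


def predict_proba(
    scorers: dict[str, FittedScorer], x: np.ndarray
) -> dict[str, np.ndarray]:
    flat = flatten_tensors(x)
    return {target: s.predict_proba(flat) for target, s in scorers.items()}
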