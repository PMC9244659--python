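"""The recurrent attention network and its multitask training loop.

Architecture, per encounter (a 51-row x 64-timestep matrix):

1. a learned elementwise normalization ``a * (v - mu) / sigma + b`` of every
   input row (sigma kept positive through an exponential parameterization);
2. a stack of GRU layers (default 4, 128 hidden units) run over the 64
   timesteps;
3. a soft attention module scoring every deepest-layer hidden state h_i
   against the final one h_n as ``K^T tanh(W_a prelu(W_b [h_n, h_i]))``,
   normalized by a softmax into attention weights whose weighted sum of
   hidden states is the context vector;
4. a two-layer classification head on ``[context, h_n]`` whose first
   fully connected activation (64-dim by default) is the penultimate
   embedding used downstream for phenotype clustering, followed by one
   logit per target and elementwise sigmoids.

Training minimizes the mean of per-target binary cross-entropies (hard
parameter sharing across tasks) with Adam, and early-stops on the
validation AUROC of the primary ARDS target.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor, parameter
from .evaluation import UndefinedMetricError, auroc
from .features import N_ROWS, N_TIMESTEPS
from .outcome_labels import LABEL_NAMES

PRIMARY_TARGET = "ards_1"


class CannotEvaluateError(ValueError):
    """Validation labels for the primary target contain a single class."""


@dataclass
class ModelConfig:
    """Architecture and optimization settings."""

    hidden_units: int = 128
    gru_layers: int = 4
    fc1_dim: int = 64
    attention_dim: int | None = None  # defaults to hidden_units
    target_subset: list[str] = field(default_factory=lambda: list(LABEL_NAMES))
    max_epochs: int = 15
    patience: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 128
    seed: int = 0

    @property
    def n_targets(self) -> int:
        return len(self.target_subset)

    def validate(self) -> None:
        if PRIMARY_TARGET not in self.target_subset:
            raise ValueError(f"target_subset must contain {PRIMARY_TARGET}")
        if self.fc1_dim <= 0 or self.hidden_units <= 0 or self.gru_layers <= 0:
            raise ValueError("architecture dimensions must be positive")
        unknown = set(self.target_subset) - set(LABEL_NAMES)
        if unknown:
            raise ValueError(f"unknown targets {sorted(unknown)}")


@dataclass
class ForwardOutput:
    """Per-patient outputs of one forward pass."""

    logits: np.ndarray  # (n, n_targets)
    probabilities: np.ndarray  # (n, n_targets), in (0, 1)
    attention_weights: np.ndarray  # (n, 64), rows sum to 1
    context_vector: np.ndarray  # (n, hidden_units)
    penultimate_embedding: np.ndarray  # (n, fc1_dim)


def learned_normalize(v: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                      a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise learned normalization ``a * (v - mu) / sigma + b``."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma parameters must be strictly positive")
    return np.asarray(a) * (np.asarray(v) - np.asarray(mu)) / sigma + np.asarray(b)


def attention_score(h_n: np.ndarray, h_i: np.ndarray, K: np.ndarray,
                    W_a: np.ndarray, W_b: np.ndarray, alpha: float = 0.25) -> float:
    """Attention score ``K^T tanh(W_a prelu(W_b [h_n, h_i]))`` for one step.

    Matrices are in mathematical orientation: ``W_b`` maps the concatenated
    pair (2H) into the attention space (A), ``W_a`` is (A, A), ``K`` is (A,).
    """
    h_n = np.asarray(h_n, dtype=float).ravel()
    h_i = np.asarray(h_i, dtype=float).ravel()
    cat = np.concatenate([h_n, h_i])
    W_b = np.asarray(W_b, dtype=float)
    W_a = np.asarray(W_a, dtype=float)
    K = np.asarray(K, dtype=float).ravel()
    if W_b.shape[1] != cat.size or W_a.shape[1] != W_b.shape[0] or K.size != W_a.shape[0]:
        raise ValueError("attention parameter dimensions do not match")
    u = W_b @ cat
    u = np.where(u > 0, u, alpha * u)
    return float(K @ np.tanh(W_a @ u))


def attention_weights(scores: np.ndarray) -> np.ndarray:
    """Softmax normalization of attention scores into weights."""
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    e = np.exp(s - s.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def multilabel_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean of per-element binary cross-entropies on raw logits."""
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if logits.shape != labels.shape:
        raise ValueError("logits and labels must share a shape")
    return float(Tensor(logits).bce_with_logits(labels).data)


class MultitaskRNN:
    """Trainable recurrent attention classifier."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        H = config.hidden_units
        A = config.attention_dim or H
        rng = np.random.default_rng(config.seed)
        s = 1.0 / np.sqrt(H)
        p: dict[str, Tensor] = {}
        # learned input normalization; sigma = exp(log_sigma) stays positive
        p["norm_mu"] = Tensor(np.zeros(N_ROWS), requires_grad=True)
        p["norm_log_sigma"] = Tensor(np.zeros(N_ROWS), requires_grad=True)
        p["norm_a"] = Tensor(np.ones(N_ROWS), requires_grad=True)
        p["norm_b"] = Tensor(np.zeros(N_ROWS), requires_grad=True)
        for layer in range(config.gru_layers):
            d_in = N_ROWS if layer == 0 else H
            for gate in ("r", "z", "n"):
                p[f"gru{layer}_Wi{gate}"] = parameter(rng, (d_in, H), s)
                p[f"gru{layer}_Wh{gate}"] = parameter(rng, (H, H), s)
                p[f"gru{layer}_bi{gate}"] = parameter(rng, (H,), s)
                p[f"gru{layer}_bh{gate}"] = parameter(rng, (H,), s)
        p["att_Wb"] = parameter(rng, (2 * H, A), s)
        p["att_Wa"] = parameter(rng, (A, A), 1.0 / np.sqrt(A))
        p["att_K"] = parameter(rng, (A, 1), 1.0 / np.sqrt(A))
        p["att_alpha"] = Tensor(np.array(0.25), requires_grad=True)
        p["fc1_W"] = parameter(rng, (2 * H, config.fc1_dim), 1.0 / np.sqrt(2 * H))
        p["fc1_b"] = parameter(rng, (config.fc1_dim,), 1.0 / np.sqrt(2 * H))
        p["fc1_alpha"] = Tensor(np.array(0.25), requires_grad=True)
        p["fc2_W"] = parameter(
            rng, (config.fc1_dim, config.n_targets), 1.0 / np.sqrt(config.fc1_dim)
        )
        p["fc2_b"] = parameter(rng, (config.n_targets,), 1.0 / np.sqrt(config.fc1_dim))
        self.params = p
        self.training_history: list[float] = []
        self.selected_epoch: int | None = None

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = state[k].copy()

    # -- forward pass ---------------------------------------------------------
    def _forward_graph(self, x: np.ndarray) -> dict[str, Tensor]:
        """Tape-building forward pass on a (B, 51, 64) batch."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[1] != N_ROWS or x.shape[2] != N_TIMESTEPS:
            raise ValueError(f"expected (batch, {N_ROWS}, {N_TIMESTEPS}) input")
        p = self.params
        B = x.shape[0]
        H = self.config.hidden_units
        inv_sigma = (Tensor(np.zeros(1)) - p["norm_log_sigma"]).exp()

        hidden = [Tensor(np.zeros((B, H))) for _ in range(self.config.gru_layers)]
        deepest: list[Tensor] = []
        for t in range(N_TIMESTEPS):
            inp = (Tensor(x[:, :, t]) - p["norm_mu"]) * p["norm_a"] * inv_sigma + p["norm_b"]
            for layer in range(self.config.gru_layers):
                h = hidden[layer]
                r = (
                    inp @ p[f"gru{layer}_Wir"] + p[f"gru{layer}_bir"]
                    + h @ p[f"gru{layer}_Whr"] + p[f"gru{layer}_bhr"]
                ).sigmoid()
                z = (
                    inp @ p[f"gru{layer}_Wiz"] + p[f"gru{layer}_biz"]
                    + h @ p[f"gru{layer}_Whz"] + p[f"gru{layer}_bhz"]
                ).sigmoid()
                n = (
                    inp @ p[f"gru{layer}_Win"] + p[f"gru{layer}_bin"]
                    + r * (h @ p[f"gru{layer}_Whn"] + p[f"gru{layer}_bhn"])
                ).tanh()
                hidden[layer] = (Tensor(np.ones(1)) - z) * n + z * h
                inp = hidden[layer]
            deepest.append(hidden[-1])

        h_n = deepest[-1]
        scores = []
        for h_i in deepest:
            cat = Tensor.concat([h_n, h_i], axis=1)  # (B, 2H)
            u = (cat @ p["att_Wb"]).prelu(p["att_alpha"])
            scores.append((u @ p["att_Wa"]).tanh() @ p["att_K"])  # (B, 1)
        score_mat = Tensor.concat(scores, axis=1)  # (B, 64)
        weights = score_mat.softmax(axis=1)
        context = None
        for t, h_i in enumerate(deepest):
            term = weights[:, t : t + 1] * h_i
            context = term if context is None else context + term

        head_in = Tensor.concat([context, h_n], axis=1)  # (B, 2H)
        penult = (head_in @ p["fc1_W"] + p["fc1_b"]).prelu(p["fc1_alpha"])
        logits = penult @ p["fc2_W"] + p["fc2_b"]
        return {
            "logits": logits,
            "weights": weights,
            "context": context,
            "penultimate": penult,
        }

    def forward(self, x: np.ndarray) -> ForwardOutput:
        """Inference forward pass; deterministic for fixed weights."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None, :, :]
        nodes = self._forward_graph(x)
        logits = nodes["logits"].data
        return ForwardOutput(
            logits=logits,
            probabilities=1.0 / (1.0 + np.exp(-logits)),
            attention_weights=nodes["weights"].data,
            context_vector=nodes["context"].data,
            penultimate_embedding=nodes["penultimate"].data,
        )

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Per-target probabilities for a stack of feature tensors."""
        outs = [
            self.forward(x[i : i + batch_size]).probabilities
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs) if outs else np.zeros((0, self.config.n_targets))


def train(
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: ModelConfig,
) -> MultitaskRNN:
    """Fit the network with early stopping on primary-target validation AUROC.

    ``train_y``/``val_y`` are (n, n_targets) binary matrices in the order of
    ``config.target_subset``. Deterministic for a fixed config (seed included).
    """
    config.validate()
    primary_col = config.target_subset.index(PRIMARY_TARGET)
    val_primary = np.asarray(val_y)[:, primary_col].astype(int)
    if val_primary.min() == val_primary.max():
        raise CannotEvaluateError(
            "validation labels for the primary target are single-class"
        )
    model = MultitaskRNN(config)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = len(train_x)
    best_state = model.get_state()
    best_auroc = -np.inf
    best_epoch = 0
    since_best = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            nodes = model._forward_graph(train_x[idx])
            loss = nodes["logits"].bce_with_logits(np.asarray(train_y)[idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        val_probs = model.predict_proba(val_x)[:, primary_col]
        epoch_auroc = auroc(val_probs, val_primary)
        model.training_history.append(epoch_auroc)
        if epoch_auroc > best_auroc:
            best_auroc = epoch_auroc
            best_epoch = epoch
            best_state = model.get_state()
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                break
    model.set_state(best_state)
    model.selected_epoch = best_epoch
    return model


def ablation_series(
    train_x: np.ndarray,
    train_labels: dict[str, np.ndarray],
    val_x: np.ndarray,
    val_labels: dict[str, np.ndarray],
    test_x: np.ndarray,
    test_labels: dict[str, np.ndarray],
    base_config: ModelConfig | None = None,
) -> list[tuple[int, MultitaskRNN, dict[str, float]]]:
    """Target-ablation protocol: train at 13 targets, then repeatedly drop
    the two lowest-AUROC targets (never the primary one) and retrain at
    11, 9, 7 and 5 targets.
    """
    if base_config is None:
        base_config = ModelConfig()
    subset = list(LABEL_NAMES)
    results: list[tuple[int, MultitaskRNN, dict[str, float]]] = []
    while len(subset) >= 5:
        config = copy.deepcopy(base_config)
        config.target_subset = list(subset)
        ty = np.column_stack([train_labels[t] for t in subset])
        vy = np.column_stack([val_labels[t] for t in subset])
        model = train(train_x, ty, val_x, vy, config)
        probs = model.predict_proba(test_x)
        per_target: dict[str, float] = {}
        for j, target in enumerate(subset):
            y = np.asarray(test_labels[target]).astype(int)
            try:
                per_target[target] = auroc(probs[:, j], y)
            except UndefinedMetricError:
                per_target[target] = float("nan")
        results.append((len(subset), model, per_target))
        if len(subset) == 5:
            break
        removable = [t for t in subset if t != PRIMARY_TARGET]
        removable.sort(key=lambda t: (np.nan_to_num(per_target[t], nan=-1.0), t))
        for victim in removable[:2]:
            subset.remove(victim)
    return results


# -- serialization -------------------------------------------------------------


def save_model(model: MultitaskRNN, path: str | Path) -> None:
    """Persist weights, config and training history as .npz + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.get_state())
    meta = {
        "config": {
            **{
                k: getattr(model.config, k)
                for k in (
                    "hidden_units",
                    "gru_layers",
                    "fc1_dim",
                    "attention_dim",
                    "max_epochs",
                    "patience",
                    "learning_rate",
                    "batch_size",
                    "seed",
                )
            },
            "target_subset": model.config.target_subset,
        },
        "training_history": model.training_history,
        "selected_epoch": model.selected_epoch,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> MultitaskRNN:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(**meta["config"])
    model = MultitaskRNN(config)
    with np.load(path.with_suffix(".npz")) as npz:
        model.set_state({k: npz[k] for k in npz.files})
    model.training_history = list(meta["training_history"])
    model.selected_epoch = meta["selected_epoch"]
    return model
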