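"""Attention-based interpretability: timestep heat maps and feature profiles.

Two complementary views of what the trained network attends to:

* a heat map matrix of attention weights over the 64 timesteps for a random
  sample of patients (rows are exact copies of the forward pass weights);
* for one patient, the normalized feature column at the timestep carrying
  the highest attention weight — readable as a z-score profile against the
  clinical normal ranges (masked features stay 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import (
    N_TIME_VARYING,
    N_TIMESTEPS,
    ROW_MASK_START,
    ROW_VALUE_START,
    TIME_VARYING,
)
from .multitask_rnn import MultitaskRNN


class UntrainedModelError(ValueError):
    """The model has not been through a training run."""


@dataclass
class AttentionProfile:
    """Attention weights plus the feature z-profile at the argmax timestep."""

    patient_id: str
    weights: np.ndarray  # (64,)
    argmax_step: int
    feature_z: dict[str, float]  # per time-varying feature; 0 where masked


def _check_trained(model: MultitaskRNN) -> None:
    if model.selected_epoch is None:
        raise UntrainedModelError("model carries no training history")


def attention_heatmap_data(
    model: MultitaskRNN,
    tensors: np.ndarray,
    n_sample: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Attention weights for a random patient sample.

    Returns (sampled row indices, n_sample x 64 weight matrix); rows are the
    forward-pass attention weights verbatim.
    """
    _check_trained(model)
    n = len(tensors)
    if n_sample > n:
        raise ValueError("n_sample exceeds the cohort size")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=n_sample, replace=False))
    weights = model.forward(tensors[idx]).attention_weights
    return idx, weights


def max_attention_feature_profile(
    model: MultitaskRNN,
    tensor: np.ndarray,
    patient_id: str = "",
) -> AttentionProfile:
    """Feature z-profile at the most-attended timestep (earliest on ties)."""
    _check_trained(model)
    tensor = np.asarray(tensor, dtype=float)
    out = model.forward(tensor)
    weights = out.attention_weights[0]
    step = int(np.argmax(weights))  # argmax takes the first index on ties
    column = tensor if tensor.ndim == 2 else tensor[0]
    feature_z = {}
    for j, feature in enumerate(TIME_VARYING):
        masked = column[ROW_MASK_START + j, step] == 0.0
        feature_z[feature] = 0.0 if masked else float(column[ROW_VALUE_START + j, step])
    return AttentionProfile(
        patient_id=patient_id,
        weights=weights,
        argmax_step=step,
        feature_z=feature_z,
    )


def heatmap_to_tsv(weights: np.ndarray, path) -> None:
    """Export a heat-map matrix as TSV (one row per sampled patient)."""
    import pandas as pd

    df = pd.DataFrame(weights, columns=[f"t{t}" for t in range(N_TIMESTEPS)])
    df.to_csv(path, sep="\t", index=False)


def plot_heatmap(weights: np.ndarray, path) -> None:
    """Optional PNG rendering of the attention heat map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, max(2, 0.12 * len(weights))))
    im = ax.imshow(weights, aspect="auto", cmap="viridis")
    ax.set_xlabel("timestep (20-minute bins, right edge = prediction time)")
    ax.set_ylabel("sampled patient")
    fig.colorbar(im, ax=ax, label="attention weight")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
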