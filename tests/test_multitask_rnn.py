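"""Network contracts: normalization, attention, forward pass, training."""

from __future__ import annotations

import numpy as np
import pytest

from ardsmtl.autodiff import Adam
from ardsmtl.multitask_rnn import (
    CannotEvaluateError,
    ModelConfig,
    MultitaskRNN,
    ablation_series,
    attention_score,
    attention_weights,
    learned_normalize,
    load_model,
    multilabel_loss,
    save_model,
    train,
)
from ardsmtl.outcome_labels import LABEL_NAMES

TINY = dict(hidden_units=8, gru_layers=2, fc1_dim=6, batch_size=16)


def _tiny_config(**over) -> ModelConfig:
    kwargs = {**TINY, "target_subset": ["ards_1", "hypox_9"], "max_epochs": 2,
              "seed": 0}
    kwargs.update(over)
    return ModelConfig(**kwargs)


def separable_dataset(n: int, seed: int, n_targets: int = 2):
    """Feature tensors whose SpO2 row separates the classes by construction."""
    rng = np.random.default_rng(seed)
    x = rng.normal(scale=0.1, size=(n, 51, 64))
    y = np.zeros((n, n_targets), dtype=int)
    pos = rng.random(n) < 0.5
    x[pos, 8, -8:] += 2.0  # strong signal on one value row near the end
    x[~pos, 8, -8:] -= 2.0
    y[pos] = 1
    return x, y


# --- learned normalization ---------------------------------------------------


def test_learned_normalize_identity_and_substitution():
    v = np.array([5.0])
    assert learned_normalize(v, 0.0, 1.0, 1.0, 0.0)[0] == 5.0
    assert learned_normalize(np.array([5.0]), 3.0, 2.0, 2.0, 1.0)[0] == 3.0
    mu = np.array([1.5])
    assert learned_normalize(mu, mu, 9.0, 7.0, 4.0)[0] == 4.0


def test_learned_normalize_requires_positive_sigma():
    with pytest.raises(ValueError):
        learned_normalize(np.ones(3), np.zeros(3), np.zeros(3), np.ones(3), np.zeros(3))


# --- attention ---------------------------------------------------------------


def test_attention_score_zero_key_and_determinism():
    rng = np.random.default_rng(0)
    h_n, h_i = rng.normal(size=4), rng.normal(size=4)
    W_b, W_a = rng.normal(size=(3, 8)), rng.normal(size=(3, 3))
    assert attention_score(h_n, h_i, np.zeros(3), W_a, W_b) == 0.0
    K = rng.normal(size=3)
    assert attention_score(h_n, h_i, K, W_a, W_b) == attention_score(
        h_n, h_i, K, W_a, W_b
    )


def test_attention_score_matches_hand_multiplied_toy():
    """2-dim weights small enough to multiply through by hand."""
    h_n, h_i = np.array([1.0, 0.0]), np.array([0.0, -1.0])
    W_b = np.array([[1.0, 0.0, 0.0, 2.0], [0.0, 1.0, -1.0, 0.0]])
    # W_b [h_n,h_i] = [1*1 + 2*(-1), 0] = [-1, 0]; prelu(0.25) -> [-0.25, 0]
    W_a = np.array([[2.0, 0.0], [0.0, 1.0]])
    # W_a u = [-0.5, 0]; tanh -> [tanh(-0.5), 0]
    K = np.array([3.0, 10.0])
    expected = 3.0 * np.tanh(-0.5)
    got = attention_score(h_n, h_i, K, W_a, W_b, alpha=0.25)
    assert got == pytest.approx(expected, rel=1e-12)


def test_attention_score_dimension_mismatch():
    with pytest.raises(ValueError):
        attention_score(np.ones(3), np.ones(3), np.ones(2), np.eye(2), np.eye(5))


def test_attention_weights_softmax_cases():
    np.testing.assert_allclose(attention_weights(np.zeros(64)), np.full(64, 1 / 64))
    np.testing.assert_allclose(attention_weights(np.array([3.7])), [1.0])
    np.testing.assert_allclose(
        attention_weights(np.array([0.0, np.log(3.0)])), [0.25, 0.75]
    )
    with pytest.raises(ValueError):
        attention_weights(np.array([np.inf, 0.0]))


# --- forward pass ---------------------------------------------------------------


def test_forward_shapes_and_attention_normalization():
    model = MultitaskRNN(_tiny_config())
    x = np.random.default_rng(1).normal(size=(5, 51, 64))
    out = model.forward(x)
    assert out.logits.shape == (5, 2)
    assert out.probabilities.shape == (5, 2)
    assert np.all((out.probabilities > 0) & (out.probabilities < 1))
    assert out.attention_weights.shape == (5, 64)
    np.testing.assert_allclose(out.attention_weights.sum(axis=1), 1.0, atol=1e-6)
    assert out.context_vector.shape == (5, 8)
    assert out.penultimate_embedding.shape == (5, 6)


def test_forward_deterministic_and_zero_input_defined():
    model = MultitaskRNN(_tiny_config())
    x = np.zeros((2, 51, 64))
    a = model.forward(x)
    b = model.forward(x)
    np.testing.assert_array_equal(a.logits, b.logits)
    np.testing.assert_allclose(a.attention_weights.sum(axis=1), 1.0, atol=1e-6)


def test_forward_batch_equivariance():
    """Permuting patients permutes outputs; batches match per-patient calls."""
    model = MultitaskRNN(_tiny_config())
    x = np.random.default_rng(2).normal(size=(6, 51, 64))
    batch = model.forward(x)
    perm = np.array([3, 1, 5, 0, 2, 4])
    permuted = model.forward(x[perm])
    np.testing.assert_allclose(permuted.logits, batch.logits[perm], atol=1e-10)
    single = model.forward(x[3])
    np.testing.assert_allclose(single.logits[0], batch.logits[3], atol=1e-10)


def test_forward_rejects_bad_shape():
    model = MultitaskRNN(_tiny_config())
    with pytest.raises(ValueError):
        model.forward(np.zeros((2, 50, 64)))


# --- loss ------------------------------------------------------------------------


def test_multilabel_loss_examples():
    assert multilabel_loss(np.zeros((3, 4)), np.random.default_rng(0).integers(
        0, 2, (3, 4))) == pytest.approx(np.log(2))
    big = np.full((2, 2), 30.0)
    assert multilabel_loss(big, np.ones((2, 2))) < 1e-10
    logits = np.array([[1.0, -1.0], [0.5, 2.0]])
    labels = np.array([[1.0, 0.0], [0.0, 1.0]])
    p = 1 / (1 + np.exp(-logits))
    hand = -(labels * np.log(p) + (1 - labels) * np.log(1 - p)).mean()
    assert multilabel_loss(logits, labels) == pytest.approx(hand)
    with pytest.raises(ValueError):
        multilabel_loss(logits, labels + 0.2)


def test_single_optimization_step_decreases_loss():
    config = _tiny_config()
    model = MultitaskRNN(config)
    x, y = separable_dataset(16, seed=5)
    opt = Adam(model.parameters(), lr=1e-3)
    nodes = model._forward_graph(x)
    before = nodes["logits"].bce_with_logits(y)
    opt.zero_grad()
    before.backward()
    opt.step()
    after = model._forward_graph(x)["logits"].bce_with_logits(y)
    assert float(after.data) < float(before.data)


# --- training ----------------------------------------------------------------------


def test_degenerate_schedule_runs_exactly_one_epoch():
    x, y = separable_dataset(30, seed=6)
    config = _tiny_config(max_epochs=1, patience=0)
    model = train(x, y, x, y, config)
    assert len(model.training_history) == 1
    assert model.selected_epoch == 1


def test_training_is_deterministic_given_seed():
    x, y = separable_dataset(40, seed=7)
    config = _tiny_config(max_epochs=2)
    a = train(x, y, x, y, config)
    b = train(x, y, x, y, config)
    assert a.training_history == b.training_history
    for k in a.params:
        np.testing.assert_array_equal(a.params[k].data, b.params[k].data)


def test_separable_fixture_reaches_high_validation_auroc():
    x, y = separable_dataset(120, seed=8)
    config = _tiny_config(max_epochs=6, learning_rate=3e-3)
    model = train(x[:80], y[:80], x[80:], y[80:], config)
    assert max(model.training_history) > 0.9


def test_single_class_validation_rejected():
    x, y = separable_dataset(20, seed=9)
    y_bad = y.copy()
    y_bad[:, 0] = 1
    with pytest.raises(CannotEvaluateError):
        train(x, y, x, y_bad, _tiny_config())


def test_config_requires_primary_target():
    with pytest.raises(ValueError):
        ModelConfig(target_subset=["hypox_9"]).validate()


def test_model_roundtrips_through_archive(tmp_path):
    x, y = separable_dataset(24, seed=10)
    model = train(x, y, x, y, _tiny_config(max_epochs=1))
    save_model(model, tmp_path / "model")
    clone = load_model(tmp_path / "model")
    np.testing.assert_array_equal(
        clone.forward(x[:3]).logits, model.forward(x[:3]).logits
    )
    assert clone.training_history == model.training_history


# --- ablation -----------------------------------------------------------------------


def test_ablation_series_follows_13_11_9_7_5_protocol():
    rng = np.random.default_rng(11)
    n = 60
    x = rng.normal(scale=0.1, size=(n, 51, 64))
    pos = rng.random(n) < 0.5
    x[pos, 8, -8:] += 2.0
    x[~pos, 8, -8:] -= 2.0
    labels = {}
    for j, name in enumerate(LABEL_NAMES):
        if name in ("ards_1", "hypox_9"):
            labels[name] = pos.astype(int)
        else:
            noisy = pos ^ (rng.random(n) < 0.3 + 0.02 * j)
            labels[name] = noisy.astype(int)
    config = ModelConfig(**TINY, max_epochs=1, seed=1)
    series = ablation_series(x, labels, x, labels, x, labels, config)
    sizes = [n_targets for n_targets, _, _ in series]
    assert sizes == [13, 11, 9, 7, 5]
    previous = None
    for n_targets, model, per_target in series:
        assert "ards_1" in model.config.target_subset
        assert set(per_target) == set(model.config.target_subset)
        if previous is not None:
            prev_targets, prev_scores = previous
            removed = set(prev_targets) - set(model.config.target_subset)
            # the two dropped targets are the argmin-2 of the previous stage
            candidates = sorted(
                (t for t in prev_targets if t != "ards_1"),
                key=lambda t: (prev_scores[t], t),
            )[:2]
            assert removed == set(candidates)
        previous = (model.config.target_subset, per_target)
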