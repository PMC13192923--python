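"""Temporal models: exact gradients, masking, determinism, reductions, training."""

import numpy as np
import pytest

from dynograph.graph import build_adjacency
from dynograph.models import (
    ModelConfig,
    TrainedModel,
    _batch_loss,
    _forward,
    _init_params,
    _loss_and_grad,
    hidden_states,
    multi_seed_run,
    predict,
    train,
)
from dynograph.panel import SequenceBatch


def _random_batch(rng, n=12, T=5, d=4, binary=False, gap_prob=0.25):
    X = rng.standard_normal((n, T, d))
    mask = (rng.random((n, T)) >= gap_prob).astype(int)
    mask[:, 0] = 1
    X[mask == 0] = 0.0
    if binary:
        y = (rng.random((n, T)) < 0.3).astype(float)
    else:
        y = rng.standard_normal((n, T))
    y_valid = (rng.random((n, T)) < 0.9).astype(int)
    y[(mask * y_valid) == 0] = 0.0
    return SequenceBatch(
        subject_ids=[f"s{i}" for i in range(n)],
        X=X,
        mask=mask,
        y=y,
        y_valid=y_valid,
        feature_names=[f"f{j}" for j in range(d)],
    )


@pytest.mark.parametrize("arch", ["graph_lstm", "graph_gtrnn"])
@pytest.mark.parametrize("head", ["continuous", "binary"])
def test_backprop_matches_finite_differences(arch, head, rng):
    """Hand-written BPTT agrees with central differences to ~1e-8."""
    B, T, D, H = 4, 5, 3, 6
    batch = _random_batch(rng, n=B, T=T, d=D, binary=head == "binary")
    cfg = ModelConfig(architecture=arch, input_width=D, hidden_width=H, head=head)
    params = _init_params(arch, D, H, np.random.default_rng(1))
    _, grads = _loss_and_grad(params, cfg, batch.X, batch.mask, batch.y, batch.y_valid)
    for k, v in params.items():
        flat = v.ravel()
        gflat = grads[k].ravel()
        for i in rng.choice(flat.size, size=min(8, flat.size), replace=False):
            eps, orig = 1e-6, flat[i]
            flat[i] = orig + eps
            lp, _ = _loss_and_grad(params, cfg, batch.X, batch.mask, batch.y, batch.y_valid)
            flat[i] = orig - eps
            lm, _ = _loss_and_grad(params, cfg, batch.X, batch.mask, batch.y, batch.y_valid)
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert gflat[i] == pytest.approx(num, abs=1e-7, rel=1e-5)


@pytest.mark.parametrize("arch", ["graph_lstm", "graph_gtrnn"])
def test_masked_positions_never_affect_loss(arch, rng):
    """Perturbing features at masked steps changes neither loss nor predictions."""
    batch = _random_batch(rng, n=10, gap_prob=0.4)
    cfg = ModelConfig(architecture=arch, input_width=4, hidden_width=5)
    params = _init_params(arch, 4, 5, np.random.default_rng(2))
    base = _batch_loss(params, cfg, batch.X, batch.mask, batch.y, batch.y_valid)
    preds0, _, _ = _forward(params, arch, batch.X, batch.mask)

    X2 = batch.X.copy()
    X2[batch.mask == 0] = 1e6  # garbage at padded slots
    y2 = batch.y.copy()
    y2[(batch.mask * batch.y_valid) == 0] = -1e6  # garbage at unlabeled slots
    pert = _batch_loss(params, cfg, X2, batch.mask, y2, batch.y_valid)
    assert pert == base
    preds1, _, _ = _forward(params, arch, X2, batch.mask)
    valid = (batch.mask * batch.y_valid).astype(bool)
    np.testing.assert_array_equal(preds0[valid], preds1[valid])


def test_binary_head_outputs_probabilities(rng):
    batch = _random_batch(rng, binary=True)
    cfg = ModelConfig(
        architecture="graph_lstm", input_width=4, hidden_width=5, head="binary",
        max_epochs=2,
    )
    model = train(cfg, batch, batch)
    p = predict(model, batch)
    assert np.all((p > 0) & (p < 1)) and np.all(np.isfinite(p))


def test_permuting_subjects_permutes_predictions(rng):
    batch = _random_batch(rng, n=9)
    cfg = ModelConfig(architecture="graph_lstm", input_width=4, hidden_width=5, max_epochs=2)
    model = train(cfg, batch, batch)
    preds = predict(model, batch)
    perm = rng.permutation(9)
    shuffled = SequenceBatch(
        subject_ids=[batch.subject_ids[i] for i in perm],
        X=batch.X[perm],
        mask=batch.mask[perm],
        y=batch.y[perm],
        y_valid=batch.y_valid[perm],
        feature_names=batch.feature_names,
    )
    np.testing.assert_array_equal(predict(model, shuffled), preds[perm])


def test_gtrnn_identity_graph_reduces_to_plain_gru(rng):
    """With A = identity, the graph-GRU equals a GRU on raw node summaries bitwise."""
    batch = _random_batch(rng, n=8, d=6)
    graph = build_adjacency(np.zeros((2, 6)), [f"n{j}" for j in range(6)], method="identity")
    cfg = ModelConfig(architecture="graph_gtrnn", input_width=6, hidden_width=7, max_epochs=3)
    with_graph = train(cfg, batch, batch, graph=graph)
    plain = train(cfg, batch, batch, graph=None)
    for k in with_graph.params:
        np.testing.assert_array_equal(with_graph.params[k], plain.params[k])
    np.testing.assert_array_equal(
        predict(with_graph, batch, graph=graph), predict(plain, batch)
    )


def test_zero_adjacency_collapses_to_shared_trajectory(rng):
    """With A = 0 every subject sees the same (zero) input sequence."""
    batch = _random_batch(rng, n=6, d=5, gap_prob=0.0)
    graph = build_adjacency(np.zeros((2, 5)), [f"n{j}" for j in range(5)], method="identity")
    graph.adjacency = np.zeros((5, 5))
    cfg = ModelConfig(architecture="graph_gtrnn", input_width=5, hidden_width=4, max_epochs=2)
    model = train(cfg, batch, batch, graph=graph)
    preds = predict(model, batch, graph=graph)
    np.testing.assert_allclose(preds, preds[:1].repeat(6, axis=0), atol=1e-12)


def test_training_is_deterministic_under_fixed_seed(rng):
    batch = _random_batch(rng, n=20)
    cfg = ModelConfig(architecture="graph_lstm", input_width=4, hidden_width=6, max_epochs=8, seed=3)
    m1 = train(cfg, batch, batch)
    m2 = train(cfg, batch, batch)
    assert m1.history == m2.history
    for k in m1.params:
        np.testing.assert_array_equal(m1.params[k], m2.params[k])


def test_constant_target_converges_to_constant(rng):
    c = 3.0
    batch = _random_batch(rng, n=30, gap_prob=0.0)
    batch.y[:] = c
    batch.y_valid[:] = 1
    cfg = ModelConfig(
        architecture="graph_lstm", input_width=4, hidden_width=8,
        max_epochs=800, patience=800, learning_rate=1e-2,
    )
    model = train(cfg, batch, batch)
    preds = predict(model, batch)
    assert np.abs(preds - c).max() < 0.05 * abs(c) + 0.05


def test_strong_signal_is_overfit(rng):
    """On separable data the training loss falls well below its initial value."""
    batch = _random_batch(rng, n=50, gap_prob=0.0)
    w = rng.standard_normal(4)
    batch.y = batch.X @ w  # exact linear signal
    batch.y_valid[:] = 1
    cfg = ModelConfig(
        architecture="graph_lstm", input_width=4, hidden_width=16,
        max_epochs=200, patience=200, learning_rate=3e-3,
    )
    model = train(cfg, batch, batch)
    assert model.history[-1]["train_loss"] < 0.2 * model.history[0]["train_loss"]


def test_early_stopping_restores_best_epoch(rng):
    batch = _random_batch(rng, n=20)
    val = _random_batch(np.random.default_rng(99), n=10)
    cfg = ModelConfig(architecture="graph_gtrnn", input_width=4, hidden_width=6,
                      max_epochs=60, patience=5)
    model = train(cfg, batch, val)
    losses = [h["val_loss"] for h in model.history]
    assert model.best_epoch == int(np.argmin(losses))
    assert model.best_val_loss == pytest.approx(min(losses))
    assert len(losses) <= cfg.max_epochs


def test_no_valid_positions_raises(rng):
    batch = _random_batch(rng, n=5)
    batch.y_valid[:] = 0
    cfg = ModelConfig(architecture="graph_lstm", input_width=4, hidden_width=4, max_epochs=2)
    with pytest.raises(ValueError, match="no valid"):
        train(cfg, batch, batch)


def test_width_mismatch_raises(rng):
    batch = _random_batch(rng)
    cfg = ModelConfig(architecture="graph_lstm", input_width=9, hidden_width=4, max_epochs=1)
    with pytest.raises(ValueError, match="width"):
        train(cfg, batch, batch)


def test_multi_seed_summary_arithmetic(rng):
    batch = _random_batch(rng, n=16)
    cfg = ModelConfig(architecture="graph_lstm", input_width=4, hidden_width=4, max_epochs=3)
    single = multi_seed_run(cfg, batch, batch, batch, seeds=[0])
    assert all(v["sd"] == 0.0 for v in single["summary"].values())
    result = multi_seed_run(cfg, batch, batch, batch, seeds=[0, 1, 2])
    r2s = [r["metrics"]["r2"] for r in result["per_seed"]]
    assert result["summary"]["r2"]["mean"] == pytest.approx(np.mean(r2s))
    assert result["summary"]["r2"]["sd"] == pytest.approx(np.std(r2s))


def test_checkpoint_round_trip(tmp_path, rng):
    batch = _random_batch(rng)
    cfg = ModelConfig(architecture="graph_lstm", input_width=4, hidden_width=4, max_epochs=2)
    model = train(cfg, batch, batch)
    model.save(tmp_path / "ckpt")
    loaded = TrainedModel.load(tmp_path / "ckpt")
    np.testing.assert_array_equal(predict(loaded, batch), predict(model, batch))
    assert loaded.best_epoch == model.best_epoch


def test_hidden_states_shape_and_mask_carry(rng):
    batch = _random_batch(rng, n=7, gap_prob=0.5)
    cfg = ModelConfig(architecture="graph_gtrnn", input_width=4, hidden_width=9, max_epochs=2)
    model = train(cfg, batch, batch)
    H = hidden_states(model, batch)
    assert H.shape == (7, 5, 9)
    # at a masked step the hidden state equals the previous one
    for i in range(7):
        for t in range(1, 5):
            if batch.mask[i, t] == 0:
                np.testing.assert_array_equal(H[i, t], H[i, t - 1])
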