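"""Fusion autoencoder: construction, gradients, training behaviour."""

import numpy as np
import pytest

from drugrepo.containers import DrugVocabulary, PPMIMatrix
from drugrepo.fusion import (
    MAEConfig,
    build_mae,
    extract_features,
    scale_inputs,
    train_mae,
)

TINY = MAEConfig(per_network_hidden=8, joint_hidden=12, embedding_dim=5,
                 epochs=60, batch_size=10, learning_rate=3e-3,
                 dropout_rate=0.0, seed=3)


@pytest.fixture()
def tiny_inputs():
    gen = np.random.default_rng(42)
    n = 20
    cluster = np.arange(n) % 2
    mats = []
    for _ in range(3):
        base = np.where(cluster[:, None] == cluster[None, :], 0.8, 0.1)
        mats.append(np.clip(base + 0.05 * gen.normal(size=(n, n)), 0, 1))
    return mats


class TestScaleInputs:
    def test_spanning_matrix_unchanged(self):
        m = np.array([[0.0, 0.5], [1.0, 0.25]])
        scaled, params = scale_inputs([m])
        assert np.allclose(scaled[0], m)
        assert params[0] == (0.0, 1.0)

    def test_constant_matrix_becomes_zero(self):
        scaled, _ = scale_inputs([np.full((3, 3), 7.0)])
        assert np.allclose(scaled[0], 0.0)

    def test_bounds_map_to_unit_interval(self):
        scaled, _ = scale_inputs([np.array([[2.0, 4.0], [6.0, 3.0]])])
        assert scaled[0].min() == 0.0 and scaled[0].max() == 1.0

    def test_accepts_ppmi_objects(self):
        scaled, _ = scale_inputs([PPMIMatrix(np.array([[1.0, 0.0], [0.0, 2.0]]))])
        assert scaled[0].max() == 1.0


class TestBuildMae:
    def test_parameter_count_closed_form(self):
        cfg = TINY
        K, n = 3, 20
        h1, h2, d = cfg.per_network_hidden, cfg.joint_hidden, cfg.embedding_dim
        model = build_mae(cfg, K, n)
        expected = (K * (n * h1 + h1)            # encoders
                    + K * h1 * h2 + h2           # joint
                    + h2 * d + d                 # embedding
                    + d * h2 + h2                # decoder joint
                    + h2 * K * h1 + K * h1       # decoder split
                    + K * (h1 * n + n))          # reconstruction heads
        assert model.n_parameters() == expected

    def test_same_seed_identical_parameters(self):
        m1 = build_mae(TINY, 3, 20)
        m2 = build_mae(TINY, 3, 20)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_embedding_dimension(self, tiny_inputs):
        model = build_mae(TINY, 3, 20)
        _, z, _ = model.forward(tiny_inputs)
        assert z.shape == (20, TINY.embedding_dim)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Analytic gradients of the summed BCE agree with central differences."""
        gen = np.random.default_rng(0)
        cfg = MAEConfig(per_network_hidden=4, joint_hidden=5, embedding_dim=3,
                        dropout_rate=0.0, seed=1)
        model = build_mae(cfg, 2, 6)
        xs = [gen.random((6, 6)) for _ in range(2)]
        _, _, cache = model.forward(xs)
        grads = model._backward(cache)
        # batch-mean scaling in _backward uses batch rows == drug count here
        for name in ("We0", "Wj", "Wz", "Wd1", "Wd2", "Wo1", "bj"):
            w = model.params[name]
            idx = (0,) if w.ndim == 1 else (0, 0)
            eps = 1e-6
            w[idx] += eps
            up, _ = model.loss(xs)
            w[idx] -= 2 * eps
            down, _ = model.loss(xs)
            w[idx] += eps
            fd = (up - down) / (2 * eps)
            assert grads[name][idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestTraining:
    def test_loss_decreases(self, tiny_inputs):
        model = build_mae(TINY, 3, 20)
        history = train_mae(model, tiny_inputs)
        assert len(history.total) == TINY.epochs
        assert history.total[-1] < history.total[0]
        assert np.all(np.isfinite(history.total))

    def test_zero_epochs_leaves_model_unchanged(self, tiny_inputs):
        cfg = MAEConfig(**{**TINY.__dict__, "epochs": 0})
        model = build_mae(cfg, 3, 20)
        before = {k: v.copy() for k, v in model.params.items()}
        history = train_mae(model, tiny_inputs)
        assert history.total == []
        for k in before:
            assert np.array_equal(before[k], model.params[k])

    def test_identical_networks_near_identical_losses(self, tiny_inputs):
        model = build_mae(TINY, 3, 20)
        history = train_mae(model, [tiny_inputs[0]] * 3)
        per_net = np.array(history.per_network[-1])
        assert np.ptp(per_net) < 0.05 * per_net.mean() + 1e-9

    def test_same_seed_reproducible(self, tiny_inputs):
        h1 = train_mae(build_mae(TINY, 3, 20), tiny_inputs)
        h2 = train_mae(build_mae(TINY, 3, 20), tiny_inputs)
        assert h1.total[-1] == pytest.approx(h2.total[-1], abs=1e-12)

    def test_heldout_loss_below_untrained(self, tiny_inputs):
        train_rows = np.arange(18)
        test_rows = np.arange(18, 20)
        model = build_mae(TINY, 3, 20)
        untrained, _ = model.loss([m[test_rows] for m in tiny_inputs])
        train_mae(model, [m[train_rows] for m in tiny_inputs])
        trained, _ = model.loss([m[test_rows] for m in tiny_inputs])
        assert np.isfinite(trained)
        assert trained < untrained


class TestExtractFeatures:
    def test_shape_and_determinism(self, tiny_inputs):
        vocab = DrugVocabulary.from_ids([f"d{i}" for i in range(20)])
        model = build_mae(TINY, 3, 20)
        train_mae(model, tiny_inputs)
        f1 = extract_features(model, tiny_inputs, vocab)
        f2 = extract_features(model, tiny_inputs, vocab)
        assert f1.matrix.shape == (20, TINY.embedding_dim)
        assert np.array_equal(f1.matrix, f2.matrix)

    def test_identical_input_rows_identical_features(self, tiny_inputs):
        vocab = DrugVocabulary.from_ids([f"d{i}" for i in range(20)])
        mats = [m.copy() for m in tiny_inputs]
        for m in mats:
            m[1] = m[0]
        model = build_mae(TINY, 3, 20)
        train_mae(model, mats)
        feats = extract_features(model, mats, vocab)
        assert np.allclose(feats.matrix[0], feats.matrix[1])

    def test_cluster_contrast_in_features(self, tiny_inputs):
        """Planted two-block inputs: within-block feature similarity wins."""
        vocab = DrugVocabulary.from_ids([f"d{i}" for i in range(20)])
        model = build_mae(TINY, 3, 20)
        train_mae(model, tiny_inputs)
        F = extract_features(model, tiny_inputs, vocab).matrix
        Fc = F - F.mean(axis=0)
        Fn = Fc / (np.linalg.norm(Fc, axis=1, keepdims=True) + 1e-12)
        cos = Fn @ Fn.T
        cluster = np.arange(20) % 2
        same = cluster[:, None] == cluster[None, :]
        off = ~np.eye(20, dtype=bool)
        assert cos[same & off].mean() > cos[~same].mean()


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_inputs, tmp_path):
        from drugrepo.fusion import load_mae, save_mae

        model = build_mae(TINY, 3, 20)
        _, params = scale_inputs(tiny_inputs)
        train_mae(model, tiny_inputs)
        save_mae(model, tmp_path / "ckpt", scaling_params=params)
        restored, scaling = load_mae(tmp_path / "ckpt")
        assert scaling == params
        assert restored.cfg == model.cfg
        for k in model.params:
            assert np.array_equal(restored.params[k], model.params[k])
        _, z1, _ = model.forward(tiny_inputs)
        _, z2, _ = restored.forward(tiny_inputs)
        assert np.array_equal(z1, z2)

    def test_wrong_checkpoint_kind_rejected(self, tmp_path):
        from drugrepo.fusion import load_mae

        (tmp_path / "manifest.json").write_text('{"kind": "other"}')
        with pytest.raises(ValueError, match="checkpoint"):
            load_mae(tmp_path)
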