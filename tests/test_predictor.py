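"""Composite-loss components and the association VAE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugrepo.containers import AssociationMatrix, DrugVocabulary, FusedFeatures
from drugrepo.predictor import (
    LatentGaussian,
    LossWeights,
    WVAEConfig,
    auxiliary_loss,
    build_wvae,
    feature_cost,
    kl_regularization,
    mse_loss,
    predict,
    total_loss,
    train_wvae,
    wasserstein_loss,
)

DIAG = LossWeights(ot_mode="diagonal")


class TestMseLoss:
    def test_zero_at_equality(self):
        assert mse_loss(np.ones(4), np.ones(4)) == 0.0

    def test_halved_square(self):
        assert mse_loss(np.array([2.0]), np.array([0.0])) == 2.0

    def test_symmetric(self, rng):
        a, b = rng.random(6), rng.random(6)
        assert mse_loss(a, b) == pytest.approx(mse_loss(b, a))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mse_loss(np.ones(3), np.ones(4))


class TestWassersteinLoss:
    def test_zero_at_equality_both_modes(self, tiny_features):
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        assert wasserstein_loss(x, x, tiny_features, DIAG) == 0.0
        sk = wasserstein_loss(x, x, tiny_features, LossWeights(sinkhorn_epsilon=0.01))
        assert sk == pytest.approx(0.0, abs=1e-4)

    def test_diagonal_mode_example(self, tiny_features):
        val = wasserstein_loss(np.array([1.0, 0.0]), np.array([0.0, 0.0]),
                               tiny_features, DIAG)
        assert val == pytest.approx(0.5)

    def test_diagonal_equals_twice_mse(self, rng, tiny_features):
        x, xh = rng.random(6), rng.random(6)
        assert wasserstein_loss(x, xh, tiny_features, DIAG) == pytest.approx(
            2.0 * mse_loss(x, xh))

    def test_sinkhorn_toy_matches_lp(self, rng):
        from _oracles import lp_transport_cost

        F = FusedFeatures(rng.normal(size=(3, 2)), DrugVocabulary.from_ids(list("abc")))
        x = np.array([1.0, 0.0, 1.0])
        xh = np.array([0.2, 0.5, 0.3])
        w = LossWeights(sinkhorn_epsilon=0.01, sinkhorn_max_iter=20000)
        got = wasserstein_loss(x, xh, F, w)
        cost = feature_cost(F)
        exact = lp_transport_cost(x / x.sum(), xh / xh.sum(), cost)
        assert got == pytest.approx(exact, rel=0.05, abs=1e-6)

    def test_all_zero_row_falls_back_to_uniform(self, tiny_features):
        with pytest.warns(RuntimeWarning, match="all-zero"):
            val = wasserstein_loss(np.zeros(6), np.full(6, 0.5), tiny_features,
                                   LossWeights(sinkhorn_epsilon=0.1))
        assert val == pytest.approx(0.0, abs=1e-6)


class TestKlRegularization:
    def test_standard_normal_is_zero(self):
        assert kl_regularization(LatentGaussian(np.zeros(3), np.ones(3))) == 0.0

    def test_unit_mean_shift(self):
        assert kl_regularization(LatentGaussian(np.array([1.0]), np.array([1.0]))) == 0.5

    @given(st.lists(st.floats(-3, 3), min_size=1, max_size=5),
           st.lists(st.floats(0.05, 5), min_size=1, max_size=5))
    @settings(deadline=None, derandomize=True)
    def test_nonnegative_everywhere(self, mus, sigmas):
        k = min(len(mus), len(sigmas))
        val = kl_regularization(LatentGaussian(np.array(mus[:k]), np.array(sigmas[:k])))
        assert val >= -1e-12

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            LatentGaussian(np.zeros(1), np.zeros(1))


class TestAuxiliaryLoss:
    def test_near_perfect_prediction(self):
        assert auxiliary_loss(np.array([1.0]), np.array([1 - 1e-7])) == pytest.approx(
            0.0, abs=1e-5)

    def test_half_prediction_gives_log_two(self):
        assert auxiliary_loss(np.array([1.0]), np.array([0.5])) == pytest.approx(np.log(2))

    def test_minimised_at_truth(self, rng):
        x = (rng.random(8) < 0.5).astype(float)
        at_truth = auxiliary_loss(x, np.clip(x, 1e-7, 1 - 1e-7))
        for _ in range(10):
            other = rng.random(8)
            assert auxiliary_loss(x, other) >= at_truth - 1e-9


class TestTotalLoss:
    def test_reduces_to_wasserstein(self, rng, tiny_features):
        x = (rng.random(6) < 0.5).astype(float)
        xh = rng.random(6)
        z = LatentGaussian(rng.normal(size=2), np.exp(rng.normal(size=2)))
        w = LossWeights(alpha=0.0, aux_weight=0.0, ot_mode="diagonal")
        assert total_loss(x, xh, z, tiny_features, w) == pytest.approx(
            wasserstein_loss(x, xh, tiny_features, w))

    def test_zero_at_perfect_reconstruction(self, tiny_features):
        x = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])
        z = LatentGaussian(np.zeros(2), np.ones(2))
        xh = np.clip(x, 1e-7, 1 - 1e-7)
        val = total_loss(x, xh, z, tiny_features, DIAG)
        assert val == pytest.approx(0.0, abs=1e-5)

    def test_linear_in_alpha(self, rng, tiny_features):
        x = (rng.random(6) < 0.5).astype(float)
        xh = np.clip(rng.random(6), 1e-6, 1 - 1e-6)
        z = LatentGaussian(rng.normal(size=2), np.exp(rng.normal(size=2)))
        vals = [total_loss(x, xh, z, tiny_features,
                           LossWeights(alpha=a, ot_mode="diagonal")) for a in (0.0, 1.0, 2.0)]
        assert vals[2] - vals[1] == pytest.approx(vals[1] - vals[0], rel=1e-9)


@pytest.fixture()
def tiny_problem(tiny_features, tiny_vocab):
    X = AssociationMatrix.from_pairs(
        [("dis0", "D0"), ("dis0", "D1"), ("dis1", "D3"), ("dis1", "D4"),
         ("dis2", "D0"), ("dis2", "D5")],
        ("dis0", "dis1", "dis2"), tiny_vocab)
    cfg = WVAEConfig(latent_dim=3, hidden_dim=8, dropout_rate=0.0,
                     epochs=150, learning_rate=5e-3, seed=2)
    return X, cfg


class TestWvaeModel:
    def test_output_length_and_range(self, tiny_features, tiny_problem):
        X, cfg = tiny_problem
        model = build_wvae(6, tiny_features, cfg)
        out = model.reconstruct(X.matrix)
        assert out.shape == (3, 6)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_same_seed_identical_initialisation(self, tiny_features, tiny_problem):
        _, cfg = tiny_problem
        m1 = build_wvae(6, tiny_features, cfg)
        m2 = build_wvae(6, tiny_features, cfg)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_feature_misalignment_raises(self, tiny_features):
        with pytest.raises(ValueError, match="align"):
            build_wvae(7, tiny_features)

    def test_deterministic_inference(self, tiny_features, tiny_problem):
        X, cfg = tiny_problem
        model = build_wvae(6, tiny_features, cfg)
        train_wvae(model, X, DIAG, epochs=20)
        r1 = model.reconstruct(X.matrix)
        r2 = model.reconstruct(X.matrix)
        assert np.array_equal(r1, r2)

    def test_gradients_match_finite_differences(self, tiny_features, tiny_problem):
        """Full backward pass (diagonal mode, fixed latent noise) against
        central differences through every parameter family."""
        X, cfg = tiny_problem
        model = build_wvae(6, tiny_features, cfg)
        noise = np.random.default_rng(9).standard_normal((3, cfg.latent_dim))

        class FixedNoise:
            def standard_normal(self, shape):
                return noise

        class Recorder:
            def step(self, grads):
                self.grads = grads

        weights = LossWeights(ot_mode="diagonal", alpha=0.3, aux_weight=0.2)

        def loss_value():
            model._train_rng = FixedNoise()
            rec = Recorder()
            total, *_ = model._epoch(X.matrix, weights, rec, diagonal_only=False)
            return total, rec.grads

        base, grads = loss_value()
        for name in sorted(model.params):
            w = model.params[name]
            idx = (0,) if w.ndim == 1 else (0, 0)
            eps = 1e-6
            w[idx] += eps
            up, _ = loss_value()
            w[idx] -= 2 * eps
            down, _ = loss_value()
            w[idx] += eps
            fd = (up - down) / (2 * eps)
            assert grads[name][idx] == pytest.approx(fd, rel=1e-4, abs=1e-7), name


class TestWvaeTraining:
    def test_loss_decreases_sinkhorn(self, tiny_features, tiny_problem):
        X, cfg = tiny_problem
        model = build_wvae(6, tiny_features, cfg)
        hist = train_wvae(model, X, LossWeights(sinkhorn_epsilon=0.1))
        assert hist.total[-1] < hist.total[0]
        assert np.all(np.isfinite(hist.total))

    def test_same_seed_reproducible(self, tiny_features, tiny_problem):
        X, cfg = tiny_problem
        h1 = train_wvae(build_wvae(6, tiny_features, cfg), X, DIAG)
        h2 = train_wvae(build_wvae(6, tiny_features, cfg), X, DIAG)
        assert h1.total[-1] == pytest.approx(h2.total[-1], abs=1e-12)

    def test_all_zero_targets_drive_scores_down(self, tiny_features, tiny_vocab):
        X = AssociationMatrix(np.zeros((3, 6)), ("a", "b", "c"), tiny_vocab)
        cfg = WVAEConfig(latent_dim=3, hidden_dim=8, dropout_rate=0.0,
                         epochs=800, learning_rate=1e-2, seed=2)
        model = build_wvae(6, tiny_features, cfg)
        train_wvae(model, X, LossWeights(alpha=0.0, aux_weight=1.0, ot_mode="diagonal"))
        assert model.reconstruct(X.matrix).max() < 0.1

    def test_pretraining_pass_runs(self, tiny_features, tiny_problem):
        X, cfg = tiny_problem
        cfg2 = WVAEConfig(**{**cfg.__dict__, "pretrain_epochs": 10, "epochs": 20})
        model = build_wvae(6, tiny_features, cfg2)
        hist = train_wvae(model, X, DIAG)
        assert len(hist.total) == 20


class TestPredict:
    def test_ranked_table_properties(self, tiny_features, tiny_vocab, tiny_problem):
        X, cfg = tiny_problem
        model = build_wvae(6, tiny_features, cfg)
        train_wvae(model, X, DIAG, epochs=30)
        table = predict(model, X.matrix[0], tiny_vocab, disease_id="dis0")
        scores = [r[2] for r in table.rows]
        ranks = [r[3] for r in table.rows]
        assert ranks == list(range(1, 7))
        assert scores == sorted(scores, reverse=True)
        assert all(0.0 <= s <= 1.0 for s in scores)
        known = {r[1] for r in table.rows if r[4]}
        assert known == {"D0", "D1"}

    def test_repeated_calls_identical(self, tiny_features, tiny_vocab, tiny_problem):
        X, cfg = tiny_problem
        model = build_wvae(6, tiny_features, cfg)
        train_wvae(model, X, DIAG, epochs=10)
        t1 = predict(model, X.matrix[0], tiny_vocab)
        t2 = predict(model, X.matrix[0], tiny_vocab)
        assert t1.rows == t2.rows

    def test_tie_break_by_vocabulary_order(self, tiny_vocab):
        F = FusedFeatures(np.zeros((6, 3)), tiny_vocab)
        model = build_wvae(6, F, WVAEConfig(latent_dim=2, hidden_dim=4, seed=0))
        # untrained zero-feature model scores every drug identically
        table = predict(model, np.zeros(6), tiny_vocab)
        assert [r[1] for r in table.rows] == list(tiny_vocab.ids)


class TestCheckpoint:
    def test_save_load_reproduces_scores(self, tiny_features, tiny_vocab,
                                         tiny_problem, tmp_path):
        from drugrepo.predictor import load_wvae, save_wvae

        X, cfg = tiny_problem
        model = build_wvae(6, tiny_features, cfg)
        train_wvae(model, X, DIAG, epochs=20)
        save_wvae(model, tmp_path / "ckpt", DIAG)
        restored = load_wvae(tmp_path / "ckpt", tiny_vocab)
        assert np.array_equal(restored.reconstruct(X.matrix),
                              model.reconstruct(X.matrix))

    def test_manifest_records_feature_hash(self, tiny_features, tiny_problem,
                                           tmp_path):
        import json

        from drugrepo.predictor import save_wvae

        X, cfg = tiny_problem
        model = build_wvae(6, tiny_features, cfg)
        save_wvae(model, tmp_path / "ckpt")
        manifest = json.loads((tmp_path / "ckpt" / "manifest.json").read_text())
        assert manifest["kind"] == "association_wvae"
        assert len(manifest["feature_sha256"]) == 64
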