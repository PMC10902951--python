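import numpy as np
import pytest

from pathsurv import objectives as obj
from pathsurv.data_io import DataError
from pathsurv.network import (
    ConfigError,
    NetworkConfig,
    backward,
    forward,
    init_model,
    load_checkpoint,
    make_dropout_masks,
    predict_risk,
    risk_input_gradient,
    save_checkpoint,
)
from conftest import random_mask, random_survival, randomized_state


def small_config(**kw):
    defaults = dict(n_hidden1=8, n_hidden2=6, n_embedding=3, seed=1)
    defaults.update(kw)
    return NetworkConfig(**defaults)


class TestInit:
    def test_layer_shapes_follow_mask(self, rng):
        mask = random_mask(rng, q=5, p=20)
        state = init_model(small_config(), mask)
        assert state.params["Ws"].shape == (20, 5)
        assert state.params["W1"].shape == (5, 8)
        assert state.params["V3"].shape == (8, 20)
        # masked entries carry no weight
        assert np.all(state.params["Ws"][state.mask_t == 0] == 0)

    def test_same_seed_same_weights(self, rng):
        mask = random_mask(rng)
        a = init_model(small_config(), mask)
        b = init_model(small_config(), mask)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_non_compressing_embedding_rejected(self, rng):
        mask = random_mask(rng)
        with pytest.raises(ConfigError, match="n_embedding"):
            init_model(small_config(n_embedding=6, n_hidden2=6), mask)


class TestForward:
    def test_zero_input_zero_bias_propagates_zero(self, rng):
        mask = random_mask(rng)
        state = init_model(small_config(), mask)
        out = forward(state, np.zeros((3, 20)))
        np.testing.assert_allclose(out.embedding, 0.0)
        np.testing.assert_allclose(out.risk, 0.0)
        np.testing.assert_allclose(out.reconstruction, 0.0)

    def test_masked_weight_is_inert(self, rng):
        mask = random_mask(rng)
        state = randomized_state(rng, mask)
        X = rng.normal(size=(4, 20))
        ref = forward(state, X)
        masked = np.argwhere(state.mask_t == 0)
        i, j = masked[0]
        state.params["Ws"][i, j] = 1e9
        out = forward(state, X)
        np.testing.assert_array_equal(out.risk, ref.risk)
        np.testing.assert_array_equal(out.reconstruction, ref.reconstruction)

    def test_deterministic_without_dropout(self, rng):
        state = randomized_state(rng, random_mask(rng))
        X = rng.normal(size=(4, 20))
        a, b = forward(state, X), forward(state, X)
        np.testing.assert_array_equal(a.risk, b.risk)
        np.testing.assert_array_equal(a.reconstruction, b.reconstruction)

    def test_shape_mismatch_rejected(self, rng):
        state = randomized_state(rng, random_mask(rng))
        with pytest.raises(DataError):
            forward(state, np.zeros((3, 7)))


class TestPredictRisk:
    def test_row_equivariance_and_length(self, rng):
        state = randomized_state(rng, random_mask(rng))
        X = rng.normal(size=(6, 20))
        risk = predict_risk(state, X)
        assert risk.shape == (6,)
        perm = rng.permutation(6)
        np.testing.assert_array_equal(predict_risk(state, X[perm]), risk[perm])

    def test_identical_patients_identical_scores(self, rng):
        state = randomized_state(rng, random_mask(rng))
        x = rng.normal(size=20)
        risk = predict_risk(state, np.vstack([x, x]))
        assert risk[0] == risk[1]


class TestGradients:
    def test_full_backward_matches_finite_differences(self, rng):
        """Analytic gradients of the weighted multitask loss vs central FD."""
        mask = random_mask(rng)
        state = randomized_state(rng, mask)
        n = 7
        X = rng.normal(size=(n, 20))
        surv = random_survival(rng, n)
        centers = rng.normal(size=(3, 3))
        masks = make_dropout_masks(
            np.random.default_rng(5), state.config, n=n, rate=0.3
        )
        out0 = forward(state, X, dropout_masks=masks)
        s0 = obj.target_distribution(obj.soft_assignment(out0.embedding, centers))

        def loss():
            out = forward(state, X, dropout_masks=masks)
            return obj.total_loss(
                obj.reconstruction_loss(X, out.reconstruction),
                obj.clustering_loss(s0, obj.soft_assignment(out.embedding, centers)),
                obj.cox_loss(out.risk, surv),
                gamma=1.0, beta=10.0,
            )

        out, cache = forward(state, X, dropout_masks=masks, return_cache=True)
        grads, _ = backward(
            state, cache,
            d_embedding=10.0 * obj.clustering_loss_grad_embedding(
                out.embedding, centers, s0
            ),
            d_reconstruction=obj.reconstruction_loss_grad(X, out.reconstruction),
            d_risk=obj.cox_loss_grad(out.risk, surv),
        )
        eps = 1e-6
        check_rng = np.random.default_rng(9)
        for k, v in state.params.items():
            flat = check_rng.choice(v.size, size=min(8, v.size), replace=False)
            for f in flat:
                idx = np.unravel_index(f, v.shape)
                old = v[idx]
                v[idx] = old + eps
                lp = loss()
                v[idx] = old - eps
                lm = loss()
                v[idx] = old
                fd = (lp - lm) / (2 * eps)
                assert grads[k][idx] == pytest.approx(fd, rel=1e-4, abs=1e-6), k

    def test_masked_weight_gradients_identically_zero(self, rng):
        mask = random_mask(rng)
        state = randomized_state(rng, mask)
        n = 6
        X = rng.normal(size=(n, 20))
        surv = random_survival(rng, n)
        out, cache = forward(state, X, return_cache=True)
        grads, _ = backward(
            state, cache,
            d_reconstruction=obj.reconstruction_loss_grad(X, out.reconstruction),
            d_risk=obj.cox_loss_grad(out.risk, surv),
        )
        assert np.all(grads["Ws"][state.mask_t == 0] == 0.0)

    def test_risk_input_gradient_matches_finite_differences(self, rng):
        state = randomized_state(rng, random_mask(rng))
        X = rng.normal(size=(3, 20))
        grad = risk_input_gradient(state, X)
        eps = 1e-6
        for i in range(3):
            for j in range(0, 20, 3):
                Xp, Xm = X.copy(), X.copy()
                Xp[i, j] += eps
                Xm[i, j] -= eps
                fd = (predict_risk(state, Xp)[i] - predict_risk(state, Xm)[i]) / (2 * eps)
                assert grad[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestReconstructionTraining:
    def test_autoencoder_path_learns_to_reconstruct(self, rng):
        """Fitting the reconstruction loss alone shrinks the error several-fold."""
        mask = random_mask(rng, q=2, p=6)
        state = randomized_state(rng, mask, n_hidden1=8, n_hidden2=6, n_embedding=4)
        # rank-2 data fits through the 4-dim bottleneck without loss
        X = rng.normal(size=(30, 2)) @ rng.normal(size=(2, 6))
        first = obj.reconstruction_loss(X, forward(state, X).reconstruction)
        for _ in range(800):
            out, cache = forward(state, X, return_cache=True)
            grads, _ = backward(
                state, cache,
                d_reconstruction=obj.reconstruction_loss_grad(X, out.reconstruction),
            )
            for k in grads:
                state.params[k] -= 1e-2 * grads[k]
        last = obj.reconstruction_loss(X, forward(state, X).reconstruction)
        assert last < 0.3 * first


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, rng):
        mask = random_mask(rng)
        state = randomized_state(rng, mask)
        state.k = 3
        state.centers = rng.normal(size=(3, 3))
        state.labels = rng.integers(3, size=10)
        path = tmp_path / "model.ckpt.npz"
        save_checkpoint(state, path)
        back = load_checkpoint(path)
        for k in state.params:
            np.testing.assert_array_equal(back.params[k], state.params[k])
        np.testing.assert_array_equal(back.centers, state.centers)
        assert back.k == 3
        assert back.mask.gene_ids == mask.gene_ids
        assert back.config == state.config
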