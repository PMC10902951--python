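import numpy as np
import pytest

from pathsurv.attribution import (
    AttributionConfig,
    adjust_uncertainty,
    attribute,
    gauss_legendre_unit,
    importance,
    integrated_gradients,
    mc_dropout_attributions,
    uncertainty,
)
from pathsurv.data_io import DataError, PathwayMask
from pathsurv.network import NetworkConfig, forward, init_model, predict_risk
from conftest import random_mask, randomized_state


def relu_gate_model():
    """Hand-built network computing F(x) = ReLU(x1 + x2 - 1)."""
    mask = PathwayMask(np.ones((1, 2)), ["P"], ["g1", "g2"])
    cfg = NetworkConfig(n_hidden1=1, n_hidden2=2, n_embedding=1, seed=0)
    state = init_model(cfg, mask)
    P = state.params
    P["Ws"][:] = 1.0
    P["bs"][:] = -1.0
    P["W1"][:] = 1.0
    P["b1"][:] = 0.0
    P["W2"][:] = np.array([[1.0, 0.0]])
    P["b2"][:] = 0.0
    P["W3"][:] = np.array([[1.0], [0.0]])
    P["b3"][:] = 0.0
    P["wr"][:] = 1.0
    P["br"][:] = 0.0
    return state


def linear_model(w):
    """Network reduced to F(x) = w . x for nonnegative inputs (single pathway,
    identity-like positive path)."""
    p = len(w)
    mask = PathwayMask(np.ones((1, p)), ["P"], [f"g{j}" for j in range(p)])
    cfg = NetworkConfig(n_hidden1=1, n_hidden2=2, n_embedding=1, seed=0)
    state = init_model(cfg, mask)
    P = state.params
    P["Ws"][:, 0] = np.asarray(w)
    P["bs"][:] = 0.0
    P["W1"][:] = 1.0
    P["b1"][:] = 0.0
    P["W2"][:] = np.array([[1.0, 0.0]])
    P["b2"][:] = 0.0
    P["W3"][:] = np.array([[1.0], [0.0]])
    P["b3"][:] = 0.0
    P["wr"][:] = 1.0
    P["br"][:] = 0.0
    return state


class TestIntegratedGradients:
    @pytest.mark.parametrize("method", ["exact", "gauss-legendre"])
    def test_linear_model_recovers_w_times_x(self, method):
        w = np.array([0.5, 2.0, -0.0, 1.5])  # keep w.x positive along the path
        state = linear_model(np.abs(w))
        x = np.array([[1.0, 0.5, 2.0, 1.0]])
        ig = integrated_gradients(
            state, x, AttributionConfig(method=method, n_quadrature=64)
        )
        np.testing.assert_allclose(ig[0], np.abs(w) * x[0], atol=1e-6)

    def test_relu_toy_matches_riemann_oracle(self):
        state = relu_gate_model()
        x = np.array([[1.0, 1.0]])
        ig = integrated_gradients(state, x, AttributionConfig(n_quadrature=64))
        # oracle: 1e5-step Riemann sum of the closed-form path gradient
        steps = 100000
        a = (np.arange(steps) + 0.5) / steps
        grad_along_path = (2 * a > 1).astype(float)  # dF/dx_i at alpha
        oracle = x[0] * grad_along_path.mean()
        np.testing.assert_allclose(ig[0], oracle, atol=1e-3)

    def test_completeness_on_trained_like_model(self, rng):
        state = randomized_state(rng, random_mask(rng))
        X = rng.normal(size=(5, 20))
        ig = integrated_gradients(state, X, AttributionConfig(n_quadrature=64))
        F = predict_risk(state, X)
        F0 = predict_risk(state, np.zeros((1, 20)))[0]
        np.testing.assert_allclose(
            ig.sum(axis=1), F - F0, rtol=1e-6, atol=1e-10
        )

    def test_quadrature_grid_convergence(self, rng):
        state = randomized_state(rng, random_mask(rng))
        X = rng.normal(size=(4, 20))
        a = integrated_gradients(state, X, AttributionConfig(n_quadrature=64))
        b = integrated_gradients(state, X, AttributionConfig(n_quadrature=256))
        assert np.max(np.abs(a - b)) < 1e-3 * max(np.max(np.abs(b)), 1.0)

    def test_gl_nodes_integrate_polynomials_exactly(self):
        nodes, weights = gauss_legendre_unit(8)
        for k in range(10):  # exact through degree 2*8-1
            assert np.sum(weights * nodes**k) == pytest.approx(1 / (k + 1), abs=1e-12)


class TestMcDropout:
    def test_zero_dropout_gives_identical_runs(self, rng):
        state = randomized_state(rng, random_mask(rng))
        X = rng.normal(size=(4, 20))
        cfg = AttributionConfig(n_mc_runs=5, dropout_rates=(0.0,), n_quadrature=16)
        runs = mc_dropout_attributions(state, X, cfg)
        assert runs.shape == (5, 20)
        for t in range(1, 5):
            np.testing.assert_array_equal(runs[t], runs[0])

    def test_fixed_seed_reproduces_matrix(self, rng):
        state = randomized_state(rng, random_mask(rng))
        X = rng.normal(size=(4, 20))
        cfg = AttributionConfig(n_mc_runs=4, dropout_rates=(0.3,), n_quadrature=16, seed=7)
        np.testing.assert_array_equal(
            mc_dropout_attributions(state, X, cfg),
            mc_dropout_attributions(state, X, cfg),
        )

    def test_too_few_runs_rejected(self):
        with pytest.raises(DataError):
            AttributionConfig(n_mc_runs=1)

    def test_completeness_holds_per_thinned_network(self, rng):
        """Each frozen dropout realization is itself a ReLU network, so the
        completeness axiom holds run by run."""
        from pathsurv.network import make_dropout_masks

        state = randomized_state(rng, random_mask(rng))
        X = rng.normal(size=(3, 20))
        for s in range(3):
            masks = make_dropout_masks(
                np.random.default_rng(s), state.config, n=None, rate=0.4
            )
            ig = integrated_gradients(state, X, dropout_masks=masks)
            F = forward(state, X, dropout_masks=masks).risk
            F0 = forward(state, np.zeros((1, 20)), dropout_masks=masks).risk[0]
            np.testing.assert_allclose(ig.sum(axis=1), F - F0, rtol=1e-6, atol=1e-9)


class TestUncertainty:
    def test_identical_runs_give_zero(self):
        runs = np.tile([[1.0, -2.0, 0.5]], (4, 1))
        u, unstable = uncertainty(runs)
        np.testing.assert_array_equal(u, 0.0)
        assert not unstable.any()

    def test_hand_computed_cv(self):
        runs = np.array([[1.0], [3.0]])
        u, _ = uncertainty(runs)
        assert u[0] == pytest.approx(np.sqrt(2) / 2, abs=1e-4)  # 0.7071

    def test_near_zero_mean_capped_and_flagged(self):
        runs = np.array([[1e-12], [-1e-12]])
        u, unstable = uncertainty(runs)
        assert unstable[0]
        assert np.isfinite(u[0])

    def test_sign_flipping_genes_get_high_uncertainty(self, rng):
        stable = rng.normal(1.0, 0.05, size=(10, 5))
        flipping = rng.normal(0.0, 1.0, size=(10, 5))
        u, _ = uncertainty(np.hstack([stable, flipping]))
        assert np.median(u[5:]) > np.median(u)


class TestAdjustAndImportance:
    def test_minmax_endpoints(self):
        u = np.array([0.0, 1.0, 4.0])
        ua = adjust_uncertainty(u)
        assert ua[0] == 0.0 and ua[2] == 1.0
        assert np.all(np.diff(ua) > 0)  # monotone in U

    def test_all_equal_maps_to_zero(self):
        np.testing.assert_array_equal(adjust_uncertainty(np.full(5, 2.0)), 0.0)

    def test_importance_arithmetic_and_ranking(self):
        v, rank = importance(np.array([2.0, -3.0, 1.0]), np.array([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(v, [2.0, -1.5, 0.0])
        np.testing.assert_array_equal(rank, [1, 2, 3])

    def test_full_discount_zeroes_importance(self):
        v, _ = importance(np.array([5.0, -7.0]), np.array([1.0, 1.0]))
        np.testing.assert_array_equal(v, 0.0)

    def test_tie_break_by_gene_index(self):
        v, rank = importance(np.array([1.0, -1.0, 1.0]), np.zeros(3))
        np.testing.assert_array_equal(rank, [1, 2, 3])


def test_attribute_zero_dropout_reduces_to_plain_ig(rng):
    state = randomized_state(rng, random_mask(rng))
    X = rng.normal(size=(4, 20))
    cfg = AttributionConfig(n_mc_runs=3, dropout_rates=(0.0,), n_quadrature=32)
    res = attribute(state, X, cfg)
    ig = integrated_gradients(state, X, cfg).mean(axis=0)
    np.testing.assert_array_equal(res.uncertainty, 0.0)
    np.testing.assert_array_equal(res.adjusted_uncertainty, 0.0)
    np.testing.assert_array_equal(res.importance, ig)
    frame = res.to_frame()
    assert list(frame.columns) == [
        "gene", "mean_IG", "U", "U_adj", "V", "rank", "unstable_flag"
    ]
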