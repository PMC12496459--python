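import numpy as np
import pytest

from kneeload.errors import ArgumentError, NumericalError, StateError
from kneeload.graph import ServeGraph, complete_edge_index
from kneeload.lrp import (
    RelevanceMap,
    aggregate_and_normalize,
    explain,
    lrp_gcn,
    lrp_gru_step,
    lrp_linear,
    phase_contribution_summary,
)
from kneeload.model import ModelConfig, MomentNet


def _graph(X: np.ndarray, self_loops_only: bool = False) -> ServeGraph:
    n = X.shape[0]
    if self_loops_only:
        ei = np.stack([np.arange(n), np.arange(n)])
    else:
        ei = complete_edge_index(n)
    return ServeGraph(
        node_features=X,
        edge_index=ei,
        edge_attr=np.ones(ei.shape[1]),
        target=np.zeros(n),
    )


def _bias_free_net(cfg: ModelConfig, n_features: int) -> MomentNet:
    net = MomentNet(cfg, n_features=n_features)
    for key, value in net.params.items():
        if key.endswith("_b") or key.startswith("b") or key == "head_b":
            net.params[key] = np.zeros_like(value)
    return net


class TestLrpLinear:
    def test_conservation_without_bias(self):
        rng = np.random.default_rng(0)
        x, W = rng.normal(size=5), rng.normal(size=(5, 4))
        R_out = rng.normal(size=4)
        R_in = lrp_linear(x, W, np.zeros(4), R_out, epsilon=0.0)
        assert R_in.sum() == pytest.approx(R_out.sum(), abs=1e-9)

    def test_single_output_proportional_to_contribution(self):
        x = np.array([1.0, 2.0, 3.0])
        W = np.array([[0.5], [0.25], [1.0]])
        R_in = lrp_linear(x, W, np.zeros(1), np.array([4.0]), epsilon=0.0)
        contrib = x * W[:, 0]
        np.testing.assert_allclose(R_in, 4.0 * contrib / contrib.sum(), atol=1e-12)

    def test_brute_force_oracle_4x3(self):
        rng = np.random.default_rng(1)
        x, W, b = rng.normal(size=4), rng.normal(size=(4, 3)), rng.normal(size=3)
        R_out = rng.normal(size=3)
        eps = 1e-3
        R_in = lrp_linear(x, W, b, R_out, epsilon=eps)
        z = np.array([sum(x[i] * W[i, j] for i in range(4)) + b[j] for j in range(3)])
        expected = np.zeros(4)
        for i in range(4):
            for j in range(3):
                denom = z[j] + eps * (1.0 if z[j] >= 0 else -1.0)
                expected[i] += x[i] * W[i, j] / denom * R_out[j]
        np.testing.assert_allclose(R_in, expected, atol=1e-12)

    def test_zero_preactivation_with_zero_epsilon_raises(self):
        x = np.array([1.0, -1.0])
        W = np.array([[1.0], [1.0]])  # z = 0
        with pytest.raises(NumericalError):
            lrp_linear(x, W, np.zeros(1), np.array([1.0]), epsilon=0.0)


class TestLrpGruStep:
    @staticmethod
    def _weights(rng, D, H):
        return {
            "Wxh": rng.normal(size=(D, H)),
            "Whh": rng.normal(size=(H, H)),
            "bh": np.zeros(H),
        }

    @staticmethod
    def _cache(rng, D, H, z_value=None):
        cache = {
            "r": rng.uniform(0.1, 0.9, H),
            "z": rng.uniform(0.1, 0.9, H) if z_value is None else np.full(H, z_value),
            "hcand": rng.uniform(-0.9, 0.9, H),
            "h_prev": rng.normal(size=H),
            "x": rng.normal(size=D),
        }
        return cache

    def test_update_gate_one_sends_all_through_candidate(self):
        rng = np.random.default_rng(2)
        D, H = 3, 4
        weights = self._weights(rng, D, H)
        cache = self._cache(rng, D, H, z_value=1.0)
        R_ht = rng.normal(size=H)
        R_h_prev, R_x = lrp_gru_step(cache, weights, R_ht, epsilon=1e-9)
        # carry path gets nothing; conservation holds through the candidate
        assert (R_h_prev.sum() + R_x.sum()) == pytest.approx(R_ht.sum(), abs=1e-6)
        cache_no_hidden = dict(cache, h_prev=np.zeros(H))
        _, R_x_only = lrp_gru_step(cache_no_hidden, weights, R_ht, epsilon=1e-9)
        assert R_x_only.sum() == pytest.approx(R_ht.sum(), abs=1e-6)

    def test_update_gate_zero_passes_relevance_back_unchanged(self):
        rng = np.random.default_rng(3)
        D, H = 3, 4
        weights = self._weights(rng, D, H)
        cache = self._cache(rng, D, H, z_value=0.0)
        R_ht = rng.normal(size=H)
        R_h_prev, R_x = lrp_gru_step(cache, weights, R_ht, epsilon=1e-12)
        np.testing.assert_allclose(R_h_prev, R_ht, atol=1e-6)
        np.testing.assert_allclose(R_x, 0.0, atol=1e-12)

    def test_conservation_on_toy_gru(self):
        # 3-unit, 2-step bias-free toy network: total relevance is conserved
        # across both unrolled steps
        rng = np.random.default_rng(4)
        cfg = ModelConfig(
            baseline_mode=True, gru_width=3, scale_inputs=False,
            scale_target=False, seed=8,
        )
        net = _bias_free_net(cfg, n_features=2)
        X = rng.normal(size=(2, 2))
        g = _graph(X, self_loops_only=True)
        cache = net.forward_cached(g)
        weights = {"Wxh": net.params["Wxh"], "Whh": net.params["Whh"], "bh": net.params["bh"]}
        R_h1 = rng.normal(size=3)
        total_in = R_h1.sum()
        step1 = {
            "r": cache["r"][1], "z": cache["z"][1], "hcand": cache["hcand"][1],
            "h_prev": cache["h_prev"][1], "x": cache["gru_input"][1],
        }
        R_h0, R_x1 = lrp_gru_step(step1, weights, R_h1, epsilon=1e-12)
        step0 = {
            "r": cache["r"][0], "z": cache["z"][0], "hcand": cache["hcand"][0],
            "h_prev": cache["h_prev"][0], "x": cache["gru_input"][0],
        }
        R_hm1, R_x0 = lrp_gru_step(step0, weights, R_h0, epsilon=1e-12)
        total_out = R_hm1.sum() + R_x0.sum() + R_x1.sum()
        assert total_out == pytest.approx(total_in, rel=1e-9, abs=1e-9)

    def test_missing_cache_raises_state_error(self):
        with pytest.raises(StateError):
            lrp_gru_step({"r": np.ones(2)}, {}, np.ones(2))


class TestLrpGcn:
    def test_single_node_equals_lrp_linear(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(1, 4))
        g = _graph(X, self_loops_only=True)
        W, b = rng.normal(size=(4, 3)), rng.normal(size=3)
        R_out = rng.normal(size=(1, 3))
        got = lrp_gcn(g, X, W, b, R_out, epsilon=1e-6)
        expected = lrp_linear(X[0], W, b, R_out[0], epsilon=1e-6)
        np.testing.assert_allclose(got[0], expected, atol=1e-12)

    def test_conservation_zero_bias(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(7, 4))
        g = _graph(X)
        W = rng.normal(size=(4, 5))
        R_out = rng.normal(size=(7, 5))
        R_in = lrp_gcn(g, X, W, np.zeros(5), R_out, epsilon=0.0)
        assert R_in.sum() == pytest.approx(R_out.sum(), abs=1e-9)

    def test_three_node_dense_oracle(self):
        # explicit epsilon rule on the flattened dense map (A_hat kron W)
        rng = np.random.default_rng(7)
        n, F, K = 3, 2, 2
        X = rng.normal(size=(n, F))
        g = _graph(X)
        W = rng.normal(size=(F, K))
        b = rng.normal(size=K)
        R_out = rng.normal(size=(n, K))
        eps = 1e-4

        A = np.zeros((n, n))
        A[g.edge_index[0], g.edge_index[1]] = 1.0
        np.fill_diagonal(A, 1.0)
        deg = A.sum(1)
        a_hat = A / np.sqrt(np.outer(deg, deg))
        big_W = np.kron(a_hat, W)  # maps flattened X (n*F) -> flattened out (n*K)
        x_flat = X.ravel()
        big_b = np.tile(b, n)
        z = x_flat @ big_W + big_b
        expected_flat = np.zeros(n * F)
        for i in range(n * F):
            for j in range(n * K):
                denom = z[j] + eps * (1.0 if z[j] >= 0 else -1.0)
                expected_flat[i] += x_flat[i] * big_W[i, j] / denom * R_out.ravel()[j]
        got = lrp_gcn(g, X, W, b, R_out, epsilon=eps)
        np.testing.assert_allclose(got, expected_flat.reshape(n, F), atol=1e-9)


class TestExplain:
    @staticmethod
    def _trained_free_net(n=9, F=4, seed=0, bias_free=True):
        rng = np.random.default_rng(seed)
        cfg = ModelConfig(
            n_gcn_layers=2, gcn_width=5, gru_width=6, seed=seed,
            scale_inputs=False, scale_target=False,
        )
        net = _bias_free_net(cfg, F) if bias_free else MomentNet(cfg, F)
        g = _graph(rng.normal(size=(n, F)))
        return net, g

    def test_output_shape(self, one_graph):
        net = MomentNet(ModelConfig(gcn_width=8, gru_width=8, seed=1))
        rmap = explain(net, one_graph)
        assert rmap.raw.shape == (101, 6)
        assert rmap.normalized.shape == (101, 6)

    def test_end_to_end_conservation_bias_free(self):
        net, g = self._trained_free_net()
        rmap = explain(net, g, epsilon=1e-9)
        total_in = rmap.explained_output["total_initial_relevance"]
        assert rmap.raw.sum() == pytest.approx(total_in, rel=1e-4)

    def test_zero_feature_receives_zero_relevance(self):
        net, g = self._trained_free_net()
        g.node_features[:, 2] = 0.0
        rmap = explain(net, g, epsilon=1e-9)
        np.testing.assert_allclose(rmap.raw[:, 2], 0.0, atol=1e-12)

    def test_normalized_in_unit_interval_with_max_one(self):
        net, g = self._trained_free_net(bias_free=False)
        rmap = explain(net, g)
        assert rmap.normalized.min() >= 0.0
        assert rmap.normalized.max() == pytest.approx(1.0)

    def test_uniform_output_seeding(self):
        net, g = self._trained_free_net(bias_free=False)
        rmap = explain(net, g, output_weights=np.ones(g.n_nodes))
        assert rmap.explained_output["seeding"] == "custom"
        assert rmap.explained_output["total_initial_relevance"] == pytest.approx(g.n_nodes)


class TestAggregateAndNormalize:
    @staticmethod
    def _maps(rng, count=3, shape=(101, 6)):
        return [
            RelevanceMap(
                raw=rng.normal(size=shape),
                normalized=np.zeros(shape),
                epsilon=1e-6,
                explained_output={},
            )
            for _ in range(count)
        ]

    def test_global_range(self):
        rng = np.random.default_rng(8)
        out = aggregate_and_normalize(self._maps(rng))
        assert out.min() == 0.0
        assert out.max() == pytest.approx(1.0)

    def test_constant_maps_give_zeros(self):
        maps = [
            RelevanceMap(
                raw=np.full((101, 6), 3.0),
                normalized=np.zeros((101, 6)),
                epsilon=0.0,
                explained_output={},
            )
        ]
        np.testing.assert_array_equal(aggregate_and_normalize(maps), np.zeros((101, 6)))

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        maps = self._maps(rng)
        base = aggregate_and_normalize(maps)
        scaled = [
            RelevanceMap(
                raw=7.0 * m.raw, normalized=m.normalized, epsilon=m.epsilon,
                explained_output={},
            )
            for m in maps
        ]
        np.testing.assert_allclose(aggregate_and_normalize(scaled), base, atol=1e-12)

    def test_per_feature_method(self):
        rng = np.random.default_rng(10)
        out = aggregate_and_normalize(self._maps(rng), method="per_feature")
        for j in range(6):
            assert out[:, j].max() == pytest.approx(1.0)
            assert out[:, j].min() == 0.0

    def test_empty_collection_rejected(self):
        with pytest.raises(ArgumentError):
            aggregate_and_normalize([])


def test_phase_contribution_summary_matches_direct_average():
    rng = np.random.default_rng(11)
    curves = rng.uniform(size=(101, 6))
    labels = np.array(["PP"] * 40 + ["FP"] * 30 + ["LP"] * 31, dtype=object)
    table = phase_contribution_summary(curves, labels)
    np.testing.assert_allclose(table["PP"].to_numpy(), curves[:40].mean(axis=0))
    np.testing.assert_allclose(table["FP"].to_numpy(), curves[40:70].mean(axis=0))
    np.testing.assert_allclose(table["LP"].to_numpy(), curves[70:].mean(axis=0))
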