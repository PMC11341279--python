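"""Moment aggregation, attention gating, residual mixing, and the estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

import hhomr as hh
from hhomr.autodiff import Tensor
from hhomr.embedding import TopoEmbedding
from hhomr.exceptions import UnknownIdError

from conftest import brute_force_neighbor_mean, brute_force_neighbor_std, random_hetero_graph


class TestSignedRoot:
    @pytest.mark.parametrize(
        "value,order,expected",
        [(0.09, 2, 0.3), (-0.008, 3, -0.2), (0.5, 1, 0.5), (-0.7, 1, -0.7)],
    )
    def test_examples(self, value, order, expected):
        assert hh.signed_root(value, order, eps=0.0) == pytest.approx(expected, abs=1e-12)

    def test_odd_order_preserves_sign(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=50)
        assert np.all(np.sign(hh.signed_root(s, 3, eps=0.0)) == np.sign(s))


class TestProjectAndConcat:
    def test_identity_projection_with_zero_topo(self):
        fm = np.array([[1.0, 2.0], [3.0, 4.0]])
        fd = np.array([[5.0, 6.0]])
        topo = TopoEmbedding(ids=[0, 1, 2], vectors=np.zeros((3, 2)))
        out = hh.project_and_concat(fm, fd, topo, np.eye(2), np.eye(2))
        assert np.array_equal(out[:, :2], np.vstack([fm, fd]))
        assert np.array_equal(out[:, 2:], np.zeros((3, 2)))

    def test_default_width_is_128(self, toy_graph):
        cfg = hh.ModelConfig(layers=1, moment_order=1)
        params = hh.init_parameters(cfg, 2, 1)
        topo = TopoEmbedding(ids=list(range(3)), vectors=np.zeros((3, 64)))
        out = hh.project_and_concat(
            toy_graph.mirna_features, toy_graph.disease_features, topo,
            params["W_m"].data, params["W_d"].data,
        )
        assert out.shape == (3, 128)

    def test_width_mismatch_rejected(self):
        topo = TopoEmbedding(ids=[0, 1], vectors=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            hh.project_and_concat(np.ones((1, 3)), np.ones((1, 2)), topo, np.eye(2), np.eye(2))


class TestMoments:
    def test_origin_first_order_is_neighbor_mean(self, toy_graph):
        h = np.array([0.2, 0.8, 0.0])
        out = hh.origin_moment(h, toy_graph, k=1)
        assert out[2, 0] == pytest.approx(0.5, abs=1e-12)

    def test_origin_second_order_example(self, toy_graph):
        out = hh.origin_moment(np.array([0.2, 0.8, 0.0]), toy_graph, k=2)
        assert out[2, 0] == pytest.approx(np.sqrt(0.34), abs=1e-12)

    def test_central_first_order_vanishes(self, toy_graph):
        out = hh.central_moment(np.array([0.3, 0.9, 0.0]), toy_graph, k=1)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_central_second_order_is_population_std(self, toy_graph):
        out = hh.central_moment(np.array([0.2, 0.8, 0.0]), toy_graph, k=2)
        assert out[2, 0] == pytest.approx(0.3, abs=1e-12)

    def test_zero_spread_neighborhood(self, toy_graph):
        for k in (1, 2, 3):
            out = hh.central_moment(np.array([0.1, 0.1, 0.0]), toy_graph, k=k)
            assert out[2, 0] == pytest.approx(0.0, abs=1e-12)

    def test_isolated_node_gets_zero_vector(self):
        graph = hh.HeteroGraph(
            mirna_ids=["m0", "m1"], disease_ids=["d0"],
            edge_index=np.array([[0, 2]]),
            mirna_features=np.zeros((2, 1)), disease_features=np.zeros((1, 1)),
        )
        out = hh.origin_moment(np.array([1.0, 2.0, 3.0]), graph, k=2)
        assert out[1, 0] == 0.0

    def test_moments_match_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            graph = random_hetero_graph(rng)
            h = rng.normal(size=(graph.n_nodes, 4))
            assert np.allclose(
                hh.origin_moment(h, graph, 1), brute_force_neighbor_mean(graph, h), atol=1e-12
            )
            assert np.allclose(
                hh.central_moment(h, graph, 2), brute_force_neighbor_std(graph, h), atol=1e-12
            )

    def test_equal_means_unequal_variances_distinguished(self):
        """Mean aggregation cannot separate two nodes whose neighbor features
        share a mean but differ in spread; the second central moment can."""
        graph = hh.HeteroGraph(
            mirna_ids=["m0", "m1", "m2", "m3"], disease_ids=["dA", "dB"],
            edge_index=np.array([[0, 4], [1, 4], [2, 5], [3, 5]]),
            mirna_features=np.zeros((4, 1)), disease_features=np.zeros((2, 1)),
        )
        h = np.array([0.2, 0.8, 0.4, 0.6, 0.0, 0.0])  # means .5/.5, stds .3/.1
        mean_slice = hh.origin_moment(h, graph, 1)
        std_slice = hh.central_moment(h, graph, 2)
        assert mean_slice[4, 0] == pytest.approx(mean_slice[5, 0], abs=1e-12)
        assert abs(std_slice[4, 0] - std_slice[5, 0]) > 0.1


class TestAttentionAndFusion:
    def test_zero_mixing_matrix_gives_half_gates(self):
        gate = hh.element_attention([0.4], [0.9], [[1.0]], [[1.0]], np.zeros((2, 1)))
        assert gate[0, 0] == pytest.approx(0.5)

    def test_scalar_example(self):
        gate = hh.element_attention([1.0], [1.0], [[1.0]], [[1.0]], [[1.0], [1.0]])
        assert gate[0, 0] == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-10)

    def test_gates_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(2)
        gate = hh.element_attention(
            rng.normal(size=(5, 3)), rng.normal(size=(5, 3)),
            rng.normal(size=(3, 3)), rng.normal(size=(3, 3)), rng.normal(size=(6, 3)),
        )
        assert np.all(gate > 0) and np.all(gate < 1)

    def test_aggregate_single_unit_gate(self):
        m = np.array([[1.0, -2.0]])
        assert np.array_equal(hh.aggregate_moments([np.ones_like(m)], [m]), m)

    def test_aggregate_weighted_sum_example(self):
        out = hh.aggregate_moments(
            [np.array([[0.5]]), np.array([[0.25]])], [np.array([[2.0]]), np.array([[4.0]])]
        )
        assert out[0, 0] == pytest.approx(2.0)

    def test_aggregate_zero_gates(self):
        m = np.ones((2, 3))
        assert np.all(hh.aggregate_moments([np.zeros_like(m)], [m]) == 0)

    def test_aggregate_misalignment_rejected(self):
        with pytest.raises(ValueError):
            hh.aggregate_moments([np.ones((2, 2))], [np.ones((2, 3))])

    @pytest.mark.parametrize(
        "beta,gamma,expected", [(1.0, 0.0, 2.0), (0.0, 1.0, 4.0), (0.5, 0.5, 3.0)]
    )
    def test_residual_examples(self, beta, gamma, expected):
        out = hh.residual_fuse(np.array([2.0]), np.array([4.0]), beta, gamma)
        assert out[0] == pytest.approx(expected)

    def test_residual_shape_mismatch(self):
        with pytest.raises(ValueError):
            hh.residual_fuse(np.ones(2), np.ones(3))


def _identity_moment_params(cfg, n_feat_m, n_feat_d):
    """Parameters whose moment projections are identities (for reductions)."""
    params = hh.init_parameters(cfg, n_feat_m, n_feat_d)
    eye = np.eye(cfg.hidden_dim)
    for layer in range(cfg.layers):
        for slot in range(len(cfg.moment_slots())):
            params[f"W_mom_{layer}_{slot}"].data = eye.copy()
    return params


class TestForward:
    def test_reduces_to_mean_aggregation(self):
        """K=1 origin moments with unit gates and a pure processed path is a
        plain neighborhood-mean layer."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            graph = random_hetero_graph(rng, feature_dim=3)
            topo = TopoEmbedding(
                ids=list(range(graph.n_nodes)), vectors=rng.normal(size=(graph.n_nodes, 2))
            )
            cfg = hh.ModelConfig(
                layers=1, moment_order=1, proj_dim=3, hidden_dim=5, beta=1.0, gamma=0.0, eps=0.0
            )
            params = _identity_moment_params(cfg, 3, 3)
            h0 = hh.project_and_concat(
                graph.mirna_features, graph.disease_features, topo,
                params["W_m"].data, params["W_d"].data,
            )
            out = hh.forward(graph, topo, cfg, params, attention_override=1.0)
            assert np.allclose(out, brute_force_neighbor_mean(graph, h0), atol=1e-9)

    def test_matches_manual_composition_of_operations(self):
        """One attention layer equals the hand-wired chain of the public ops."""
        rng = np.random.default_rng(3)
        graph = random_hetero_graph(rng, feature_dim=3)
        topo = TopoEmbedding(
            ids=list(range(graph.n_nodes)), vectors=rng.normal(size=(graph.n_nodes, 2))
        )
        cfg = hh.ModelConfig(layers=1, moment_order=2, moment_family="hybrid",
                             proj_dim=3, hidden_dim=5, beta=0.7, gamma=0.3)
        params = hh.init_parameters(cfg, 3, 3)
        h0 = hh.project_and_concat(
            graph.mirna_features, graph.disease_features, topo,
            params["W_m"].data, params["W_d"].data,
        )
        moments, gates = [], []
        for slot, (family, k) in enumerate(cfg.moment_slots()):
            fn = hh.origin_moment if family == "origin" else hh.central_moment
            m = fn(h0, graph, k, W=params[f"W_mom_0_{slot}"].data, eps=cfg.eps)
            moments.append(m)
            gates.append(
                hh.element_attention(
                    h0, m, params["W_q_0"].data, params[f"W_key_0_{slot}"].data,
                    params["W_alpha_0"].data,
                )
            )
        expected = hh.residual_fuse(
            hh.aggregate_moments(gates, moments), h0, cfg.beta, cfg.gamma
        )
        assert np.allclose(hh.forward(graph, topo, cfg, params), expected, atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        graph = random_hetero_graph(rng, feature_dim=3)
        topo_vecs = rng.normal(size=(graph.n_nodes, 2))
        cfg = hh.ModelConfig(layers=2, moment_order=2, proj_dim=3, hidden_dim=5)
        params = hh.init_parameters(cfg, 3, 3)

        perm_m = rng.permutation(graph.n_mirnas)
        perm_d = rng.permutation(graph.n_diseases)
        node_perm = np.concatenate([perm_m, graph.n_mirnas + perm_d])
        inverse = np.argsort(node_perm)
        remapped_edges = np.stack(
            [inverse[graph.edge_index[:, 0]], inverse[graph.edge_index[:, 1]]], axis=1
        )
        permuted = hh.HeteroGraph(
            mirna_ids=[graph.mirna_ids[i] for i in perm_m],
            disease_ids=[graph.disease_ids[j] for j in perm_d],
            edge_index=remapped_edges,
            mirna_features=graph.mirna_features[perm_m],
            disease_features=graph.disease_features[perm_d],
        )
        out = hh.forward(graph, topo := TopoEmbedding(list(range(graph.n_nodes)), topo_vecs),
                         cfg, params)
        out_perm = hh.forward(
            permuted, TopoEmbedding(list(range(graph.n_nodes)), topo_vecs[node_perm]),
            cfg, params,
        )
        assert np.allclose(out_perm, out[node_perm], atol=1e-10)

    def test_deterministic_for_fixed_inputs(self, toy_graph):
        cfg = hh.ModelConfig(layers=2, moment_order=2, proj_dim=2, hidden_dim=4, seed=1)
        params = hh.init_parameters(cfg, 2, 1)
        topo = TopoEmbedding(ids=[0, 1, 2], vectors=np.ones((3, 2)))
        a = hh.forward(toy_graph, topo, cfg, params)
        b = hh.forward(toy_graph, topo, cfg, params)
        assert np.array_equal(a, b)

    def test_zero_layer_config_forbidden(self):
        with pytest.raises(ValueError):
            hh.ModelConfig(layers=0)

    def test_degenerate_residual_weights_forbidden(self):
        with pytest.raises(ValueError):
            hh.ModelConfig(beta=0.0, gamma=0.0)


class TestScorePairs:
    def _params(self):
        cfg = hh.ModelConfig(layers=1, moment_order=1, proj_dim=2, hidden_dim=4)
        return cfg, hh.init_parameters(cfg, 2, 1)

    def test_zero_weight_mlp_scores_half(self):
        cfg, params = self._params()
        for name in ("W_mlp1", "b_mlp1", "W_mlp2", "b_mlp2"):
            params[name].data[...] = 0.0
        scores = hh.score_pairs(np.ones((3, 4)), np.array([[0, 2], [1, 2]]), params)
        assert np.allclose(scores, 0.5)

    def test_scores_inside_unit_interval(self):
        _, params = self._params()
        rng = np.random.default_rng(0)
        scores = hh.score_pairs(rng.normal(size=(3, 4)), np.array([[0, 2], [1, 2]]), params)
        assert np.all((scores > 0) & (scores < 1))

    def test_identical_embeddings_swap_invariance(self):
        _, params = self._params()
        emb = np.ones((3, 4))
        emb[1] = emb[0]
        scores = hh.score_pairs(emb, np.array([[0, 2], [1, 2]]), params)
        assert scores[0] == scores[1]

    def test_unknown_index_rejected(self):
        _, params = self._params()
        with pytest.raises(UnknownIdError):
            hh.score_pairs(np.ones((3, 4)), np.array([[0, 7]]), params)


class TestMomentGNNEstimator:
    def test_sklearn_param_round_trip(self):
        est = hh.MomentGNN(n_layers=2, moment_order=3)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_single_label_training_rejected(self, bundle, fast_walks):
        topo = hh.embed_graph(bundle.graph, fast_walks)
        X = bundle.pairs.index_pairs(bundle.graph)
        with pytest.raises(ValueError):
            hh.MomentGNN().fit(X[:10], np.ones(10), graph=bundle.graph, topo=topo)

    def test_training_reduces_loss_and_is_deterministic(self, small_bundle, fast_walks, fast_model):
        topo = hh.embed_graph(small_bundle.graph, fast_walks)
        X = small_bundle.pairs.index_pairs(small_bundle.graph)
        y = small_bundle.pairs.labels
        a = clone(fast_model).fit(X, y, graph=small_bundle.graph, topo=topo)
        assert a.loss_trace_[-1] < a.loss_trace_[0]
        b = clone(fast_model).fit(X, y, graph=small_bundle.graph, topo=topo)
        assert np.allclose(a.loss_trace_, b.loss_trace_, atol=1e-6)
        assert np.array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_predict_proba_shape_and_threshold(self, small_bundle, fast_walks, fast_model):
        topo = hh.embed_graph(small_bundle.graph, fast_walks)
        X = small_bundle.pairs.index_pairs(small_bundle.graph)
        est = clone(fast_model).fit(X, small_bundle.pairs.labels,
                                    graph=small_bundle.graph, topo=topo)
        proba = est.predict_proba(X)
        assert proba.shape == (len(X), 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert np.array_equal(est.predict(X), (proba[:, 1] >= 0.5).astype(int))

    def test_checkpoint_round_trip(self, small_bundle, fast_walks, fast_model, tmp_path):
        topo = hh.embed_graph(small_bundle.graph, fast_walks)
        X = small_bundle.pairs.index_pairs(small_bundle.graph)
        est = clone(fast_model).fit(X, small_bundle.pairs.labels,
                                    graph=small_bundle.graph, topo=topo)
        est.save(tmp_path / "ckpt.npz")
        restored = hh.MomentGNN.load(tmp_path / "ckpt.npz", graph=small_bundle.graph, topo=topo)
        assert np.array_equal(restored.predict_proba(X), est.predict_proba(X))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    s=st.floats(min_value=-100, max_value=100, allow_nan=False),
    k=st.integers(min_value=1, max_value=9),
)
def test_signed_root_sign_and_magnitude_properties(s, k):
    """sign is preserved and the magnitude is the (stabilised) k-th root."""
    out = float(hh.signed_root(s, k, eps=1e-8))
    assert np.sign(out) == np.sign(s)
    if s != 0:
        assert abs(out) == pytest.approx((abs(s) + 1e-8) ** (1 / k), rel=1e-12)
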