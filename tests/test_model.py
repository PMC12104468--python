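"""GAT branch, selective-SSM branch, block fusion, risk head, checkpoints."""

import dataclasses

import numpy as np
import pytest

from slidesurv.autodiff import Tensor
from slidesurv.graph_construction import GraphConfig, SUBTYPES, build_graph
from slidesurv.model import (
    GATMambaModel,
    ModelConfig,
    PatientBatch,
    load_checkpoint,
    save_checkpoint,
    selective_scan,
    selective_scan_op,
    ssm_discretize,
)
from conftest import make_tiles


def small_config(**kw):
    base = dict(d_features=8, dtype="float64", seed=0)
    base.update(kw)
    return ModelConfig(**base)


def batch_of(graphs_per_patient):
    ids = [f"P{i}" for i in range(len(graphs_per_patient))]
    return PatientBatch.from_patients(ids, graphs_per_patient)


@pytest.fixture
def toy_batch(toy_graph):
    return batch_of([[toy_graph]])


class TestProjectInputs:
    def test_zero_weights_pass_through_positional_encoding(self, toy_batch):
        m = GATMambaModel(small_config())
        for name in ("L_node.W", "L_node.b", "L_edge.W", "L_edge.b", "EB_cat"):
            m.params[name].data[:] = 0.0
        X, E = m.project_inputs(
            toy_batch.X_deep, toy_batch.X_pe, toy_batch.E_cat, toy_batch.E_cont
        )
        assert np.allclose(X.data[:, :64], 0.0)
        assert np.allclose(X.data[:, 64:], toy_batch.X_pe)
        assert np.allclose(E.data, 0.0)

    def test_shapes(self, toy_batch):
        m = GATMambaModel(small_config())
        X, E = m.project_inputs(
            toy_batch.X_deep, toy_batch.X_pe, toy_batch.E_cat, toy_batch.E_cont
        )
        assert X.shape == (toy_batch.X_deep.shape[0], 80)
        assert E.shape == (toy_batch.E_cat.shape[0], 16)

    def test_identity_edge_projection(self):
        m = GATMambaModel(small_config())
        m.params["EB_cat"].data[:] = 0.0
        m.params["L_edge.b"].data[:] = 0.0
        m.params["L_edge.W"].data[:] = np.eye(2, 16)
        _, E = m.project_inputs(
            np.zeros((2, 8)), np.zeros((2, 16)), np.array([0]), np.array([[1.0, 0.0]])
        )
        expected = np.zeros(16)
        expected[0] = 1.0
        assert np.allclose(E.data, expected)

    def test_out_of_range_category_rejected(self):
        m = GATMambaModel(small_config())
        with pytest.raises(ValueError, match="category"):
            m.project_inputs(
                np.zeros((2, 8)), np.zeros((2, 16)), np.array([21]), np.zeros((1, 2))
            )


class TestGatAttention:
    def _setup(self, n_nodes, edges, seed=0):
        m = GATMambaModel(small_config(seed=seed))
        rng = np.random.default_rng(seed)
        X = Tensor(rng.standard_normal((n_nodes, 80)))
        E = Tensor(rng.standard_normal((len(edges[0]), 16)))
        return m, X, E, np.asarray(edges)

    def test_single_in_edge_attention_is_one(self):
        m, X, E, e = self._setup(2, [[0, 1], [1, 0]])
        alpha = m.gat_attention(X, E, e)
        assert np.allclose(alpha.data, 1.0)

    def test_identical_neighbours_uniform(self):
        # 3 identical sources feeding node 0 (and a self-sufficient node set)
        m = GATMambaModel(small_config())
        X = Tensor(np.ones((4, 80)))
        e = np.array([[1, 2, 3, 0, 0, 0], [0, 0, 0, 1, 2, 3]])
        E = Tensor(np.ones((6, 16)))
        alpha = m.gat_attention(X, E, e)
        assert np.allclose(alpha.data[:3], 1 / 3)

    def test_normalizes_over_each_target(self, rng):
        m = GATMambaModel(small_config())
        n = 9
        from slidesurv.graph_construction import knn_edges

        e = knn_edges(rng.uniform(0, 10, (n, 2)), k=3)
        X = Tensor(rng.standard_normal((n, 80)))
        E = Tensor(rng.standard_normal((e.shape[1], 16)))
        alpha = m.gat_attention(X, E, e)
        sums = np.zeros(n)
        np.add.at(sums, e[1], alpha.data)
        assert np.allclose(sums, 1.0, atol=1e-6)
        assert np.all(alpha.data >= 0)

    def test_three_node_line_hand_evaluation(self):
        # 1-dim effective feature; W = identity block trick is impractical at
        # width 80, so evaluate the formula with the model's own parameters
        m, X, E, e = self._setup(3, [[0, 2, 1, 1], [1, 1, 0, 2]], seed=4)
        alpha = m.gat_attention(X, E, e)
        W = m.params["gat.W_n.0"].data
        We = m.params["gat.W_e.0"].data
        a = m.params["gat.a.0"].data
        WX, WE = X.data @ W, E.data @ We
        scores = []
        for k, (s, t) in enumerate(e.T):
            v = np.concatenate([WX[t], WX[s], WE[k]]) @ a
            scores.append(v if v > 0 else 0.2 * v)
        scores = np.array(scores)
        expected = np.empty(4)
        for t in np.unique(e[1]):
            mask = e[1] == t
            ex = np.exp(scores[mask] - scores[mask].max())
            expected[mask] = ex / ex.sum()
        assert np.allclose(alpha.data, expected, atol=1e-10)

    def test_isolated_node_rejected(self):
        m, X, E, e = self._setup(3, [[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="isolated"):
            m.gat_attention(X, E, e)


class TestGatLayer:
    def test_single_neighbour_copies_transformed_source(self):
        m = GATMambaModel(small_config())
        rng = np.random.default_rng(1)
        X = Tensor(rng.standard_normal((2, 80)))
        E = Tensor(rng.standard_normal((2, 16)))
        e = np.array([[0, 1], [1, 0]])
        out = m.gat_layer(X, E, e)
        W = m.params["gat.W_n.0"].data
        assert np.allclose(out.data[1], X.data[0] @ W, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        m = GATMambaModel(small_config())
        from slidesurv.graph_construction import knn_edges

        n = 8
        coords = rng.uniform(0, 10, (n, 2))
        e = knn_edges(coords, k=3)
        X = rng.standard_normal((n, 80))
        E = rng.standard_normal((e.shape[1], 16))
        out = m.gat_layer(Tensor(X), Tensor(E), e).data

        perm = rng.permutation(n)
        inv = np.argsort(perm)
        e_p = inv[e]  # relabel nodes
        out_p = m.gat_layer(Tensor(X[perm]), Tensor(E), e_p).data
        assert np.allclose(out_p, out[perm], atol=1e-10)

    def test_matches_dense_softmax_oracle(self, rng):
        m = GATMambaModel(small_config(seed=2))
        from slidesurv.graph_construction import knn_edges

        n = 6
        e = knn_edges(rng.uniform(0, 10, (n, 2)), k=2)
        X = rng.standard_normal((n, 80))
        E = rng.standard_normal((e.shape[1], 16))
        out = m.gat_layer(Tensor(X), Tensor(E), e).data

        W = m.params["gat.W_n.0"].data
        We = m.params["gat.W_e.0"].data
        a = m.params["gat.a.0"].data
        WX, WE = X @ W, E @ We
        scores = np.full((n, n), -np.inf)
        for k, (s, t) in enumerate(e.T):
            v = np.concatenate([WX[t], WX[s], WE[k]]) @ a
            scores[t, s] = v if v > 0 else 0.2 * v
        att = np.exp(scores - scores.max(axis=1, keepdims=True))
        att[~np.isfinite(scores)] = 0.0
        att /= att.sum(axis=1, keepdims=True)
        assert np.allclose(out, att @ WX, atol=1e-6)


class TestDiscretization:
    def test_zero_state_matrix_limit(self):
        A_bar, B_bar = ssm_discretize(np.zeros(3), np.full(3, 2.0), np.full(3, 0.5))
        assert np.allclose(A_bar, 1.0)
        assert np.allclose(B_bar, 0.5 * 2.0)

    def test_scalar_closed_form(self):
        A, B, d = -1.0, 1.0, 0.1
        A_bar, B_bar = ssm_discretize(np.array([A]), np.array([B]), np.array([d]))
        assert np.isclose(A_bar[0], np.exp(-0.1))
        assert np.isclose(B_bar[0], (np.exp(-0.1) - 1) / (-0.1) * 0.1 * 1.0)

    def test_small_step_limits_monotone(self):
        deltas = np.array([1.0, 0.1, 0.01, 0.001])
        A_bar, B_bar = ssm_discretize(
            np.full(4, -1.0), np.ones(4), deltas
        )
        assert np.all(np.diff(A_bar) > 0) and A_bar[-1] < 1.0  # -> 1 from below
        assert np.all(np.diff(B_bar) < 0) and B_bar[-1] > 0.0  # -> 0 from above

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            ssm_discretize(np.array([-1.0]), np.array([1.0]), np.array([0.0]))


class TestSelectiveScan:
    def test_zero_input_stays_zero(self, rng):
        L, D, N = 6, 3, 4
        y = selective_scan(
            np.zeros((L, D)),
            rng.uniform(0.01, 1, (L, D)),
            rng.standard_normal((L, N)),
            rng.standard_normal((L, N)),
            -rng.uniform(0.1, 1, (D, N)),
        )
        assert np.allclose(y, 0.0)

    def test_constant_parameters_reduce_to_lti_convolution(self, rng):
        L, D, N = 12, 2, 3
        x = rng.standard_normal((L, D))
        delta = np.full((L, D), 0.2)
        B = np.tile(rng.standard_normal(N), (L, 1))
        C = np.tile(rng.standard_normal(N), (L, 1))
        A = -rng.uniform(0.1, 2, (D, N))
        y = selective_scan(x, delta, B, C, A)
        A_bar, B_bar = ssm_discretize(A, B[0][None, :], delta[0][:, None])
        expected = np.zeros((L, D))
        for t in range(L):
            for s in range(t + 1):
                kern = (A_bar ** (t - s)) * B_bar  # (D, N)
                expected[t] += (kern * x[s][:, None]) @ C[0]
        assert np.allclose(y, expected, atol=1e-5)

    @pytest.mark.parametrize("L", [1, 3, 12])
    def test_batched_op_equals_naive_recurrence(self, L, rng):
        G, D, N = 2, 4, 3
        x = rng.standard_normal((G, L, D))
        dt = rng.uniform(0.01, 1, (G, L, D))
        B = rng.standard_normal((G, L, N))
        C = rng.standard_normal((G, L, N))
        A = -rng.uniform(0.05, 2, (D, N))
        y = selective_scan_op(Tensor(x), Tensor(dt), Tensor(B), Tensor(C), Tensor(A))
        for g in range(G):
            assert np.allclose(
                y.data[g], selective_scan(x[g], dt[g], B[g], C[g], A), atol=1e-5
            )


class TestMambaBranch:
    def test_single_node_graph(self):
        tiles = make_tiles(1, 2)
        g = build_graph(tiles, np.random.default_rng(0).standard_normal((2, 8)),
                        GraphConfig(k=1))
        m = GATMambaModel(small_config())
        batch = batch_of([[g]])
        X, _ = m.project_inputs(batch.X_deep, batch.X_pe, batch.E_cat, batch.E_cont)
        out = m.mamba_branch(X, batch, train=False, rng=np.random.default_rng(0))
        assert out.shape == (2, 80)
        assert np.all(np.isfinite(out.data))

    def test_order_sensitivity(self, toy_graph):
        """Token order matters: reversing the node sequence changes outputs."""
        m = GATMambaModel(small_config())
        batch = batch_of([[toy_graph]])
        X, _ = m.project_inputs(batch.X_deep, batch.X_pe, batch.E_cat, batch.E_cont)
        out = m.mamba_branch(X, batch, False, np.random.default_rng(0))
        Xr = Tensor(X.data[::-1].copy())
        out_r = m.mamba_branch(Xr, batch, False, np.random.default_rng(0))
        assert not np.allclose(out.data, out_r.data[::-1], atol=1e-8)

    def test_unequal_graph_sizes_padded_correctly(self):
        """Padding a short graph must not change its own outputs."""
        rng = np.random.default_rng(3)
        g_small = build_graph(make_tiles(1, 3), rng.standard_normal((3, 8)), GraphConfig(k=2))
        g_large = build_graph(make_tiles(3, 3), rng.standard_normal((9, 8)), GraphConfig(k=3))
        m = GATMambaModel(small_config())
        b_both = batch_of([[g_small], [g_large]])
        b_small = batch_of([[g_small]])
        X_b, _ = m.project_inputs(b_both.X_deep, b_both.X_pe, b_both.E_cat, b_both.E_cont)
        X_s, _ = m.project_inputs(b_small.X_deep, b_small.X_pe, b_small.E_cat, b_small.E_cont)
        out_b = m.mamba_branch(X_b, b_both, False, np.random.default_rng(0))
        out_s = m.mamba_branch(X_s, b_small, False, np.random.default_rng(0))
        assert np.allclose(out_b.data[:3], out_s.data, atol=1e-10)


class TestBlockAndHead:
    def test_zeroed_branches_pass_residual_through(self, toy_batch):
        m = GATMambaModel(small_config(dropout=0.0))
        # zero both branch outputs and the closing MLP
        for name, t in m.params.items():
            if name.startswith(("gat.", "ssm.", "mlp.")):
                t.data[:] = 0.0
        X, E = m.project_inputs(
            toy_batch.X_deep, toy_batch.X_pe, toy_batch.E_cat, toy_batch.E_cont
        )
        out = m.gat_mamba_block(X, E, toy_batch, train=False, rng=np.random.default_rng(0))
        # eval-mode BN at init is identity, so each branch contributes X
        assert np.allclose(out.data, 2.0 * X.data, atol=1e-3)

    def test_single_block_enforced(self):
        with pytest.raises(ValueError, match="one block"):
            ModelConfig(n_blocks=2)

    def test_block_composes_branch_operations(self, toy_batch):
        m = GATMambaModel(small_config(dropout=0.0))
        X, E = m.project_inputs(
            toy_batch.X_deep, toy_batch.X_pe, toy_batch.E_cat, toy_batch.E_cont
        )
        rng = np.random.default_rng(0)
        out = m.gat_mamba_block(X, E, toy_batch, False, rng)
        local = m.bn_local(X + m.gat_layer(X, E, toy_batch.edge_index), False)
        glob = m.bn_global(
            X + m.mamba_branch(X, toy_batch, False, rng), False
        )
        h = local + glob
        p = m.params
        mlp = (h @ p["mlp.W1"] + p["mlp.b1"]).relu() @ p["mlp.W2"] + p["mlp.b2"]
        expected = m.bn_out(h + mlp, False)
        assert np.allclose(out.data, expected.data, atol=1e-10)

    def test_duplicate_graphs_do_not_change_risk(self, toy_graph):
        m = GATMambaModel(small_config(dropout=0.0))
        r1 = m.predict_risk(batch_of([[toy_graph]])).data
        r2 = m.predict_risk(batch_of([[toy_graph, toy_graph]])).data
        assert np.allclose(r1, r2, atol=1e-8)

    def test_zero_head_weights_give_bias(self, toy_batch):
        m = GATMambaModel(small_config(dropout=0.0))
        m.params["head.W2"].data[:] = 0.0
        m.params["head.b2"].data[:] = 1.25
        risks = m.predict_risk(toy_batch)
        assert np.allclose(risks.data, 1.25)

    def test_risk_head_shift_covariance(self, toy_batch):
        m = GATMambaModel(small_config(dropout=0.0))
        base = m.predict_risk(toy_batch).data.copy()
        m.params["head.b2"].data += 3.5
        shifted = m.predict_risk(toy_batch).data
        assert np.allclose(shifted, base + 3.5, atol=1e-8)

    def test_empty_patient_rejected(self):
        with pytest.raises(ValueError, match="no graphs"):
            PatientBatch.from_patients(["P0"], [[]])


class TestParameterCounts:
    def test_component_counts(self):
        m = GATMambaModel(small_config())
        counts = m.count_parameters()
        assert counts["edge_projection"] == 21 * 16 + (2 * 16 + 16)  # 336 + 48

    def test_no_edge_ablation_drops_exactly_384(self):
        full = GATMambaModel(small_config()).count_parameters()["total"]
        no_e = GATMambaModel(
            small_config(use_edge_features=False)
        ).count_parameters()["total"]
        assert full - no_e == 384

    def test_no_pe_ablation_narrows_block_to_64(self):
        cfg = small_config(use_positional_encoding=False)
        assert cfg.width == 64
        m = GATMambaModel(cfg)
        g = build_graph(
            make_tiles(3, 3), np.random.default_rng(0).standard_normal((9, 8)),
            GraphConfig(k=3),
        )
        out = m.predict_risk(batch_of([[g]]))
        assert out.shape == (1,)


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, toy_batch, tmp_path):
        m = GATMambaModel(small_config(dropout=0.0))
        risks = m.predict_risk(toy_batch).data
        path = tmp_path / "ckpt.npz"
        save_checkpoint(m, path)
        m2 = load_checkpoint(path)
        assert m2.config == m.config
        assert np.array_equal(m2.predict_risk(toy_batch).data, risks)

    def test_deterministic_construction(self, toy_batch):
        a = GATMambaModel(small_config(seed=5))
        b = GATMambaModel(small_config(seed=5))
        assert np.array_equal(
            a.predict_risk(toy_batch).data, b.predict_risk(toy_batch).data
        )
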