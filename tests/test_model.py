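"""The four-module network: layer semantics, oracles, composition contracts."""

import numpy as np
import pytest

from supragnn.autodiff import Tensor
from supragnn.features import NodeAttributeSet
from supragnn.graph import (SpectralGraph, SupraAdjacency, assemble_supra,
                            normalize_laplacian, scale_laplacian)
from supragnn.model import (ModelConfig, ModelError, SupraGNN, cheb_conv,
                            classify, decode, dim_increase,
                            expected_parameter_count, gat_attention, gat_layer,
                            graph_readout, parallel_branch, softmax)

from conftest import random_connected_adjacency, random_supra_blocks


def spectral(adjacency: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lap = normalize_laplacian(adjacency)
    lam = float(np.linalg.eigvalsh(lap)[-1])
    if lam <= 1e-12:
        lam = 2.0
    return lap, scale_laplacian(lap, lam)


class TestDimIncrease:
    def test_zero_weights_give_zero_output(self):
        params = {"gene_w": Tensor(np.zeros((2, 3))), "gene_b": Tensor(np.zeros(3)),
                  "mirna_w": Tensor(np.zeros((1, 3))), "mirna_b": Tensor(np.zeros(3))}
        out = dim_increase(np.ones((4, 2, 2)), np.ones((4, 1, 1)), params)
        assert out.shape == (4, 3, 3) and not out.data.any()

    def test_hand_computed_projection(self):
        params = {"gene_w": Tensor([[1.0], [1.0]]), "gene_b": Tensor([0.0]),
                  "mirna_w": Tensor([[2.0]]), "mirna_b": Tensor([0.0])}
        out = dim_increase(np.array([[[3.0, 4.0]]]), np.array([[[5.0]]]), params)
        np.testing.assert_allclose(out.data, [[[7.0], [10.0]]])

    def test_row_count_is_total_node_count(self):
        rng = np.random.default_rng(0)
        params = {"gene_w": Tensor(rng.normal(size=(2, 5))),
                  "gene_b": Tensor(np.zeros(5)),
                  "mirna_w": Tensor(rng.normal(size=(1, 5))),
                  "mirna_b": Tensor(np.zeros(5))}
        out = dim_increase(rng.normal(size=(2, 7, 2)),
                           rng.normal(size=(2, 3, 1)), params)
        assert out.shape == (2, 10, 5)

    def test_wrong_widths_rejected(self):
        params = {"gene_w": Tensor(np.zeros((2, 3)))}
        with pytest.raises(ModelError):
            dim_increase(np.ones((1, 2, 3)), np.ones((1, 1, 1)), params)


class TestChebConv:
    def test_k1_identity_coefficient_reproduces_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 5, 3))
        _, lt = spectral(random_connected_adjacency(rng, 5))
        out = cheb_conv(Tensor(x), lt, [Tensor(np.eye(3))])
        np.testing.assert_allclose(out.data, x)

    def test_k2_selects_laplacian_term(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 6, 2))
        _, lt = spectral(random_connected_adjacency(rng, 6))
        out = cheb_conv(Tensor(x), lt,
                        [Tensor(np.zeros((2, 2))), Tensor(np.eye(2))])
        np.testing.assert_allclose(out.data, lt @ x, atol=1e-12)

    def test_empty_coefficients_rejected(self):
        with pytest.raises(ModelError):
            cheb_conv(Tensor(np.zeros((1, 2, 2))), np.eye(2), [])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_spectral_oracle(self, seed):
        """The recurrence equals the eigendecomposition form
        U (Σ_k β_k T_k(Λ̃)) Uᵀ X per scalar channel, K up to 6."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 13))
        k = int(rng.integers(1, 7))
        adj = random_connected_adjacency(rng, n)
        lap, lt = spectral(adj)
        x = rng.normal(size=(1, n, 1))
        betas = rng.normal(size=k)
        coeffs = [Tensor(np.array([[b]])) for b in betas]
        got = cheb_conv(Tensor(x), lt, coeffs).data[0, :, 0]

        lam, u = np.linalg.eigh(lt)
        t_prev2, t_prev1 = np.ones_like(lam), lam.copy()
        filt = betas[0] * t_prev2
        if k > 1:
            filt = filt + betas[1] * t_prev1
        for kk in range(2, k):
            t_k = 2 * lam * t_prev1 - t_prev2
            filt = filt + betas[kk] * t_k
            t_prev2, t_prev1 = t_prev1, t_k
        oracle = u @ np.diag(filt) @ u.T @ x[0, :, 0]
        np.testing.assert_allclose(got, oracle, atol=1e-6)


class TestAttention:
    def path_graph(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = 1.0
        np.fill_diagonal(adj, 1.0)
        return adj

    def test_rows_are_probability_vectors_on_neighborhoods(self):
        rng = np.random.default_rng(0)
        adj = random_connected_adjacency(rng, 7)
        x = Tensor(rng.normal(size=(2, 7, 4)))
        alpha = gat_attention(x, adj, Tensor(rng.normal(size=(3, 4))),
                              Tensor(rng.normal(size=6)))
        np.testing.assert_allclose(alpha.data.sum(axis=-1), 1.0, atol=1e-12)
        assert (alpha.data[:, adj == 0] == 0).all()
        assert (alpha.data >= 0).all()

    def test_identical_features_give_uniform_weights(self):
        rng = np.random.default_rng(1)
        adj = random_connected_adjacency(rng, 6)
        x = Tensor(np.ones((1, 6, 3)))
        alpha = gat_attention(x, adj, Tensor(rng.normal(size=(2, 3))),
                              Tensor(rng.normal(size=4)))
        nb_sizes = adj.sum(axis=1)
        for i in range(6):
            expected = np.where(adj[i] > 0, 1.0 / nb_sizes[i], 0.0)
            np.testing.assert_allclose(alpha.data[0, i], expected, atol=1e-12)

    def test_three_node_path_hand_example(self):
        """Middle node of a 3-node path with features (0,1,2), W=1, a=(1,1),
        slope 0.2: its row is softmax(1, 2, 3) over all three nodes."""
        adj = self.path_graph()
        x = Tensor(np.array([[[0.0], [1.0], [2.0]]]))
        alpha = gat_attention(x, adj, Tensor([[1.0]]), Tensor([1.0, 1.0]),
                              slope=0.2)
        expected = np.exp([1.0, 2.0, 3.0])
        expected /= expected.sum()
        np.testing.assert_allclose(alpha.data[0, 1], expected, atol=1e-8)

    def test_node_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        adj = random_connected_adjacency(rng, 6)
        x = rng.normal(size=(1, 6, 3))
        w = Tensor(rng.normal(size=(3, 3)))
        a = Tensor(rng.normal(size=6))
        alpha = gat_attention(Tensor(x), adj, w, a).data
        perm = rng.permutation(6)
        alpha_p = gat_attention(Tensor(x[:, perm]), adj[np.ix_(perm, perm)],
                                w, a).data
        np.testing.assert_allclose(alpha_p, alpha[:, perm][:, :, perm],
                                   atol=1e-12)


class TestGatLayer:
    def test_self_only_neighborhood_reduces_to_linear_map(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 4, 3))
        w = Tensor(rng.normal(size=(3, 3)))
        a = Tensor(rng.normal(size=6))
        out = gat_layer(Tensor(x), np.eye(4), [{"w": w, "a": a}],
                        agg="concat", activation="none")
        np.testing.assert_allclose(out.data, x @ w.data.T, atol=1e-12)

    def test_zero_weights_give_zero_preactivation(self):
        out = gat_layer(Tensor(np.ones((1, 3, 2))), np.eye(3),
                        [{"w": Tensor(np.zeros((2, 2))),
                          "a": Tensor(np.zeros(4))}],
                        agg="concat", activation="none")
        assert not out.data.any()

    def test_matches_per_head_attention_loop(self):
        """The batched multi-head layer equals looping gat_attention +
        weighted sums head by head (concat and average aggregation)."""
        rng = np.random.default_rng(3)
        adj = random_connected_adjacency(rng, 7)
        x = Tensor(rng.normal(size=(2, 7, 4)))
        heads = [{"w": Tensor(rng.normal(size=(3, 4))),
                  "a": Tensor(rng.normal(size=6))} for _ in range(4)]
        per_head = [gat_attention(x, adj, hp["w"], hp["a"]).data
                    @ (x.data @ hp["w"].data.T) for hp in heads]
        got_cat = gat_layer(x, adj, heads, agg="concat", activation="none")
        np.testing.assert_allclose(got_cat.data,
                                   np.concatenate(per_head, axis=-1), atol=1e-10)
        got_avg = gat_layer(x, adj, heads, agg="average", activation="none")
        np.testing.assert_allclose(got_avg.data,
                                   np.mean(per_head, axis=0), atol=1e-10)


class TestReadout:
    def test_constant_input_pools_to_constant(self):
        w = Tensor(np.eye(2))
        b = Tensor(np.zeros(2))
        out = graph_readout(Tensor(np.full((1, 16, 1), 3.5)), 8, w, b)
        np.testing.assert_allclose(out.data, [[3.5, 3.5]])

    def test_window_max_oracle(self):
        vals = np.arange(1, 17, dtype=float).reshape(1, 16, 1)
        out = graph_readout(Tensor(vals), 8, Tensor(np.eye(2)),
                            Tensor(np.zeros(2)))
        np.testing.assert_allclose(out.data, [[8.0, 16.0]])

    def test_partial_final_window(self):
        vals = np.arange(1, 11, dtype=float).reshape(1, 10, 1)  # 10 nodes, p=8
        out = graph_readout(Tensor(vals), 8, Tensor(np.eye(2)),
                            Tensor(np.zeros(2)))
        np.testing.assert_allclose(out.data, [[8.0, 10.0]])

    def test_invalid_window_rejected(self):
        with pytest.raises(ModelError):
            graph_readout(Tensor(np.zeros((1, 4, 1))), 0, Tensor(np.eye(1)),
                          Tensor(np.zeros(1)))


class TestBranches:
    def test_parallel_zero_weights(self):
        params = {"w1": Tensor(np.zeros((4, 6))), "b1": Tensor(np.zeros(4)),
                  "w2": Tensor(np.zeros((2, 4))), "b2": Tensor(np.zeros(2))}
        out = parallel_branch(Tensor(np.ones((3, 2, 3))), params)
        assert out.shape == (3, 2) and not out.data.any()

    def test_parallel_hand_computed_affine_composition(self):
        params = {"w1": Tensor(np.ones((2, 4))), "b1": Tensor([1.0, -100.0]),
                  "w2": Tensor(np.ones((3, 2))), "b2": Tensor([0.5, 0.5, 0.5])}
        x = np.ones((1, 2, 2))  # flattens to (1, 1, 1, 1)
        out = parallel_branch(Tensor(x), params)
        # h = relu((4+1, 4-100)) = (5, 0); out = 5 + 0.5
        np.testing.assert_allclose(out.data, [[5.5, 5.5, 5.5]])

    def test_decoder_output_matches_flat_length(self):
        n, m, repr_dim = 4, 2, 6
        params = {"w1": Tensor(np.zeros((3, repr_dim))), "b1": Tensor(np.zeros(3)),
                  "w2": Tensor(np.zeros((2 * n + m, 3))),
                  "b2": Tensor(np.zeros(2 * n + m))}
        out = decode(Tensor(np.ones((5, repr_dim))), params)
        assert out.shape == (5, 2 * n + m)
        # zero weights -> zero reconstruction, so L_recon = sum(x^2)
        assert not out.data.any()


class TestClassify:
    def test_zero_logits_uniform(self):
        probs = classify(Tensor(np.zeros((2, 3))), None,
                         Tensor(np.zeros((4, 3))), Tensor(np.zeros(4)))
        np.testing.assert_allclose(probs.data, 0.25)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        probs = classify(Tensor(rng.normal(size=(5, 3))),
                         Tensor(rng.normal(size=(5, 3))),
                         Tensor(rng.normal(size=(4, 6))),
                         Tensor(rng.normal(size=4)))
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-12)

    def test_closed_form_two_class(self):
        logits = Tensor(np.array([[np.log(3.0), 0.0]]))
        np.testing.assert_allclose(softmax(logits).data, [[0.75, 0.25]],
                                   atol=1e-12)


def make_attrs(rng, s, n, m):
    return NodeAttributeSet(gene_attrs=rng.normal(size=(s, n, 2)),
                            mirna_attrs=rng.normal(size=(s, m, 1)),
                            sample_ids=[f"s{i}" for i in range(s)],
                            omic_combo="mRNA+CNV+miRNA")


def toy_graph(rng, n, m):
    a_gg, a_gm, a_mm = random_supra_blocks(rng, n, m)
    supra = assemble_supra(a_gg, a_gm, a_mm, "full")
    return SpectralGraph.from_adjacency(supra)


class TestForward:
    @pytest.mark.parametrize("gnn_type", ["GCN", "GAT"])
    def test_ablation_contracts(self, gnn_type):
        rng = np.random.default_rng(0)
        graph = toy_graph(rng, 10, 4)
        attrs = make_attrs(rng, 3, 10, 4)
        full_cfg = dict(gnn_type=gnn_type, F=4, repr_dim=8, pool_p=4,
                        n_classes=2, seed=1)
        out = SupraGNN(ModelConfig(**full_cfg), 10, 4).forward(attrs, graph)
        assert out.x_hat is not None and out.theta_global is not None
        assert out.x_hat.shape == (3, 24)  # 2N+M

        no_dec = SupraGNN(ModelConfig(include_decoder=False, **full_cfg), 10, 4)
        out = no_dec.forward(attrs, graph)
        assert out.x_hat is None

        no_par = SupraGNN(ModelConfig(include_parallel=False, **full_cfg), 10, 4)
        out = no_par.forward(attrs, graph)
        assert out.theta_global is None
        assert out.representation().theta_global.any() == False  # zero sentinel

    def test_representation_lengths_default_64(self):
        rng = np.random.default_rng(2)
        graph = toy_graph(rng, 10, 4)
        attrs = make_attrs(rng, 2, 10, 4)
        model = SupraGNN(ModelConfig(n_classes=2, seed=0), 10, 4)
        out = model.forward(attrs, graph)
        assert out.theta_local.shape == (2, 64)
        assert out.theta_global.shape == (2, 64)

    @pytest.mark.parametrize("gnn_type", ["GCN", "GAT"])
    def test_forward_is_deterministic(self, gnn_type):
        rng = np.random.default_rng(3)
        graph = toy_graph(rng, 8, 3)
        attrs = make_attrs(rng, 2, 8, 3)
        cfg = ModelConfig(gnn_type=gnn_type, F=4, repr_dim=8, n_classes=3, seed=7)
        p1 = SupraGNN(cfg, 8, 3).forward(attrs, graph).probabilities.data
        p2 = SupraGNN(cfg, 8, 3).forward(attrs, graph).probabilities.data
        assert p1.tobytes() == p2.tobytes()

    def test_graph_type_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        graph = toy_graph(rng, 6, 2)
        attrs = make_attrs(rng, 1, 6, 2)
        model = SupraGNN(ModelConfig(gnn_type="GCN", n_classes=2, seed=0), 6, 2)
        with pytest.raises(ModelError, match="SpectralGraph"):
            model.forward(attrs, graph.adjacency)

    @pytest.mark.parametrize("gnn_type", ["GCN", "GAT"])
    @pytest.mark.parametrize("include_decoder", [True, False])
    @pytest.mark.parametrize("include_parallel", [True, False])
    def test_parameter_count_matches_closed_form(self, gnn_type,
                                                 include_decoder,
                                                 include_parallel):
        cfg = ModelConfig(gnn_type=gnn_type, include_decoder=include_decoder,
                          include_parallel=include_parallel, n_classes=4,
                          seed=0)
        model = SupraGNN(cfg, 60, 20)
        assert model.n_parameters() == expected_parameter_count(cfg, 60, 20)

    def test_parameter_count_linear_in_nodes(self):
        cfg = ModelConfig(n_classes=2, seed=0)
        # readout+parallel+decoder scale linearly in node count
        c1 = expected_parameter_count(cfg, 64, 16)
        c2 = expected_parameter_count(cfg, 128, 32)
        c3 = expected_parameter_count(cfg, 192, 48)
        assert c3 - c2 == c2 - c1

    def test_checkpoint_roundtrip_reproduces_forward_bitwise(self, tmp_path):
        rng = np.random.default_rng(6)
        graph = toy_graph(rng, 9, 3)
        attrs = make_attrs(rng, 2, 9, 3)
        model = SupraGNN(ModelConfig(gnn_type="GAT", F=4, repr_dim=8,
                                     n_classes=2, seed=9), 9, 3)
        # perturb away from the seeded init so the roundtrip is non-trivial
        model.parameters()[0].data += 0.123
        before = model.forward(attrs, graph).probabilities.data
        model.save(tmp_path / "ckpt.npz")
        back = SupraGNN.load(tmp_path / "ckpt.npz")
        after = back.forward(attrs, graph).probabilities.data
        assert before.tobytes() == after.tobytes()


class TestPoolingOrderSensitivity:
    def test_gcn_node_features_equivariant_but_readout_order_sensitive(self):
        """Up to the readout, the Chebyshev path is equivariant to a
        consistent node relabeling; pooled windows depend on the frozen
        order, so the readout generally is not."""
        rng = np.random.default_rng(8)
        n = 12
        adj = random_connected_adjacency(rng, n)
        _, lt = spectral(adj)
        x = rng.normal(size=(1, n, 2))
        coeffs = [Tensor(rng.normal(size=(2, 2))) for _ in range(3)]
        y = cheb_conv(Tensor(x), lt, coeffs).data
        perm = rng.permutation(n)
        lt_p = lt[np.ix_(perm, perm)]
        y_p = cheb_conv(Tensor(x[:, perm]), lt_p, coeffs).data
        np.testing.assert_allclose(y_p, y[:, perm], atol=1e-10)
        # max over permuted windows differs from permuted window max
        pooled = y.reshape(1, 3, 4, 2).max(axis=2)
        pooled_p = y_p.reshape(1, 3, 4, 2).max(axis=2)
        assert not np.allclose(pooled, pooled_p)
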