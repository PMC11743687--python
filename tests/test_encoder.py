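"""Row-norm scaling, message propagation, the two variational branches
and the reparameterization trick."""

import numpy as np
import pytest

from snolink.autodiff import Tensor
from snolink.encoder import (NodeFeatures, encode_degree, encode_similarity,
                             init_encoder_params, l2_scale, propagate,
                             reparameterize)
from snolink.graph import BipartiteGraph, build_propagation_operator
from snolink.kan import init_kan_layer


class TestL2Scale:
    def test_three_four_row(self):
        out = l2_scale(np.array([[3.0, 4.0]]), t=1.8)
        assert np.allclose(out.data, [[1.08, 1.44]])

    def test_every_nonzero_row_has_norm_t(self):
        rng = np.random.default_rng(0)
        h = rng.normal(size=(50, 7)) * rng.uniform(0.01, 100, size=(50, 1))
        out = l2_scale(h, t=1.8)
        norms = np.linalg.norm(out.data, axis=1)
        assert np.all(np.abs(norms - 1.8) < 1e-6)

    def test_unit_row_scaled_by_t(self):
        v = np.array([[0.6, 0.8]])
        assert np.allclose(l2_scale(v, 1.8).data, 1.8 * v)

    def test_zero_row_stays_zero(self, caplog):
        h = np.array([[0.0, 0.0], [1.0, 0.0]])
        with caplog.at_level("WARNING"):
            out = l2_scale(h, 1.8)
        assert np.allclose(out.data[0], 0.0)
        assert np.allclose(out.data[1], [1.8, 0.0])
        assert any("zero row" in r.message for r in caplog.records)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            l2_scale(np.array([[np.inf, 1.0]]), 1.8)

    def test_nonpositive_t_rejected(self):
        with pytest.raises(ValueError):
            l2_scale(np.ones((1, 2)), 0.0)


class TestPropagate:
    def test_isolated_node_keeps_own_features(self):
        g = BipartiteGraph(["s1", "s2"], ["d"], {(0, 0)})
        op = build_propagation_operator(g)
        n = np.eye(3)
        out = propagate(n, op)
        assert np.allclose(out.data[1], n[1])

    def test_two_nodes_one_edge_average(self):
        g = BipartiteGraph(["s"], ["d"], {(0, 0)})
        op = build_propagation_operator(g)
        n = np.eye(2)
        out = propagate(n, op)
        assert np.allclose(out.data, 0.5 * np.ones((2, 2)))

    def test_matches_dense_matmul_oracle(self):
        rng = np.random.default_rng(1)
        pairs = {(int(rng.integers(20)), int(rng.integers(10)))
                 for _ in range(35)}
        g = BipartiteGraph([f"s{i}" for i in range(20)],
                           [f"d{i}" for i in range(10)], pairs)
        op = build_propagation_operator(g)
        n = rng.normal(size=(30, 6))
        assert np.max(np.abs(propagate(n, op).data - op.matrix @ n)) < 1e-10

    def test_shape_mismatch_raises(self):
        g = BipartiteGraph(["s"], ["d"], {(0, 0)})
        op = build_propagation_operator(g)
        with pytest.raises(ValueError, match="operator dim"):
            propagate(np.ones((5, 2)), op)


@pytest.fixture()
def small_setup():
    rng = np.random.default_rng(2)
    pairs = {(int(rng.integers(8)), int(rng.integers(5)))
             for _ in range(12)}
    g = BipartiteGraph([f"s{i}" for i in range(8)],
                       [f"d{i}" for i in range(5)], pairs)
    op = build_propagation_operator(g)
    return g, op, rng


class TestSimilarityBranch:
    def test_output_shapes_and_positive_sigma(self, small_setup):
        g, op, rng = small_setup
        params = init_encoder_params(g.n_nodes, 6, 4, rng)
        emb = encode_similarity(NodeFeatures.one_hot(g.n_nodes), op, params)
        assert emb.mu.shape == (g.n_nodes, 4)
        assert emb.sigma.shape == (g.n_nodes, 4)
        assert np.all(emb.sigma.data > 0)

    def test_shared_first_layer_structure(self, small_setup):
        """W1 perturbation moves both heads; W2_mu moves only mu."""
        g, op, rng = small_setup
        params = init_encoder_params(g.n_nodes, 6, 4, rng)
        feats = NodeFeatures.one_hot(g.n_nodes)
        base = encode_similarity(feats, op, params)
        params.W2_mu.data[0, 0] += 0.5
        moved = encode_similarity(feats, op, params)
        assert not np.allclose(moved.mu.data, base.mu.data)
        assert np.allclose(moved.sigma.data, base.sigma.data)
        params.W1.data[0, 0] += 0.5
        moved2 = encode_similarity(feats, op, params)
        assert not np.allclose(moved2.mu.data, moved.mu.data)
        assert not np.allclose(moved2.sigma.data, moved.sigma.data)

    def test_permutation_equivariance(self):
        """Relabeling snoRNA nodes permutes output rows identically."""
        rng = np.random.default_rng(5)
        pairs = {(0, 0), (1, 1), (2, 0), (3, 2)}
        g = BipartiteGraph(["a", "b", "c", "d"], ["x", "y", "z"], pairs)
        perm_s = [2, 0, 3, 1]  # new index of each old snoRNA
        pairs_p = {(perm_s[s], d) for s, d in pairs}
        g_p = BipartiteGraph(["c", "a", "d", "b"], ["x", "y", "z"], pairs_p)
        n = g.n_nodes
        params = init_encoder_params(n, 5, 3, rng)
        # permute the one-hot feature rows AND the W1 rows consistently
        full_perm = perm_s + [4, 5, 6]
        p_mat = np.zeros((n, n))
        for old, new in enumerate(full_perm):
            p_mat[new, old] = 1.0
        params_p = init_encoder_params(n, 5, 3, np.random.default_rng(5))
        params_p.W1.data[:] = p_mat @ params.W1.data
        emb = encode_similarity(NodeFeatures.one_hot(n),
                                build_propagation_operator(g), params)
        emb_p = encode_similarity(NodeFeatures.one_hot(n),
                                  build_propagation_operator(g_p), params_p)
        assert np.allclose(emb_p.mu.data, p_mat @ emb.mu.data, atol=1e-10)
        assert np.allclose(emb_p.sigma.data, p_mat @ emb.sigma.data,
                           atol=1e-10)

    def test_wrong_branch_rejected(self, small_setup):
        g, op, rng = small_setup
        kan = init_kan_layer(6, 4, rng)
        params = init_encoder_params(g.n_nodes, 6, 4, rng, branch="degree",
                                     kan=kan)
        with pytest.raises(ValueError, match="similarity"):
            encode_similarity(NodeFeatures.one_hot(g.n_nodes), op, params)


class TestDegreeBranch:
    def test_shapes_and_degree_varying_norms(self, small_setup):
        g, op, rng = small_setup
        kan = init_kan_layer(6, 4, rng)
        params = init_encoder_params(g.n_nodes, 6, 4, rng, branch="degree",
                                     kan=kan)
        emb = encode_degree(op, params)
        assert emb.mu.shape == (g.n_nodes, 4)
        norms = np.linalg.norm(emb.mu.data, axis=1)
        # no per-row normalization: norms vary on a degree-heterogeneous graph
        assert norms.std() > 1e-6

    def test_degree_regular_graph_symmetric_rows(self):
        """On a degree-regular bipartite graph with symmetric weights all
        rows within a part coincide."""
        # 3 snoRNAs x 3 diseases, perfect matching cycle: every node degree 2
        pairs = {(0, 0), (0, 1), (1, 1), (1, 2), (2, 2), (2, 0)}
        g = BipartiteGraph(["a", "b", "c"], ["x", "y", "z"], pairs)
        op = build_propagation_operator(g)
        rng = np.random.default_rng(0)
        kan = init_kan_layer(4, 3, rng)
        params = init_encoder_params(g.n_nodes, 4, 3, rng, branch="degree",
                                     kan=kan)
        params.W1.data[:] = np.ones((g.n_nodes, 4))  # symmetric init
        emb = encode_degree(op, params)
        mu = emb.mu.data
        assert np.allclose(mu[0], mu[1]) and np.allclose(mu[1], mu[2])
        assert np.allclose(mu[3], mu[4]) and np.allclose(mu[4], mu[5])


class TestReparameterize:
    def test_sigma_to_zero_limit_returns_mu(self, small_setup):
        g, op, rng = small_setup
        params = init_encoder_params(g.n_nodes, 6, 4, rng,
                                     log_sigma_init=-40.0)
        params.W2_sigma.data[:] = 0.0
        emb = encode_similarity(NodeFeatures.one_hot(g.n_nodes), op, params)
        z = reparameterize(emb, seed=0)
        assert np.allclose(z.data, emb.mu.data, atol=1e-12)

    def test_same_seed_same_draw(self, small_setup):
        g, op, rng = small_setup
        params = init_encoder_params(g.n_nodes, 6, 4, rng)
        emb = encode_similarity(NodeFeatures.one_hot(g.n_nodes), op, params)
        assert np.array_equal(reparameterize(emb, seed=3).data,
                              reparameterize(emb, seed=3).data)
        assert not np.array_equal(reparameterize(emb, seed=3).data,
                                  reparameterize(emb, seed=4).data)

    def test_monte_carlo_mean_recovers_mu(self):
        """Mean of 10,000 draws is within 3*sigma/100 of mu elementwise."""
        mu = np.array([[0.5, -1.0], [2.0, 0.0]])
        sigma = np.array([[0.3, 0.5], [1.0, 0.2]])
        from snolink.encoder import VariationalEmbedding
        emb = VariationalEmbedding(mu=Tensor(mu), sigma=Tensor(sigma))
        rng = np.random.default_rng(0)
        acc = np.zeros_like(mu)
        n = 10_000
        for _ in range(n):
            acc += mu + sigma * rng.standard_normal(mu.shape)
        assert np.all(np.abs(acc / n - mu) < 3 * sigma / np.sqrt(n))
        # the implementation draws from the same distribution
        draws = np.stack([reparameterize(emb, seed=s).data
                          for s in range(200)])
        assert np.all(np.abs(draws.mean(axis=0) - mu)
                      < 4 * sigma / np.sqrt(200))
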