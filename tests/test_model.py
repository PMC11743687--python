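"""Variational objective, EM updates, and the training loop."""

import numpy as np
import pytest
from scipy.integrate import quad

from snolink.autodiff import Tensor, as_tensor
from snolink.decoder import MixtureDecoderState, cosine_scores
from snolink.encoder import (NodeFeatures, VariationalEmbedding,
                             encode_similarity, init_encoder_params,
                             reparameterize)
from snolink.graph import build_propagation_operator, sample_negatives
from snolink.model import (AssociationModel, AssociationResults,
                           LossBreakdown, TrainConfig, bernoulli_loglik,
                           elbo, em_step, gaussian_kl, mixture_loglik)


def _kl_quadrature(mu, sigma):
    """Numerical KL( N(mu, sigma^2) || N(0,1) ) for one scalar entry."""
    def integrand(x):
        q = np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        p = np.exp(-0.5 * x ** 2) / np.sqrt(2 * np.pi)
        return q * (np.log(q) - np.log(p)) if q > 1e-300 else 0.0
    lo, hi = mu - 12 * sigma, mu + 12 * sigma
    val, _ = quad(integrand, lo, hi, limit=200)
    return val


class TestGaussianKL:
    def test_prior_equals_posterior_gives_zero(self):
        assert gaussian_kl(np.zeros((3, 2)), np.ones((3, 2))) == 0.0

    def test_unit_mean_single_entry(self):
        assert gaussian_kl(np.array([[1.0]]), np.array([[1.0]])) == \
            pytest.approx(0.5)

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            mu = float(rng.normal(0, 2))
            sigma = float(rng.uniform(0.1, 3))
            closed = gaussian_kl(np.array([[mu]]), np.array([[sigma]]))
            assert closed == pytest.approx(_kl_quadrature(mu, sigma),
                                           abs=1e-6)

    def test_nonnegative_and_zero_only_at_prior(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            mu = rng.normal(size=(4, 3))
            sigma = rng.uniform(0.05, 4, size=(4, 3))
            kl = gaussian_kl(mu, sigma)
            assert kl >= 0
            if not (np.allclose(mu, 0) and np.allclose(sigma, 1)):
                assert kl > 0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            gaussian_kl(np.zeros((1, 1)), np.zeros((1, 1)))


class TestElbo:
    def _embeddings(self, n=4, d=2):
        return VariationalEmbedding(mu=Tensor(np.zeros((n, d))),
                                    sigma=Tensor(np.ones((n, d))))

    def test_perfect_probabilities_zero_reconstruction(self):
        labels = np.array([1.0, 0.0, 1.0])
        probs = Tensor(labels.copy())
        total, bd = elbo(labels, np.full(3, 0.5), probs, probs,
                         self._embeddings(), self._embeddings())
        # both branch probabilities equal the labels -> log-likelihood 0
        # (up to the numerical probability floor)
        assert bd.reconstruction == pytest.approx(0.0, abs=1e-6)

    def test_total_never_exceeds_reconstruction(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, size=6).astype(float)
        p1 = Tensor(rng.uniform(0.01, 0.99, size=6))
        p2 = Tensor(rng.uniform(0.01, 0.99, size=6))
        mu = Tensor(rng.normal(size=(5, 3)))
        sigma = Tensor(rng.uniform(0.2, 2, size=(5, 3)))
        emb = VariationalEmbedding(mu=mu, sigma=sigma)
        total, bd = elbo(labels, np.full(6, 0.3), p1, p2, emb,
                         self._embeddings(5, 3))
        assert bd.total <= bd.reconstruction
        assert bd.kl_similarity >= 0 and bd.kl_degree >= 0

    def test_weight_one_ignores_degree_branch(self):
        labels = np.array([1.0, 0.0])
        good = Tensor(np.array([0.9, 0.1]))
        bad = Tensor(np.array([0.1, 0.9]))
        _, with_bad = elbo(labels, np.ones(2), good, bad,
                           self._embeddings(), self._embeddings())
        _, with_good = elbo(labels, np.ones(2), good, good,
                            self._embeddings(), self._embeddings())
        assert with_bad.reconstruction == pytest.approx(
            with_good.reconstruction)


class TestEMStep:
    def test_equal_likelihoods_fixed_point(self):
        state = MixtureDecoderState(p_s=0.37)
        lik = np.column_stack([np.full(10, 0.6), np.full(10, 0.6)])
        new = em_step(lik, state)
        assert new.p_s == pytest.approx(0.37)
        assert np.allclose(new.responsibilities, 0.37)

    def test_zero_degree_likelihood_gives_full_responsibility(self):
        state = MixtureDecoderState(p_s=0.5)
        new = em_step(np.array([[0.8, 0.0]]), state)
        assert new.responsibilities[0] == pytest.approx(1.0)

    def test_degenerate_zero_zero_resolves_to_prior(self):
        state = MixtureDecoderState(p_s=0.41)
        new = em_step(np.array([[0.0, 0.0]]), state)
        assert new.responsibilities[0] == pytest.approx(0.41)

    @pytest.mark.parametrize("seed", range(10))
    def test_loglik_nondecreasing_over_twenty_steps(self, seed):
        """EM monotonicity with frozen branch likelihoods."""
        rng = np.random.default_rng(seed)
        lik = rng.uniform(0.01, 1.0, size=(40, 2))
        state = MixtureDecoderState(p_s=float(rng.uniform(0.05, 0.95)))
        prev = mixture_loglik(lik, state.p_s)
        for _ in range(20):
            state = em_step(lik, state)
            cur = mixture_loglik(lik, state.p_s)
            assert cur >= prev - 1e-10
            prev = cur
        assert 0.0 <= state.p_s <= 1.0

    def test_negative_likelihood_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            em_step(np.array([[-0.1, 0.5]]), MixtureDecoderState(0.5))


class TestFit:
    def test_deterministic_under_seed(self, sim_sample, fast_config):
        graph = sim_sample.graph
        cfg = TrainConfig(**{**fast_config.to_dict(), "epochs": 15})
        r1 = AssociationModel(graph, cfg).fit(seed=5)
        r2 = AssociationModel(graph, cfg).fit(seed=5)
        assert np.array_equal(r1.mu_similarity, r2.mu_similarity)
        assert r1.p_s == r2.p_s
        assert [b.total for b in r1.loss_history] == \
            [b.total for b in r2.loss_history]

    def test_loss_trajectory_finite_and_p_s_in_unit_interval(
            self, trained_sim):
        results, _ = trained_sim
        assert all(np.isfinite(b.total) for b in results.loss_history)
        assert all(0.0 <= p <= 1.0 for p in results.p_s_history)
        assert all(b.kl_similarity >= 0 and b.kl_degree >= 0
                   for b in results.loss_history)

    def test_empty_graph_rejected(self):
        from snolink.graph import BipartiteGraph
        g = BipartiteGraph(["s"], ["d"], set())
        with pytest.raises(ValueError, match="at least one edge"):
            AssociationModel(g)

    def test_results_roundtrip_through_checkpoint(self, trained_sim,
                                                  tmp_path):
        results, _ = trained_sim
        results.save(tmp_path / "ckpt")
        back = AssociationResults.load(tmp_path / "ckpt")
        assert np.array_equal(back.mu_similarity, results.mu_similarity)
        assert back.p_s == results.p_s
        assert back.train_edges == results.train_edges
        pairs = sorted(results.train_edges)[:5]
        assert np.allclose(back.scores_for_pairs_array(pairs),
                           results.scores_for_pairs_array(pairs))

    def test_summary_mentions_key_quantities(self, trained_sim):
        results, _ = trained_sim
        text = results.summary()
        assert "mixture weight" in text
        assert "reconstruction" in text
        assert str(results.graph.n_s) in text


class TestPlainVgaeReduction:
    """With p_s fixed at 1 and the degree branch at its prior, the model
    is a plain cosine-decoder VGAE: an independent numpy implementation
    of that forward pass must reproduce loss and predictions exactly."""

    def test_loss_and_scores_match_reference(self, tiny_graph):
        g = tiny_graph
        op = build_propagation_operator(g)
        rng = np.random.default_rng(0)
        params = init_encoder_params(g.n_nodes, 5, 3, rng)
        feats = NodeFeatures.one_hot(g.n_nodes)

        emb = encode_similarity(feats, op, params)
        z = reparameterize(emb, seed=11)
        pos = sorted(g.edges)
        negs = sorted(sample_negatives(g, 1, seed=2))
        pairs = pos + negs
        labels = np.array([1.0] * len(pos) + [0.0] * len(negs))
        a = np.array([s for s, _ in pairs])
        b = np.array([g.n_s + d for _, d in pairs])
        probs = cosine_scores(z.take_rows(a), z.take_rows(b))
        prior = VariationalEmbedding(mu=Tensor(np.zeros((g.n_nodes, 2))),
                                     sigma=Tensor(np.ones((g.n_nodes, 2))))
        total, bd = elbo(labels, np.ones(len(pairs)), probs,
                         Tensor(np.full(len(pairs), 0.5)), emb, prior,
                         recon_scale=2.0, kl_scale=0.25)

        # ----- independent reference (numpy only, no autodiff) -----
        def ref_l2(h, t):
            n = np.linalg.norm(h, axis=1, keepdims=True)
            out = np.where(n > 1e-12, t * h / np.where(n > 0, n, 1.0), 0.0)
            return out

        P = op.matrix
        h1 = P @ ref_l2(np.eye(g.n_nodes) @ params.W1.data, 1.8)
        mu = P @ ref_l2(h1 @ params.W2_mu.data, 1.8)
        log_sig = P @ (h1 @ params.W2_sigma.data) + params.b_sigma.data
        sig = np.exp(log_sig)
        eta = np.random.default_rng(11).standard_normal(mu.shape)
        z_ref = mu + sig * eta
        za, zb = z_ref[a], z_ref[b]
        cos = np.einsum("ij,ij->i", za, zb) / (
            np.linalg.norm(za, axis=1) * np.linalg.norm(zb, axis=1) + 1e-12)
        p_ref = 1 / (1 + np.exp(-cos))
        p_ref = np.clip(p_ref, 1e-10, 1 - 1e-10)
        recon_ref = np.sum(labels * np.log(p_ref)
                           + (1 - labels) * np.log(1 - p_ref)) * 2.0
        kl_ref = 0.25 * 0.5 * np.sum(sig ** 2 + mu ** 2 - 1 - 2 * log_sig)
        # degree branch at its prior contributes zero KL
        total_ref = recon_ref - kl_ref

        assert np.allclose(emb.mu.data, mu, atol=1e-10)
        assert np.allclose(probs.data, p_ref, atol=1e-10)
        assert bd.reconstruction == pytest.approx(recon_ref, abs=1e-6)
        assert bd.kl_similarity == pytest.approx(kl_ref, abs=1e-6)
        assert bd.kl_degree == pytest.approx(0.0, abs=1e-12)
        assert float(total.data) == pytest.approx(total_ref, abs=1e-6)


def test_bernoulli_loglik_floors_extreme_probabilities():
    probs = Tensor(np.array([0.0, 1.0, 0.5]))
    labels = np.array([1.0, 0.0, 1.0])
    ll = bernoulli_loglik(probs, labels)
    assert np.all(np.isfinite(ll.data))


def test_loss_breakdown_rejects_negative_kl():
    with pytest.raises(ValueError):
        LossBreakdown(reconstruction=-1.0, kl_similarity=-0.1,
                      kl_degree=0.0, total=-1.0)
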