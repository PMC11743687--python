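"""Decoupled variational graph autoencoder for bipartite association data.

:class:`AssociationModel` is built from a :class:`~snolink.graph.BipartiteGraph`
and a :class:`TrainConfig`; :meth:`AssociationModel.fit` maximizes the
evidence lower bound

    L = E_q[log p(A | Z_s, Z_d)] - KL(q(Z_s) || N(0, I)) - KL(q(Z_d) || N(0, I))

where the reconstruction term is a two-component Bernoulli mixture: each
observed pair is explained either by the similarity decoder (cosine of the
similarity-branch embeddings) or by the popularity decoder (component sum
of the degree-branch embeddings), with mixture weight ``p_s`` re-estimated
by EM during training. Gradient steps on the encoder/decoder parameters
alternate with EM updates of ``p_s``; balanced negatives are redrawn every
epoch.

:meth:`fit` returns an :class:`AssociationResults` carrying the fitted
posterior means, the mixture weight, per-edge responsibilities, the loss
trajectory and prediction/ranking helpers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .autodiff import Tensor, as_tensor
from .decoder import MixtureDecoderState, cosine_scores, popularity_scores
from .encoder import (NodeFeatures, VariationalEmbedding, encode_degree,
                      encode_similarity, init_encoder_params, reparameterize)
from .graph import BipartiteGraph, Edge, build_propagation_operator, \
    sample_negatives
from .kan import init_kan_layer

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "LossBreakdown", "TrainingError",
           "gaussian_kl", "elbo", "em_step",
           "AssociationModel", "AssociationResults"]

_EPS = 1e-12
_PROB_FLOOR = 1e-10  # keeps Bernoulli log-likelihoods finite


class TrainingError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the epoch index."""

    def __init__(self, epoch: int, message: str):
        super().__init__(f"epoch {epoch}: {message}")
        self.epoch = epoch


@dataclass
class TrainConfig:
    """Hyperparameters of the model and its training loop.

    The row-norm scale ``t`` defaults to 1.8 and the hidden dimension to
    256 (upper end of the range where held-out accuracy plateaus); the
    similarity latent dimension is 64. The degree branch is deliberately
    narrower — popularity is close to a scalar signal per node.
    """

    epochs: int = 200
    learning_rate: float = 1e-2
    hidden_dim: int = 256
    latent_dim: int = 64
    degree_hidden_dim: int = 64
    degree_latent_dim: int = 16
    t: float = 1.8
    k_folds: int = 5
    seed: int = 0
    em_period: int = 1          # run one EM update every this many epochs
    em_warmup: int = 50         # epochs before the first EM update
    p_s_floor: float = 0.01     # keep p_s in [floor, 1-floor] during training
    negatives_per_positive: float = 1.0
    init_p_s: float = 0.5
    kan_grid_intervals: int = 5
    kan_order: int = 3
    log_sigma_init: float = -2.0

    def __post_init__(self):
        positive = ["epochs", "learning_rate", "hidden_dim", "latent_dim",
                    "degree_hidden_dim", "degree_latent_dim", "t", "k_folds",
                    "em_period", "negatives_per_positive"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.init_p_s <= 1.0:
            raise ValueError("init_p_s must lie in [0, 1]")

    @staticmethod
    def from_yaml(path: str | Path) -> "TrainConfig":
        import yaml
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return TrainConfig(**payload)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LossBreakdown:
    """Per-epoch decomposition of the (maximized) objective."""

    reconstruction: float
    kl_similarity: float
    kl_degree: float
    total: float

    def __post_init__(self):
        if self.kl_similarity < 0 or self.kl_degree < 0:
            raise ValueError("KL terms must be nonnegative")


# ----------------------------------------------------------------------
def gaussian_kl(mu, sigma):
    """KL( N(mu, diag(sigma^2)) || N(0, I) ), summed over all entries.

    Closed form: sum of 0.5 * (sigma^2 + mu^2 - 1 - 2 log sigma) >= 0.
    Accepts numpy arrays (returns float) or Tensors (returns a scalar
    Tensor for backpropagation).
    """
    mu_t, sigma_t = as_tensor(mu), as_tensor(sigma)
    if np.any(sigma_t.data <= 0):
        raise ValueError("sigma must be strictly positive")
    kl = ((sigma_t * sigma_t + mu_t * mu_t - 1.0
           - 2.0 * sigma_t.log()) * 0.5).sum()
    if isinstance(mu, Tensor) or isinstance(sigma, Tensor):
        return kl
    return float(kl.data)


def bernoulli_loglik(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Elementwise y log p + (1-y) log(1-p), with probabilities floored
    away from {0, 1} so the log stays finite."""
    p = probs.data
    clipped_low = p < _PROB_FLOOR
    clipped_high = p > 1.0 - _PROB_FLOOR

    # clip with pass-through gradient in the interior
    def bwd(g):
        probs._accumulate(np.where(clipped_low | clipped_high, 0.0, g))

    safe = Tensor.from_op(np.clip(p, _PROB_FLOOR, 1.0 - _PROB_FLOOR),
                          (probs,), bwd)
    y = as_tensor(labels)
    return y * safe.log() + (1.0 - y) * (1.0 - safe).log()


def elbo(labels: np.ndarray, weights: np.ndarray,
         probs_similarity: Tensor, probs_degree: Tensor,
         emb_s: VariationalEmbedding, emb_d: VariationalEmbedding,
         recon_scale: float = 1.0, kl_scale: float = 1.0
         ) -> tuple[Tensor, LossBreakdown]:
    """Mixture evidence lower bound over a balanced labeled batch.

    ``weights`` carries, per pair, the weight on the similarity branch's
    Bernoulli log-likelihood (EM responsibility for positives, the global
    mixture weight for negatives); the degree branch gets ``1 - weight``.

    Scaling follows the reference variational graph autoencoder training
    convention: the reconstruction likelihood is defined over the whole
    adjacency, so the trainer passes ``recon_scale`` = (total pairs) /
    (batch pairs) to scale the balanced subsample up to the full-graph
    bound, and ``kl_scale`` = 1 / (node count) so each KL term enters as
    a per-node average. Returns (scalar Tensor to maximize, float
    breakdown). The total never exceeds the reconstruction term because
    both KL terms are >= 0.
    """
    w = as_tensor(np.asarray(weights, dtype=np.float64))
    ll_s = bernoulli_loglik(probs_similarity, labels)
    ll_d = bernoulli_loglik(probs_degree, labels)
    recon = (w * ll_s + (1.0 - w) * ll_d).sum() * recon_scale
    kl_s = gaussian_kl(emb_s.mu, emb_s.sigma) * kl_scale
    kl_d = gaussian_kl(emb_d.mu, emb_d.sigma) * kl_scale
    total = recon - kl_s - kl_d
    breakdown = LossBreakdown(reconstruction=float(recon.data),
                              kl_similarity=float(kl_s.data),
                              kl_degree=float(kl_d.data),
                              total=float(total.data))
    return total, breakdown


def em_step(likelihoods: Sequence[tuple[float, float]] | np.ndarray,
            state: MixtureDecoderState) -> MixtureDecoderState:
    """One EM update of the mixture weight from per-edge branch likelihoods.

    E-step: r_e = p_s L_s(e) / (p_s L_s(e) + q_s L_d(e)), with the 0/0
    degenerate case resolved to r_e = p_s. M-step: p_s' = mean(r_e).
    With frozen likelihoods the observed-data log-likelihood
    sum_e log(p_s L_s + q_s L_d) is non-decreasing across steps.
    """
    lik = np.asarray(likelihoods, dtype=np.float64)
    if lik.ndim != 2 or lik.shape[1] != 2:
        raise ValueError("likelihoods must be an (n, 2) array of (L_s, L_d)")
    if np.any(lik < 0):
        raise ValueError("likelihoods must be nonnegative")
    ls, ld = lik[:, 0], lik[:, 1]
    num = state.p_s * ls
    den = num + state.q_s * ld
    with np.errstate(invalid="ignore", divide="ignore"):
        resp = np.where(den > 0, num / np.maximum(den, _EPS), state.p_s)
    p_s = float(np.mean(resp)) if resp.size else state.p_s
    return MixtureDecoderState(p_s=min(max(p_s, 0.0), 1.0),
                               responsibilities=resp)


def mixture_loglik(likelihoods, p_s: float) -> float:
    """Observed-data log-likelihood of the Bernoulli mixture (EM monitor)."""
    lik = np.asarray(likelihoods, dtype=np.float64)
    mix = p_s * lik[:, 0] + (1.0 - p_s) * lik[:, 1]
    return float(np.sum(np.log(np.maximum(mix, _EPS))))


# ----------------------------------------------------------------------
class _Adam:
    """Minimal Adam optimizer over a list of Tensors (maximizes by
    stepping against the gradient of the negated objective)."""

    def __init__(self, params: Sequence[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, *betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ----------------------------------------------------------------------
class AssociationModel:
    """Decoupled VGAE over a bipartite association graph.

    Parameters
    ----------
    graph : BipartiteGraph
        Node vocabularies and observed associations.
    config : TrainConfig, optional
        Hyperparameters; defaults are the package defaults.
    features : NodeFeatures, optional
        Similarity-branch input features; one-hot identity by default.
    """

    def __init__(self, graph: BipartiteGraph, config: TrainConfig | None = None,
                 features: NodeFeatures | None = None):
        if graph.n_edges < 1:
            raise ValueError("graph must contain at least one edge")
        self.graph = graph
        self.config = config or TrainConfig()
        self.features = features or NodeFeatures.one_hot(graph.n_nodes)
        if self.features.matrix.shape[0] != graph.n_nodes:
            raise ValueError("feature rows must match node count")

    @classmethod
    def from_edge_list(cls, path: str | Path,
                       config: TrainConfig | None = None) -> "AssociationModel":
        from .graph import load_edge_list
        return cls(load_edge_list(path), config)

    # ------------------------------------------------------------------
    def _init_params(self, rng: np.random.Generator):
        cfg = self.config
        n = self.graph.n_nodes
        grid = np.linspace(-1.0, 1.0, cfg.kan_grid_intervals + 1)
        kan = init_kan_layer(cfg.degree_hidden_dim, cfg.degree_latent_dim,
                             rng, grid=grid, order=cfg.kan_order)
        sim = init_encoder_params(self.features.matrix.shape[1],
                                  cfg.hidden_dim, cfg.latent_dim, rng,
                                  t=cfg.t, branch="similarity",
                                  log_sigma_init=cfg.log_sigma_init)
        deg = init_encoder_params(n, cfg.degree_hidden_dim,
                                  cfg.degree_latent_dim, rng, t=cfg.t,
                                  branch="degree", kan=kan,
                                  log_sigma_init=cfg.log_sigma_init)
        return sim, deg

    def fit(self, train_edges: Iterable[Edge] | None = None,
            seed: int | None = None, verbose: bool = False,
            exclude_negatives: set[Edge] | None = None
            ) -> "AssociationResults":
        """Train on ``train_edges`` (default: all observed edges).

        ``exclude_negatives`` pairs are never drawn as training negatives
        (use for frozen evaluation negatives). Deterministic under
        (config, seed).
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        positives = sorted(set(train_edges) if train_edges is not None
                           else self.graph.edges)
        if not positives:
            raise ValueError("no training edges")
        train_graph = self.graph.with_edges(positives)
        op = build_propagation_operator(train_graph)
        sim_params, deg_params = self._init_params(rng)
        trainable = sim_params.trainable + deg_params.trainable
        optimizer = _Adam(trainable, cfg.learning_rate)
        state = MixtureDecoderState(p_s=cfg.init_p_s)
        n_s = self.graph.n_s
        pos_a = np.array([s for s, _ in positives])
        pos_b = np.array([n_s + d for _, d in positives])
        n_pos = len(positives)
        n_neg = int(round(cfg.negatives_per_positive * n_pos))
        exclude = set(exclude_negatives or ())
        history: list[LossBreakdown] = []
        p_s_history: list[float] = [state.p_s]

        for epoch in range(cfg.epochs):
            optimizer.zero_grad()
            emb_s = encode_similarity(self.features, op, sim_params)
            emb_d = encode_degree(op, deg_params)
            z_s = reparameterize(emb_s, rng=rng)
            z_d = reparameterize(emb_d, rng=rng)

            negatives = sorted(sample_negatives(
                self.graph, n_neg, exclude=exclude,
                seed=int(rng.integers(2 ** 31))))
            neg_a = np.array([s for s, _ in negatives])
            neg_b = np.array([n_s + d for _, d in negatives])
            a_idx = np.concatenate([pos_a, neg_a])
            b_idx = np.concatenate([pos_b, neg_b])
            labels = np.concatenate([np.ones(n_pos), np.zeros(len(negatives))])

            p_sim = cosine_scores(z_s.take_rows(a_idx), z_s.take_rows(b_idx))
            p_deg = popularity_scores(z_d.take_rows(a_idx),
                                      z_d.take_rows(b_idx))

            # EM update on the positive edges with frozen branch likelihoods.
            # The warm-up lets both branches acquire signal before the
            # mixture weight starts moving; updating from epoch 0 lets the
            # initially-better branch freeze the other out (rich-get-richer
            # collapse to p_s in {0, 1}).
            if epoch >= cfg.em_warmup and epoch % cfg.em_period == 0:
                lik = np.stack([p_sim.data[:n_pos], p_deg.data[:n_pos]],
                               axis=1)
                state = em_step(lik, state)
                # keep the mixture weight off the absorbing boundaries so
                # the minority branch keeps receiving gradient
                clamped = min(max(state.p_s, cfg.p_s_floor),
                              1.0 - cfg.p_s_floor)
                if clamped != state.p_s:
                    state = MixtureDecoderState(
                        p_s=clamped,
                        responsibilities=state.responsibilities)
            weights = np.concatenate([
                state.responsibilities if state.responsibilities is not None
                and len(state.responsibilities) == n_pos
                else np.full(n_pos, state.p_s),
                np.full(len(negatives), state.p_s)])

            recon_scale = (self.graph.n_s * self.graph.n_d) / len(labels)
            total, breakdown = elbo(labels, weights, p_sim, p_deg,
                                    emb_s, emb_d, recon_scale=recon_scale,
                                    kl_scale=1.0 / self.graph.n_nodes)
            if not np.isfinite(breakdown.total):
                raise TrainingError(epoch, "non-finite loss")
            (-total).backward()
            optimizer.step()
            history.append(breakdown)
            p_s_history.append(state.p_s)
            if verbose and (epoch % 20 == 0 or epoch == cfg.epochs - 1):
                logger.info("epoch %d: total=%.2f recon=%.2f p_s=%.3f",
                            epoch, breakdown.total, breakdown.reconstruction,
                            state.p_s)

        # final deterministic embeddings (posterior means) and responsibilities
        emb_s = encode_similarity(self.features, op, sim_params)
        emb_d = encode_degree(op, deg_params)
        mu_s, sig_s = emb_s.mu.data.copy(), emb_s.sigma.data.copy()
        mu_d, sig_d = emb_d.mu.data.copy(), emb_d.sigma.data.copy()
        p_fs = _pair_probs(mu_s, pos_a, pos_b, "cosine")
        p_fd = _pair_probs(mu_d, pos_a, pos_b, "sum")
        state = em_step(np.stack([p_fs, p_fd], axis=1), state)
        return AssociationResults(
            graph=self.graph, config=cfg, seed=seed,
            train_edges=set(positives),
            mu_similarity=mu_s, sigma_similarity=sig_s,
            mu_degree=mu_d, sigma_degree=sig_d,
            p_s=state.p_s,
            responsibilities={e: float(r)
                              for e, r in zip(positives,
                                              state.responsibilities)},
            loss_history=history, p_s_history=p_s_history,
            params={"similarity": sim_params, "degree": deg_params})


def _pair_probs(mu: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray,
                kind: str) -> np.ndarray:
    za, zb = mu[a_idx], mu[b_idx]
    if kind == "cosine":
        na = np.linalg.norm(za, axis=1)
        nb = np.linalg.norm(zb, axis=1)
        cos = np.where((na > _EPS) & (nb > _EPS),
                       np.einsum("ij,ij->i", za, zb)
                       / np.maximum(na * nb, _EPS), 0.0)
        return 1.0 / (1.0 + np.exp(-cos))
    return 1.0 / (1.0 + np.exp(-np.clip(za.sum(1) + zb.sum(1), -500, 500)))


# ----------------------------------------------------------------------
@dataclass
class AssociationResults:
    """Fitted decoupled-VGAE: posterior means, mixture weight, diagnostics.

    Prediction uses the posterior means (no sampling), scoring a pair as
    ``p_s * sigmoid(cos) + (1 - p_s) * sigmoid(sum)``.
    """

    graph: BipartiteGraph
    config: TrainConfig
    seed: int
    train_edges: set[Edge]
    mu_similarity: np.ndarray
    sigma_similarity: np.ndarray
    mu_degree: np.ndarray
    sigma_degree: np.ndarray
    p_s: float
    responsibilities: dict[Edge, float]
    loss_history: list[LossBreakdown]
    p_s_history: list[float]
    params: dict = field(default_factory=dict, repr=False)

    # -- scoring -------------------------------------------------------
    def pair_scores(self, pairs: Sequence[Edge]) -> pd.DataFrame:
        """Score (snorna_index, disease_index) pairs.

        Returns a frame with the mixture score, both branch probabilities,
        and the similarity-mechanism responsibility for each pair.
        """
        pairs = list(pairs)
        n_s = self.graph.n_s
        a_idx = np.array([s for s, _ in pairs], dtype=int)
        b_idx = np.array([n_s + d for _, d in pairs], dtype=int)
        p_fs = _pair_probs(self.mu_similarity, a_idx, b_idx, "cosine")
        p_fd = _pair_probs(self.mu_degree, a_idx, b_idx, "sum")
        score = self.p_s * p_fs + (1.0 - self.p_s) * p_fd
        num = self.p_s * p_fs
        den = num + (1.0 - self.p_s) * p_fd
        resp = np.where(den > 0, num / np.maximum(den, _EPS), self.p_s)
        return pd.DataFrame({
            "snorna_id": [self.graph.snorna_ids[s] for s, _ in pairs],
            "disease_id": [self.graph.disease_ids[d] for _, d in pairs],
            "score": score,
            "p_similarity_branch": p_fs,
            "p_degree_branch": p_fd,
            "responsibility": resp,
        })

    def predict(self, snorna_id: str, disease_id: str) -> pd.Series:
        pair = (self.graph.snorna_index(snorna_id),
                self.graph.disease_index(disease_id))
        return self.pair_scores([pair]).iloc[0]

    def scores_for_pairs_array(self, pairs: Sequence[Edge]) -> np.ndarray:
        return self.pair_scores(pairs)["score"].to_numpy()

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        """Statsmodels-style text summary of the fit."""
        cfg = self.config
        last = self.loss_history[-1] if self.loss_history else None
        lines = [
            "            Decoupled Variational Graph Autoencoder",
            "=" * 64,
            f"snoRNA nodes:      {self.graph.n_s:>8}    "
            f"disease nodes:   {self.graph.n_d:>8}",
            f"training edges:    {len(self.train_edges):>8}    "
            f"epochs:          {cfg.epochs:>8}",
            f"hidden dim:        {cfg.hidden_dim:>8}    "
            f"latent dim (sim):{cfg.latent_dim:>8}",
            f"latent dim (deg):  {cfg.degree_latent_dim:>8}    "
            f"norm scale t:    {cfg.t:>8.2f}",
            "-" * 64,
            f"mixture weight p_s (similarity mechanism): {self.p_s:.4f}",
            f"degree-mechanism weight 1 - p_s:           {1 - self.p_s:.4f}",
        ]
        if last is not None:
            lines += [
                f"final ELBO:            {last.total:>12.3f}",
                f"  reconstruction:      {last.reconstruction:>12.3f}",
                f"  KL (similarity):     {last.kl_similarity:>12.3f}",
                f"  KL (degree):         {last.kl_degree:>12.3f}",
            ]
        resp = np.array(list(self.responsibilities.values()))
        if resp.size:
            lines.append(
                f"edge responsibilities: mean {resp.mean():.3f}, "
                f"{(resp > 0.5).mean() * 100:.1f}% similarity-attributed")
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Plot the ELBO trajectory (total and components) per epoch."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(len(self.loss_history))
        ax.plot(epochs, [b.total for b in self.loss_history], label="ELBO")
        ax.plot(epochs, [b.reconstruction for b in self.loss_history],
                label="reconstruction", alpha=0.7)
        ax.plot(epochs, [-(b.kl_similarity + b.kl_degree)
                         for b in self.loss_history],
                label="-(KL_s + KL_d)", alpha=0.7)
        ax.set_xlabel("epoch")
        ax.set_ylabel("objective")
        ax.legend()
        return ax

    def loss_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(b) for b in self.loss_history])

    # -- persistence -----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Checkpoint: JSON metadata plus parameter arrays (.npz)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.to_dict(), "seed": self.seed,
            "p_s": self.p_s,
            "snorna_ids": self.graph.snorna_ids,
            "disease_ids": self.graph.disease_ids,
            "edges": sorted(self.graph.edges),
            "train_edges": sorted(self.train_edges),
            "responsibilities": {f"{s},{d}": r for (s, d), r
                                 in self.responsibilities.items()},
            "p_s_history": self.p_s_history,
            "loss_history": [asdict(b) for b in self.loss_history],
        }
        (directory / "meta.json").write_text(json.dumps(meta))
        np.savez(directory / "arrays.npz",
                 mu_similarity=self.mu_similarity,
                 sigma_similarity=self.sigma_similarity,
                 mu_degree=self.mu_degree,
                 sigma_degree=self.sigma_degree)

    @staticmethod
    def load(directory: str | Path) -> "AssociationResults":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        arrays = np.load(directory / "arrays.npz")
        graph = BipartiteGraph(meta["snorna_ids"], meta["disease_ids"],
                               {tuple(e) for e in meta["edges"]})
        return AssociationResults(
            graph=graph, config=TrainConfig(**meta["config"]),
            seed=meta["seed"],
            train_edges={tuple(e) for e in meta["train_edges"]},
            mu_similarity=arrays["mu_similarity"],
            sigma_similarity=arrays["sigma_similarity"],
            mu_degree=arrays["mu_degree"],
            sigma_degree=arrays["sigma_degree"],
            p_s=meta["p_s"],
            responsibilities={tuple(map(int, k.split(","))): v for k, v
                              in meta["responsibilities"].items()},
            loss_history=[LossBreakdown(**b) for b in meta["loss_history"]],
            p_s_history=meta["p_s_history"])
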