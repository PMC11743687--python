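"""The L2-regularized GCN encoder and its two variational branches.

A two-layer graph convolution produces per-node Gaussian posteriors
N(mu_a, diag(sigma_a^2)). Two branches exist:

* the **similarity** branch encodes one-hot (or user) node features, with
  every layer's linear output rescaled row-wise to Euclidean norm ``t``
  before propagation — this keeps low-degree nodes from vanishing and
  high-degree nodes from dominating message passing;
* the **degree** branch encodes the identity matrix (the node itself, not
  its features) through the same symmetric normalized propagation but
  *without* the per-row rescaling, so embedding norms remain free to track
  node degree; its second mean layer is a Kolmogorov-Arnold layer.

The mu and sigma heads of a branch share the first-layer weights and then
propagate independently; sigma is parameterized as exp(log sigma) so it
stays strictly positive, and the row rescaling is applied on the mu path
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .autodiff import Tensor, as_tensor
from .graph import PropagationOperator
from .kan import KanLayerParams, kan_layer

logger = logging.getLogger(__name__)

__all__ = ["NodeFeatures", "EncoderParams", "VariationalEmbedding",
           "l2_scale", "propagate", "encode_similarity", "encode_degree",
           "reparameterize", "init_encoder_params"]

_EPS = 1e-12


@dataclass
class NodeFeatures:
    """Initial node feature matrix X, rows in unified node ordering."""

    matrix: np.ndarray
    provenance: Literal["one_hot_identity", "user_supplied"] = "one_hot_identity"

    @staticmethod
    def one_hot(n_nodes: int) -> "NodeFeatures":
        return NodeFeatures(np.eye(n_nodes), "one_hot_identity")

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.provenance == "one_hot_identity":
            n, f = self.matrix.shape
            if n != f or not np.array_equal(self.matrix, np.eye(n)):
                raise ValueError("one_hot_identity features must be I(n)")


@dataclass
class EncoderParams:
    """Trainable weights of one branch.

    W1 is shared between the mu and sigma heads; W2_mu / W2_sigma are the
    per-head second layers. ``t`` is the row-norm scale (default 1.8). The
    degree branch replaces the W2_mu linear map with a KAN layer.
    """

    W1: Tensor
    W2_mu: Tensor | None
    W2_sigma: Tensor
    t: float = 1.8
    branch: Literal["similarity", "degree"] = "similarity"
    kan: KanLayerParams | None = None
    b_sigma: Tensor | None = None  # additive log-sigma bias (trainable)

    def __post_init__(self):
        if self.t <= 0:
            raise ValueError("scaling parameter t must be positive")
        if self.branch == "degree" and self.kan is None:
            raise ValueError("degree branch requires a KAN layer")
        if self.branch == "similarity" and self.W2_mu is None:
            raise ValueError("similarity branch requires W2_mu")

    @property
    def trainable(self) -> tuple[Tensor, ...]:
        params = [self.W1, self.W2_sigma]
        if self.W2_mu is not None:
            params.append(self.W2_mu)
        if self.b_sigma is not None:
            params.append(self.b_sigma)
        if self.kan is not None:
            params.extend(self.kan.trainable)
        return tuple(params)


@dataclass
class VariationalEmbedding:
    """Per-node Gaussian posterior parameters of one branch."""

    mu: Tensor
    sigma: Tensor
    branch: Literal["similarity", "degree"] = "similarity"

    def __post_init__(self):
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma shapes disagree")
        if np.any(self.sigma.data <= 0):
            raise ValueError("sigma must be strictly positive")

    @property
    def n_nodes(self) -> int:
        return self.mu.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.mu.shape[1]


def l2_scale(h: Tensor | np.ndarray, t: float = 1.8) -> Tensor:
    """Rescale each row to Euclidean norm ``t``; zero rows stay zero.

    Rows with norm <= 1e-12 are returned as zero (a warning is logged):
    rescaling them would divide by ~0 and their direction is undefined.
    """
    h = as_tensor(h)
    if t <= 0:
        raise ValueError("scaling parameter t must be positive")
    if not np.all(np.isfinite(h.data)):
        raise ValueError("non-finite values in input to l2_scale")
    sq = (h * h).sum(axis=1, keepdims=True)
    norms = np.sqrt(sq.data)
    zero_rows = norms[:, 0] <= _EPS
    if np.any(zero_rows):
        logger.warning("l2_scale: %d zero row(s) left unscaled",
                       int(zero_rows.sum()))
    # gradient flows through the norm for nonzero rows; zero rows are gated
    gate = (~zero_rows).astype(np.float64)[:, None]
    safe_norm = (sq + np.where(zero_rows[:, None], 1.0, 0.0)).sqrt()
    return h * (gate * t) / safe_norm


def propagate(n_mat: Tensor | np.ndarray, op: PropagationOperator) -> Tensor:
    """One round of symmetric-normalized message passing: op.matrix @ N.

    Row a of the output is n_a/(d_a+1) + sum_{b in N(a)} n_b/sqrt((d_a+1)(d_b+1)).
    """
    n_mat = as_tensor(n_mat)
    if n_mat.shape[0] != op.n_nodes:
        raise ValueError(
            f"feature rows {n_mat.shape[0]} != operator dim {op.n_nodes}")
    return as_tensor(op.matrix) @ n_mat


def encode_similarity(x: NodeFeatures, op: PropagationOperator,
                      params: EncoderParams) -> VariationalEmbedding:
    """Two-layer variational encoding of node features.

    mu path: propagate(l2_scale(X W1, t)) -> propagate(l2_scale(H W2_mu, t));
    sigma path shares the first layer, then propagates H W2_sigma without
    the row rescaling and exponentiates.
    """
    if params.branch != "similarity":
        raise ValueError("params.branch must be 'similarity'")
    x_t = as_tensor(x.matrix)
    h1 = propagate(l2_scale(x_t @ params.W1, params.t), op)
    mu = propagate(l2_scale(h1 @ params.W2_mu, params.t), op)
    log_sigma = propagate(h1 @ params.W2_sigma, op)
    if params.b_sigma is not None:
        log_sigma = log_sigma + params.b_sigma
    return VariationalEmbedding(mu=mu, sigma=log_sigma.exp(),
                                branch="similarity")


def encode_degree(op: PropagationOperator, params: EncoderParams
                  ) -> VariationalEmbedding:
    """Two-layer variational encoding of node identity (degree branch).

    Input features are the identity matrix, so the first layer is the
    t-scaled propagation t * P @ W1 with no per-row normalization; the
    second mean layer applies the KAN transform before a final propagation,
    and the sigma head stays linear. Output norms are free to vary with
    node degree.
    """
    if params.branch != "degree":
        raise ValueError("params.branch must be 'degree'")
    # X = I so g(X, W) = W; Eq.-4-style layer: t * P @ W
    h1 = propagate(params.W1, op) * params.t
    mu = propagate(kan_layer(h1, params.kan), op)
    log_sigma = propagate(h1 @ params.W2_sigma, op)
    if params.b_sigma is not None:
        log_sigma = log_sigma + params.b_sigma
    return VariationalEmbedding(mu=mu, sigma=log_sigma.exp(), branch="degree")


def reparameterize(emb: VariationalEmbedding, seed: int | None = None,
                   rng: np.random.Generator | None = None) -> Tensor:
    """Draw Z = mu + sigma * eta with eta ~ N(0, I); reproducible under seed.

    The noise is treated as a constant, so gradients flow to mu and sigma
    (the standard reparameterization trick).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    eta = rng.standard_normal(emb.mu.shape)
    return emb.mu + emb.sigma * as_tensor(eta)


def init_encoder_params(n_features: int, hidden_dim: int, latent_dim: int,
                        rng: np.random.Generator, t: float = 1.8,
                        branch: str = "similarity",
                        kan: KanLayerParams | None = None,
                        log_sigma_init: float = -2.0) -> EncoderParams:
    """Glorot-style initialization.

    The sigma head starts with small weights plus a trainable negative
    bias (sigma ~ exp(log_sigma_init)), so early epochs are nearly
    deterministic and the means can acquire signal before the KL term
    re-inflates the posterior scale; with the norm-capped means a
    unit-scale start would drown the cosine decoder in noise.
    """
    def glorot(n_in, n_out):
        limit = np.sqrt(6.0 / (n_in + n_out))
        return Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)),
                      requires_grad=True)

    w1 = glorot(n_features, hidden_dim)
    w2_sigma = Tensor(0.01 * rng.standard_normal((hidden_dim, latent_dim)),
                      requires_grad=True)
    w2_mu = None if branch == "degree" else glorot(hidden_dim, latent_dim)
    b_sigma = Tensor(np.full((1, latent_dim), float(log_sigma_init)),
                     requires_grad=True)
    return EncoderParams(W1=w1, W2_mu=w2_mu, W2_sigma=w2_sigma, t=t,
                         branch=branch, kan=kan, b_sigma=b_sigma)
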