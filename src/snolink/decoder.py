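"""Decoupled two-mechanism edge decoder.

An association between a snoRNA and a disease can arise in two ways:

* **similarity** — the two nodes are close in latent space; the decoder
  scores sigmoid(cosine(z_a, z_b)), which is invariant to embedding norm;
* **popularity** — one or both nodes are simply well connected; the degree
  branch scores sigmoid(1'z_a + 1'z_b), monotone in every component, so
  large-norm (high-degree) embeddings raise the probability.

A Bernoulli mixture with weight ``p_s`` (probability the similarity
mechanism generates an edge) combines the branches. The per-edge posterior
probability of the similarity mechanism — the EM responsibility — is what
makes the decoupling inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, sigmoid

__all__ = ["MixtureDecoderState", "similarity_edge_prob", "degree_edge_prob",
           "edge_probability", "two_stage_sample",
           "cosine_scores", "popularity_scores"]

_EPS = 1e-12


@dataclass
class MixtureDecoderState:
    """Mixture weight and per-edge responsibilities.

    ``p_s`` is the prior probability an edge is similarity-generated;
    ``responsibilities`` (aligned with an edge list) hold the posterior for
    each observed edge.
    """

    p_s: float = 0.5
    responsibilities: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_s <= 1.0:
            raise ValueError("p_s must lie in [0, 1]")
        if self.responsibilities is not None:
            r = np.asarray(self.responsibilities, dtype=np.float64)
            if np.any((r < 0) | (r > 1)):
                raise ValueError("responsibilities must lie in [0, 1]")
            self.responsibilities = r

    @property
    def q_s(self) -> float:
        return 1.0 - self.p_s


# -- batched scoring (Tensor-aware, used in training) -------------------
def cosine_scores(z_a: Tensor, z_b: Tensor) -> Tensor:
    """Row-wise sigmoid(cosine) for paired embedding batches."""
    dots = (z_a * z_b).sum(axis=1)
    na = ((z_a * z_a).sum(axis=1) + _EPS ** 2).sqrt()
    nb = ((z_b * z_b).sum(axis=1) + _EPS ** 2).sqrt()
    return sigmoid(dots / (na * nb + _EPS))

def popularity_scores(z_a: Tensor, z_b: Tensor) -> Tensor:
    """Row-wise sigmoid(sum of all components of both embeddings)."""
    return sigmoid(z_a.sum(axis=1) + z_b.sum(axis=1))


# -- scalar operations ---------------------------------------------------
def similarity_edge_prob(z_a, z_b) -> float:
    """sigmoid(cos(z_a, z_b)); symmetric and scale-invariant.

    Zero vectors get cosine 0 by convention (probability 0.5).
    """
    z_a = np.asarray(z_a, dtype=np.float64)
    z_b = np.asarray(z_b, dtype=np.float64)
    na, nb = np.linalg.norm(z_a), np.linalg.norm(z_b)
    cos = 0.0 if na <= _EPS or nb <= _EPS else float(z_a @ z_b / (na * nb))
    return float(1.0 / (1.0 + np.exp(-cos)))


def degree_edge_prob(z_a, z_b) -> float:
    """sigmoid(1'z_a + 1'z_b); symmetric, monotone in every component."""
    total = float(np.sum(z_a) + np.sum(z_b))
    return float(1.0 / (1.0 + np.exp(-np.clip(total, -500, 500))))


def edge_probability(p_fs: float, p_fd: float,
                     state: MixtureDecoderState) -> float:
    """Mixture probability p_s*p_fs + (1-p_s)*p_fd.

    This is the training and inference score; it is linear in p_s and lies
    between the two branch probabilities.
    """
    for name, p in (("p_fs", p_fs), ("p_fd", p_fd)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    return state.p_s * p_fs + state.q_s * p_fd


def two_stage_sample(p_fs: float, p_fd: float, seed: int | None = None,
                     rng: np.random.Generator | None = None
                     ) -> tuple[int, str | None]:
    """Sequential generative sampler: try the similarity Bernoulli first,
    then, only on failure, the popularity Bernoulli.

    Returns (0 or 1, mechanism tag or None). The marginal success
    probability is p_fs + (1-p_fs)*p_fd — a generative utility distinct
    from the mixture score used for training.
    """
    for name, p in (("p_fs", p_fs), ("p_fd", p_fd)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if rng.random() < p_fs:
        return 1, "similarity"
    if rng.random() < p_fd:
        return 1, "popularity"
    return 0, None
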