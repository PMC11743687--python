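"""Synthetic bipartite graphs with a known similarity/popularity mixture.

The generator emulates the structure the decoupled model assumes: each
edge is produced either by a latent-similarity mechanism (nodes carry
block-structured latent vectors; pair probability follows a softmax over
cosine similarities) or by a popularity mechanism (each node carries a
heavy-tailed Pareto weight; pair probability is proportional to the weight
product). The mixture weight, the block structure, the tail exponent and
the per-edge ground-truth mechanism labels are all known, so mechanism
recovery can be tested directly — something no real association database
offers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .graph import BipartiteGraph, Edge, load_edge_list, save_edge_list

__all__ = ["SyntheticSpec", "SyntheticSample", "generate", "fixture_suite"]


@dataclass
class SyntheticSpec:
    """Generator settings.

    ``mix_weight`` is the probability an edge comes from the similarity
    mechanism; ``degree_exponent`` is the Pareto tail exponent of the
    popularity weights (smaller = heavier tail, must exceed 1).
    """

    n_s: int = 200
    n_d: int = 50
    latent_dim: int = 8
    n_blocks: int = 4
    mix_weight: float = 0.95
    degree_exponent: float = 2.0
    n_edges: int = 1000
    temperature: float = 0.1
    noise: float = 0.3
    seed: int = 1

    def __post_init__(self):
        if not 0.0 <= self.mix_weight <= 1.0:
            raise ValueError("mix_weight must lie in [0, 1]")
        if self.degree_exponent <= 1.0:
            raise ValueError("degree_exponent must exceed 1")
        if self.n_edges > self.n_s * self.n_d:
            raise ValueError(
                f"n_edges={self.n_edges} exceeds the {self.n_s * self.n_d} "
                "possible pairs")
        if min(self.n_s, self.n_d, self.latent_dim, self.n_blocks,
               self.n_edges) < 1:
            raise ValueError("counts must be positive")


@dataclass
class SyntheticSample:
    """A generated graph plus its ground truth."""

    graph: BipartiteGraph
    mechanism: dict[Edge, str]           # "similarity" | "popularity"
    latent_s: np.ndarray                 # (n_s, latent_dim)
    latent_d: np.ndarray                 # (n_d, latent_dim)
    popularity_s: np.ndarray             # (n_s,)
    popularity_d: np.ndarray             # (n_d,)
    spec: SyntheticSpec = field(default=None)  # type: ignore[assignment]

    def mechanism_labels(self) -> np.ndarray:
        """1 for similarity-generated edges, 0 for popularity, in sorted
        edge order."""
        return np.array([1 if self.mechanism[e] == "similarity" else 0
                         for e in sorted(self.graph.edges)])


def _block_vectors(n: int, spec: SyntheticSpec,
                   centers: np.ndarray, rng: np.random.Generator
                   ) -> np.ndarray:
    blocks = rng.integers(0, spec.n_blocks, size=n)
    vecs = centers[blocks] + spec.noise * rng.standard_normal(
        (n, spec.latent_dim))
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)


def generate(spec: SyntheticSpec) -> SyntheticSample:
    """Draw a graph of exactly ``spec.n_edges`` distinct edges.

    Each edge first flips a ``mix_weight`` coin. Similarity edges are
    drawn from softmax(cosine / temperature) over all pairs; popularity
    edges from probabilities proportional to the product of the two
    endpoints' Pareto weights. Duplicate draws are rejected, so dense
    specs remain feasible. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    centers = rng.standard_normal((spec.n_blocks, spec.latent_dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    z_s = _block_vectors(spec.n_s, spec, centers, rng)
    z_d = _block_vectors(spec.n_d, spec, centers, rng)
    w_s = rng.pareto(spec.degree_exponent - 1.0, size=spec.n_s) + 1.0
    w_d = rng.pareto(spec.degree_exponent - 1.0, size=spec.n_d) + 1.0

    cos = z_s @ z_d.T                      # rows unit norm -> cosine
    sim_logits = cos / spec.temperature
    sim_p = np.exp(sim_logits - sim_logits.max())
    sim_p /= sim_p.sum()
    pop_p = np.outer(w_s, w_d)
    pop_p /= pop_p.sum()

    total = spec.n_s * spec.n_d
    sim_flat = sim_p.reshape(-1).copy()
    pop_flat = pop_p.reshape(-1).copy()
    edges: set[Edge] = set()
    mechanism: dict[Edge, str] = {}
    # sequential draws without replacement: the mechanism coin keeps its
    # Binomial(mix_weight) marginal even when one mechanism's mass is
    # concentrated on few pairs (rejection sampling would skew it)
    for _ in range(spec.n_edges):
        is_sim = bool(rng.random() < spec.mix_weight)
        weights = sim_flat if is_sim else pop_flat
        mass = weights.sum()
        if mass <= 0:  # that mechanism's support is exhausted
            weights = pop_flat if is_sim else sim_flat
            mass = weights.sum()
        flat = int(rng.choice(total, p=weights / mass))
        pair = divmod(flat, spec.n_d)
        edges.add(pair)
        mechanism[pair] = "similarity" if is_sim else "popularity"
        sim_flat[flat] = 0.0
        pop_flat[flat] = 0.0

    graph = BipartiteGraph(
        snorna_ids=[f"s{i:04d}" for i in range(spec.n_s)],
        disease_ids=[f"d{i:03d}" for i in range(spec.n_d)],
        edges=edges)
    return SyntheticSample(graph=graph, mechanism=mechanism,
                           latent_s=z_s, latent_d=z_d,
                           popularity_s=w_s, popularity_d=w_d, spec=spec)


_TINY_EDGES = [("snoA", "dis1"), ("snoB", "dis1"), ("snoB", "dis2")]

_FIXTURE_SPECS = {
    "similarity_dominant": SyntheticSpec(n_s=60, n_d=20, n_edges=200,
                                         mix_weight=0.95, seed=1),
    "popularity_dominant": SyntheticSpec(n_s=60, n_d=20, n_edges=200,
                                         mix_weight=0.05,
                                         degree_exponent=1.5, seed=1),
    "balanced": SyntheticSpec(n_s=60, n_d=20, n_edges=200,
                              mix_weight=0.5, seed=1),
}


def fixture_suite(directory: str | Path | None = None
                  ) -> dict[str, SyntheticSample | BipartiteGraph]:
    """Deterministic named test graphs.

    ``tiny`` is a hand-written 3-edge graph (2 snoRNAs x 2 diseases); the
    other three are generated at fixed seeds with similarity-dominant,
    popularity-dominant and balanced mixtures. When ``directory`` is
    given, each fixture is written as a TSV edge list plus a JSON manifest
    (spec, seed, ground-truth labels) and can be reloaded through
    :func:`snolink.graph.load_edge_list` without loss.
    """
    tiny = BipartiteGraph(
        snorna_ids=["snoA", "snoB"], disease_ids=["dis1", "dis2"],
        edges={(0, 0), (1, 0), (1, 1)})
    out: dict[str, SyntheticSample | BipartiteGraph] = {"tiny": tiny}
    for name, spec in _FIXTURE_SPECS.items():
        out[name] = generate(spec)

    if directory is not None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_edge_list(tiny, directory / "tiny.tsv")
        (directory / "tiny.json").write_text(json.dumps(
            {"name": "tiny", "hand_written": True,
             "edges": _TINY_EDGES}, indent=1))
        for name, spec in _FIXTURE_SPECS.items():
            sample = out[name]
            save_edge_list(sample.graph, directory / f"{name}.tsv")
            manifest = {
                "name": name, "spec": asdict(spec),
                "mechanism": {f"{s},{d}": m for (s, d), m
                              in sorted(sample.mechanism.items())},
            }
            (directory / f"{name}.json").write_text(
                json.dumps(manifest, indent=1))
    return out
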