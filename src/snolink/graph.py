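"""Bipartite snoRNA-disease graphs: edge-list I/O, the normalized
propagation operator, train/test splits, negative sampling and stratified
folds.

The graph is bipartite by construction: edges connect a snoRNA to a disease
and nothing else. Nodes live in a unified ordering — snoRNAs occupy indices
``[0, n_s)`` and diseases ``[n_s, n_s + n_d)`` — so one symmetric operator
propagates messages over the whole graph.

Identifier hygiene: lookups are case-insensitive and whitespace-trimmed;
the stored spelling is the first one seen.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteGraph", "PropagationOperator", "SplitSpec",
    "load_edge_list", "save_edge_list", "build_propagation_operator",
    "make_split", "sample_negatives", "stratified_folds",
]

Edge = tuple[int, int]


def _norm_key(identifier: str) -> str:
    return identifier.strip().casefold()


@dataclass
class BipartiteGraph:
    """Node vocabularies plus observed association edges.

    ``edges`` holds (snorna_index, disease_index) pairs; indices refer to
    the ordered vocabularies. Duplicate edges are collapsed on construction.
    """

    snorna_ids: list[str]
    disease_ids: list[str]
    edges: set[Edge] = field(default_factory=set)

    def __post_init__(self):
        self._s_lookup = {_norm_key(s): i for i, s in enumerate(self.snorna_ids)}
        self._d_lookup = {_norm_key(d): i for i, d in enumerate(self.disease_ids)}
        if len(self._s_lookup) != len(self.snorna_ids):
            raise ValueError("duplicate snoRNA identifiers after normalization")
        if len(self._d_lookup) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers after normalization")
        self.edges = set(self.edges)
        for s, d in self.edges:
            if not (0 <= s < self.n_s and 0 <= d < self.n_d):
                raise ValueError(f"edge ({s},{d}) references invalid indices")

    @property
    def n_s(self) -> int:
        return len(self.snorna_ids)

    @property
    def n_d(self) -> int:
        return len(self.disease_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_s + self.n_d

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def snorna_index(self, identifier: str) -> int:
        key = _norm_key(identifier)
        if key not in self._s_lookup:
            raise KeyError(f"unknown snoRNA identifier: {identifier!r}")
        return self._s_lookup[key]

    def disease_index(self, identifier: str) -> int:
        key = _norm_key(identifier)
        if key not in self._d_lookup:
            raise KeyError(f"unknown disease identifier: {identifier!r}")
        return self._d_lookup[key]

    def has_snorna(self, identifier: str) -> bool:
        return _norm_key(identifier) in self._s_lookup

    def has_disease(self, identifier: str) -> bool:
        return _norm_key(identifier) in self._d_lookup

    def degrees(self) -> np.ndarray:
        """Degree of every node in unified ordering."""
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for s, d in self.edges:
            deg[s] += 1
            deg[self.n_s + d] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        """Dense symmetric adjacency in unified ordering (no self-loops)."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        for s, d in self.edges:
            a[s, self.n_s + d] = 1.0
            a[self.n_s + d, s] = 1.0
        return a

    def with_edges(self, edges: Iterable[Edge]) -> "BipartiteGraph":
        """Same vocabularies, different edge set (e.g. the training fold)."""
        return BipartiteGraph(self.snorna_ids, self.disease_ids, set(edges))

    def edge_frame(self) -> pd.DataFrame:
        rows = sorted(self.edges)
        return pd.DataFrame({
            "snorna_id": [self.snorna_ids[s] for s, _ in rows],
            "disease_id": [self.disease_ids[d] for _, d in rows],
        })


@dataclass
class PropagationOperator:
    """Symmetric normalized propagation matrix D^(-1/2) (A + I) D^(-1/2).

    ``matrix`` has shape (n_s+n_d, n_s+n_d); the diagonal entry of a node
    with degree d is 1/(d+1) and the entry for an edge (a, b) is
    1/sqrt((d_a+1)(d_b+1)).
    """

    matrix: np.ndarray
    n_s: int
    n_d: int

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != self.n_s + self.n_d:
            raise ValueError("operator shape does not match node counts")
        if not np.allclose(m, m.T):
            raise ValueError("propagation operator must be symmetric")
        if np.any(m < 0):
            raise ValueError("propagation operator entries must be >= 0")

    @property
    def n_nodes(self) -> int:
        return self.n_s + self.n_d


@dataclass
class SplitSpec:
    """A train/test partition of the positive edges plus frozen evaluation
    negatives, all replayable from (inputs, seed)."""

    train_edges: set[Edge]
    test_edges: set[Edge]
    negatives: set[Edge]
    seed: int
    ratio: float

    def __post_init__(self):
        if self.train_edges & self.test_edges:
            raise ValueError("train and test edges overlap")
        pos = self.train_edges | self.test_edges
        if self.negatives & pos:
            raise ValueError("negatives overlap positive edges")

    def to_json(self, path: str | Path, graph: BipartiteGraph) -> None:
        def as_ids(pairs: set[Edge]):
            return sorted([graph.snorna_ids[s], graph.disease_ids[d]]
                          for s, d in pairs)
        payload = {
            "seed": self.seed, "ratio": self.ratio,
            "train_edges": as_ids(self.train_edges),
            "test_edges": as_ids(self.test_edges),
            "negatives": as_ids(self.negatives),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def from_json(path: str | Path, graph: BipartiteGraph) -> "SplitSpec":
        payload = json.loads(Path(path).read_text())

        def as_idx(rows):
            return {(graph.snorna_index(s), graph.disease_index(d))
                    for s, d in rows}
        return SplitSpec(train_edges=as_idx(payload["train_edges"]),
                         test_edges=as_idx(payload["test_edges"]),
                         negatives=as_idx(payload["negatives"]),
                         seed=payload["seed"], ratio=payload["ratio"])


# ----------------------------------------------------------------------
def load_edge_list(path: str | Path, sep: str = "\t",
                   header: bool | None = None) -> BipartiteGraph:
    """Read a TSV edge list ``snorna_id<TAB>disease_id[<TAB>label]``.

    Duplicate rows collapse to one edge; rows with a missing identifier are
    dropped (and counted in the log). Rows labeled 0 are treated as
    explicit negatives and excluded from the edge set. A header row is
    auto-detected when ``header`` is None: if the first row's third column
    is present but not a 0/1 label, or its first cell equals 'snorna_id',
    it is skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")
    try:
        raw = path.read_text(encoding="utf-8")
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"could not read edge list {path}: {exc}") from exc

    lines = [ln for ln in raw.splitlines() if ln.strip()]
    if header is None and lines:
        first = lines[0].split(sep)
        head_names = {"snorna_id", "snorna", "disease_id", "disease", "label"}
        header = _norm_key(first[0]) in head_names
    if header and lines:
        lines = lines[1:]

    snorna_ids: list[str] = []
    disease_ids: list[str] = []
    s_lookup: dict[str, int] = {}
    d_lookup: dict[str, int] = {}
    edges: set[Edge] = set()
    dropped = 0
    for ln in lines:
        cols = ln.split(sep)
        s_raw = cols[0].strip() if len(cols) > 0 else ""
        d_raw = cols[1].strip() if len(cols) > 1 else ""
        if not s_raw or not d_raw:
            dropped += 1
            continue
        label = cols[2].strip() if len(cols) > 2 and cols[2].strip() else "1"
        if label not in {"0", "1"}:
            raise ValueError(f"bad label {label!r} in row: {ln!r}")
        sk, dk = _norm_key(s_raw), _norm_key(d_raw)
        if sk not in s_lookup:
            s_lookup[sk] = len(snorna_ids)
            snorna_ids.append(s_raw)
        if dk not in d_lookup:
            d_lookup[dk] = len(disease_ids)
            disease_ids.append(d_raw)
        if label == "1":
            edges.add((s_lookup[sk], d_lookup[dk]))

    if not edges:
        raise ValueError(f"no valid association rows in {path}")
    logger.info("loaded %s: %d snoRNAs, %d diseases, %d edges (%d rows dropped)",
                path, len(snorna_ids), len(disease_ids), len(edges), dropped)
    graph = BipartiteGraph(snorna_ids, disease_ids, edges)
    graph.dropped_rows = dropped  # type: ignore[attr-defined]
    return graph


def save_edge_list(graph: BipartiteGraph, path: str | Path,
                   header: bool = True) -> None:
    """Write the graph back to the TSV dialect ``load_edge_list`` reads."""
    frame = graph.edge_frame()
    frame["label"] = 1
    frame.to_csv(path, sep="\t", index=False, header=header)


def build_propagation_operator(graph: BipartiteGraph) -> PropagationOperator:
    """Symmetric normalization with self-loops over the unified ordering."""
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    a_hat = graph.adjacency()
    np.fill_diagonal(a_hat, 1.0)
    d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))
    matrix = a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return PropagationOperator(matrix=matrix, n_s=graph.n_s, n_d=graph.n_d)


def make_split(graph: BipartiteGraph, ratio: float = 0.8,
               seed: int = 0, with_negatives: bool = True) -> SplitSpec:
    """Uniform random split of positive edges; floor(ratio*|E|) go to train,
    the remainder to test. Frozen balanced negatives are drawn for the test
    set (one per test positive) unless ``with_negatives`` is False.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    edges = sorted(graph.edges)
    if len(edges) < 2:
        raise ValueError("need at least 2 edges to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(edges))
    n_train = int(np.floor(ratio * len(edges)))
    train = {edges[i] for i in perm[:n_train]}
    test = {edges[i] for i in perm[n_train:]}
    negatives: set[Edge] = set()
    if with_negatives and test:
        negatives = sample_negatives(graph, len(test), exclude=set(),
                                     seed=int(rng.integers(2 ** 31)))
    return SplitSpec(train_edges=train, test_edges=test,
                     negatives=negatives, seed=seed, ratio=ratio)


def sample_negatives(graph: BipartiteGraph, m: int,
                     exclude: set[Edge] | None = None,
                     seed: int = 0) -> set[Edge]:
    """Draw ``m`` distinct snoRNA-disease pairs that are neither observed
    edges nor in ``exclude``; reproducible under ``seed``."""
    exclude = set(exclude or ())
    forbidden = graph.edges | exclude
    total = graph.n_s * graph.n_d
    available = total - len({(s, d) for s, d in forbidden
                             if 0 <= s < graph.n_s and 0 <= d < graph.n_d})
    if m > available:
        raise ValueError(
            f"requested {m} negatives but only {available} non-edges exist")
    rng = np.random.default_rng(seed)
    out: set[Edge] = set()
    # rejection sampling with a dense fallback for near-complete graphs
    dense_cutoff = 0.5 * total
    if len(forbidden) + m > dense_cutoff:
        flat = [(s, d) for s in range(graph.n_s) for d in range(graph.n_d)
                if (s, d) not in forbidden]
        idx = rng.choice(len(flat), size=m, replace=False)
        return {flat[i] for i in idx}
    while len(out) < m:
        draw = m - len(out)
        s = rng.integers(0, graph.n_s, size=2 * draw + 8)
        d = rng.integers(0, graph.n_d, size=2 * draw + 8)
        for pair in zip(s.tolist(), d.tolist()):
            if pair not in forbidden and pair not in out:
                out.add(pair)
                if len(out) == m:
                    break
    return out


def stratified_folds(positives: Sequence[Edge], negatives: Sequence[Edge],
                     k: int = 5, seed: int = 0):
    """Stratified k-fold partition over the pooled positive+negative pairs.

    Returns a list of (train_indices, val_indices) into the concatenated
    [positives..., negatives...] ordering; per-fold class counts differ by
    at most one from |class|/k.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n_pos, n_neg = len(positives), len(negatives)
    if min(n_pos, n_neg) < k:
        raise ValueError(f"each class needs >= {k} members for {k} folds")
    labels = np.concatenate([np.ones(n_pos, dtype=int),
                             np.zeros(n_neg, dtype=int)])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train.copy(), val.copy())
            for train, val in skf.split(np.zeros(len(labels)), labels)]
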