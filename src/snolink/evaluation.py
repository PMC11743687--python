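"""Threshold metrics, cross-validation, external testing, and the
leave-disease-out ranking protocol.

Metrics follow the usual link-prediction conventions: AUC is the pairwise
ranking statistic (ties credited 1/2), AUPR the step-interpolated area
under the precision-recall curve, and ACC/PRE/SEN/F1 are computed at a
fixed threshold (0.5 by default). Evaluation batches are balanced: each
positive set is paired with an equal number of sampled non-edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .graph import (BipartiteGraph, Edge, sample_negatives, stratified_folds)
from .model import AssociationModel, AssociationResults, TrainConfig

logger = logging.getLogger(__name__)

__all__ = ["EvalReport", "binary_metrics", "cross_validate", "external_test",
           "rank_candidates", "leave_target_out_rank"]

METRICS = ("auc", "aupr", "acc", "pre", "sen", "f1")


@dataclass
class EvalReport:
    """Threshold metrics plus (for CV) per-fold rows and mean +/- std."""

    auc: float
    aupr: float
    acc: float
    pre: float
    sen: float
    f1: float
    threshold: float = 0.5
    per_fold: list["EvalReport"] = field(default_factory=list)
    mean_std: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {m: getattr(self, m) for m in METRICS}
        out["threshold"] = self.threshold
        if self.per_fold:
            out["per_fold"] = [f.as_dict() for f in self.per_fold]
            out["mean_std"] = {k: list(v) for k, v in self.mean_std.items()}
        return out

    def fold_table(self) -> pd.DataFrame:
        """Fold rows plus an average row (percent scale)."""
        rows = []
        for i, f in enumerate(self.per_fold, start=1):
            rows.append({"Test set": str(i),
                         **{m.upper(): 100 * getattr(f, m) for m in METRICS}})
        if self.mean_std:
            rows.append({"Test set": "Average",
                         **{m.upper(): 100 * self.mean_std[m][0]
                            for m in METRICS}})
        return pd.DataFrame(rows)


def binary_metrics(scores: Sequence[float], labels: Sequence[int],
                   threshold: float = 0.5) -> EvalReport:
    """AUC/AUPR plus thresholded accuracy, precision, sensitivity and F1.

    Precision with zero predicted positives is defined as 0 (warned).
    Raises if only one class is present (AUC/AUPR undefined).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    auc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    acc = (tp + tn) / len(labels)
    if tp + fp == 0:
        logger.warning("no predicted positives at threshold %.3f; "
                       "precision defined as 0", threshold)
        pre = 0.0
    else:
        pre = tp / (tp + fp)
    sen = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    return EvalReport(auc=auc, aupr=aupr, acc=acc, pre=pre, sen=sen, f1=f1,
                      threshold=threshold)


def _aggregate(folds: list[EvalReport], threshold: float) -> EvalReport:
    means = {m: float(np.mean([getattr(f, m) for f in folds]))
             for m in METRICS}
    stds = {m: float(np.std([getattr(f, m) for f in folds]))
            for m in METRICS}
    return EvalReport(**means, threshold=threshold, per_fold=folds,
                      mean_std={m: (means[m], stds[m]) for m in METRICS})


def cross_validate(graph: BipartiteGraph, config: TrainConfig | None = None,
                   k: int | None = None, seed: int | None = None,
                   threshold: float = 0.5) -> EvalReport:
    """Stratified k-fold cross-validation over balanced positives+negatives.

    A frozen negative set equal in size to the positives is drawn once;
    folds stratify over the two classes. Each fold trains a fresh model on
    the training-fold positives (training negatives are redrawn per epoch
    and never touch the fold's evaluation pairs) and is scored on the
    held-out fold.
    """
    config = config or TrainConfig()
    k = k or config.k_folds
    seed = config.seed if seed is None else seed
    positives = sorted(graph.edges)
    rng = np.random.default_rng(seed)
    negatives = sorted(sample_negatives(graph, len(positives),
                                        seed=int(rng.integers(2 ** 31))))
    folds = stratified_folds(positives, negatives, k=k,
                             seed=int(rng.integers(2 ** 31)))
    pooled = positives + negatives
    labels_all = np.concatenate([np.ones(len(positives), dtype=int),
                                 np.zeros(len(negatives), dtype=int)])
    reports: list[EvalReport] = []
    for fold_i, (train_idx, val_idx) in enumerate(folds):
        train_pos = [pooled[i] for i in train_idx if labels_all[i] == 1]
        val_pairs = [pooled[i] for i in val_idx]
        val_labels = labels_all[val_idx]
        val_negs = {pooled[i] for i in val_idx if labels_all[i] == 0}
        model = AssociationModel(graph.with_edges(graph.edges), config)
        results = model.fit(train_edges=train_pos,
                            seed=int(rng.integers(2 ** 31)),
                            exclude_negatives=val_negs)
        scores = results.scores_for_pairs_array(val_pairs)
        report = binary_metrics(scores, val_labels, threshold)
        logger.info("fold %d: AUC=%.4f AUPR=%.4f", fold_i + 1,
                    report.auc, report.aupr)
        reports.append(report)
    return _aggregate(reports, threshold)


def external_test(results: AssociationResults,
                  external_graph: BipartiteGraph,
                  seed: int = 0, threshold: float = 0.5) -> EvalReport:
    """Score a trained model on an external association set.

    External identifiers are mapped into the training vocabulary
    (case-insensitive, trimmed); pairs involving unseen identifiers are
    excluded with a warning. Metrics are computed over the mappable
    positives plus an equal number of freshly sampled negatives.
    """
    graph = results.graph
    mapped: list[Edge] = []
    unseen = 0
    for s, d in sorted(external_graph.edges):
        s_id = external_graph.snorna_ids[s]
        d_id = external_graph.disease_ids[d]
        if graph.has_snorna(s_id) and graph.has_disease(d_id):
            mapped.append((graph.snorna_index(s_id),
                           graph.disease_index(d_id)))
        else:
            unseen += 1
    if unseen:
        logger.warning("external test: %d pair(s) with unseen identifiers "
                       "excluded", unseen)
    if not mapped:
        raise ValueError("no external edges map into the training vocabulary")
    negatives = sorted(sample_negatives(graph, len(mapped),
                                        exclude=set(mapped), seed=seed))
    pairs = mapped + negatives
    labels = np.concatenate([np.ones(len(mapped), dtype=int),
                             np.zeros(len(negatives), dtype=int)])
    scores = results.scores_for_pairs_array(pairs)
    return binary_metrics(scores, labels, threshold)


def rank_candidates(results: AssociationResults, target_id: str,
                    k: int = 20,
                    mode: Literal["snorna_for_disease",
                                  "disease_for_snorna"] = "snorna_for_disease"
                    ) -> pd.DataFrame:
    """Rank candidate partners for one disease (or snoRNA).

    Scores every entity whose association with the target was *not* in the
    training edge set, sorts by mixture score descending (ties broken by
    identifier), and returns the top ``k`` with branch scores and the
    similarity responsibility. The caller is responsible for having
    trained with the target's edges held out (see
    :func:`leave_target_out_rank`).
    """
    graph = results.graph
    if mode == "snorna_for_disease":
        d = graph.disease_index(target_id)
        trained = {s for s, dd in results.train_edges if dd == d}
        pairs = [(s, d) for s in range(graph.n_s) if s not in trained]
        id_col = "snorna_id"
    elif mode == "disease_for_snorna":
        s = graph.snorna_index(target_id)
        trained = {dd for ss, dd in results.train_edges if ss == s}
        pairs = [(s, dd) for dd in range(graph.n_d) if dd not in trained]
        id_col = "disease_id"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not pairs:
        raise ValueError(f"no candidate partners for {target_id!r}")
    frame = results.pair_scores(pairs)
    frame = frame.sort_values(["score", id_col],
                              ascending=[False, True]).head(k)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame.reset_index(drop=True)


def leave_target_out_rank(graph: BipartiteGraph, target_id: str,
                          config: TrainConfig | None = None, k: int = 20,
                          mode: Literal["snorna_for_disease",
                                        "disease_for_snorna"]
                          = "snorna_for_disease",
                          seed: int | None = None) -> pd.DataFrame:
    """Case-study protocol: drop every training edge touching the target,
    retrain, then rank all candidates for the target."""
    config = config or TrainConfig()
    if mode == "snorna_for_disease":
        d = graph.disease_index(target_id)
        kept = {(s, dd) for s, dd in graph.edges if dd != d}
    else:
        s = graph.snorna_index(target_id)
        kept = {(ss, dd) for ss, dd in graph.edges if ss != s}
    if not kept:
        raise ValueError("removing the target's edges empties the graph")
    model = AssociationModel(graph, config)
    results = model.fit(train_edges=kept, seed=seed)
    return rank_candidates(results, target_id, k=k, mode=mode)
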