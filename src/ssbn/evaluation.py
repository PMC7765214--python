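"""Stratified cross-validated classification metrics for the Bayesian
classifiers.

Metrics are pooled over folds (micro-average): the confusion matrix is
accumulated across held-out folds and accuracy / precision / recall / F
are computed once from the pooled counts.  With a rare positive class
this is far more stable than averaging per-fold ratios.  AUC is the
Mann-Whitney rank statistic of the positive-class scores.  A classifier
that never predicts the positive class has an undefined F-measure; it is
flagged as degenerate and F is reported as absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datatable import DataTable
from .exceptions import ConfigurationError, ImpossibleEvidenceError, StratificationError
from .learning import LearnerConfig, learn_naive_bayes, learn_sons_and_spouses, learn_tan
from .network import Assignment, BayesianNetwork, posterior

logger = logging.getLogger(__name__)

LEARNERS: dict[str, Callable] = {
    "nb": learn_naive_bayes,
    "tan": learn_tan,
    "ss": learn_sons_and_spouses,
}


@dataclass
class CVMetrics:
    pooled: dict[str, float | None]
    per_fold: pd.DataFrame
    confusion: dict[str, int]
    degenerate: bool
    prior_fallbacks: int = 0

    def to_frame(self) -> pd.DataFrame:
        """One-row table shaped like a classifier-benchmark report."""
        return pd.DataFrame([self.pooled])


def positive_state(net_or_data, target: str) -> str:
    """Convention: the positive class is the target's last declared state
    (e.g. ("no", "yes") -> "yes")."""
    if isinstance(net_or_data, BayesianNetwork):
        return net_or_data.variable(target).states[-1]
    return net_or_data.variable(target).states[-1]


def stratified_folds(
    data: DataTable, k: int, seed: int, target: str | None = None
) -> list[np.ndarray]:
    """k disjoint, stratified test-index sets covering all rows."""
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if target is None:
        targets = [v.name for v in data.variables if v.role == "target"]
        if len(targets) != 1:
            raise ConfigurationError("no unique target variable declared")
        target = targets[0]
    y = data.codes(target)
    if (y < 0).any():
        raise ConfigurationError("target column has missing values")
    counts = np.bincount(y)
    if (counts[counts > 0] < k).any():
        raise StratificationError(
            f"smallest target class ({counts[counts > 0].min()} records) is "
            f"smaller than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


def classify(
    net: BayesianNetwork, record: Assignment, target: str | None = None
) -> tuple[str, float, bool]:
    """Argmax-posterior prediction and positive-class score for a record.

    The record is restricted to the network's variables; evidence the
    network deems impossible falls back to the prior (flagged in the
    third return slot).  Posterior ties go to the negative class.
    """
    target = target or net.target
    evidence = {
        k: v for k, v in record.items() if k in net.variables and k != target
    }
    fallback = False
    try:
        dist = posterior(net, target, evidence)
    except ImpossibleEvidenceError:
        dist = posterior(net, target, {})
        fallback = True
    pos = positive_state(net, target)
    states = net.variable(target).states
    probs = dist.probabilities
    best = float(probs.max())
    # ties toward the negative (majority) class: first non-positive argmax
    tied = [s for s, p in zip(states, probs) if p == best]
    pred = tied[0] if len(tied) == 1 else next(
        (s for s in tied if s != pos), tied[0]
    )
    return pred, dist[pos], fallback


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float | None]:
    """Percent-scale accuracy/precision/recall/F from pooled counts.

    Undefined ratios (no predicted or no actual positives) are None.
    """
    n = tp + fp + fn + tn
    acc = 100.0 * (tp + tn) / n if n else None
    prec = 100.0 * tp / (tp + fp) if (tp + fp) else None
    rec = 100.0 * tp / (tp + fn) if (tp + fn) else None
    if prec is None or rec is None or (prec + rec) == 0:
        f = None
    else:
        f = 2 * prec * rec / (prec + rec)
    return {"accuracy": acc, "precision": prec, "recall": rec, "f_measure": f}


def auc_percent(labels: np.ndarray, scores: np.ndarray) -> float | None:
    """Mann-Whitney AUC of positive-class scores, in percent."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return None
    return 100.0 * float(roc_auc_score(labels, np.asarray(scores, float)))


def evaluate_cv(
    data: DataTable,
    learner: str | Callable,
    k: int = 10,
    seed: int = 0,
    config: LearnerConfig | None = None,
    target: str | None = None,
) -> CVMetrics:
    """k-fold stratified CV of a Bayesian-family classifier."""
    if isinstance(learner, str):
        if learner not in LEARNERS:
            raise ConfigurationError(
                f"unknown learner {learner!r}; choose from {sorted(LEARNERS)}"
            )
        learn = LEARNERS[learner]
    else:
        learn = learner
    if target is None:
        targets = [v.name for v in data.variables if v.role == "target"]
        if len(targets) != 1:
            raise ConfigurationError("no unique target variable declared")
        target = targets[0]
    # rows with a missing target cannot be scored
    observed = np.flatnonzero(data.codes(target) >= 0)
    data = data.subset_rows(observed)
    folds = stratified_folds(data, k, seed, target)
    pos = positive_state(data, target)
    all_idx = np.arange(data.n_rows)
    tp = fp = fn = tn = 0
    fallbacks = 0
    fold_rows = []
    all_labels: list[int] = []
    all_scores: list[float] = []
    for fold_no, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        net = learn(data.subset_rows(train_idx), target, config)
        ftp = ffp = ffn = ftn = 0
        flabels, fscores = [], []
        for i in test_idx:
            record = data.record(int(i))
            truth = record[target]
            pred, score, fell_back = classify(net, record, target)
            fallbacks += fell_back
            is_pos, pred_pos = truth == pos, pred == pos
            ftp += is_pos and pred_pos
            ffp += (not is_pos) and pred_pos
            ffn += is_pos and not pred_pos
            ftn += (not is_pos) and not pred_pos
            flabels.append(int(is_pos))
            fscores.append(score)
        tp, fp, fn, tn = tp + ftp, fp + ffp, fn + ffn, tn + ftn
        all_labels.extend(flabels)
        all_scores.extend(fscores)
        row = {"fold": fold_no, **confusion_metrics(ftp, ffp, ffn, ftn)}
        row["auc"] = auc_percent(np.array(flabels), np.array(fscores))
        fold_rows.append(row)
    pooled = confusion_metrics(tp, fp, fn, tn)
    pooled["auc"] = auc_percent(np.array(all_labels), np.array(all_scores))
    degenerate = (tp + fp) == 0 or pooled["f_measure"] is None
    if degenerate:
        logger.warning("degenerate classifier: no usable F-measure")
    if fallbacks:
        logger.info("prior fallback used for %d impossible-evidence records", fallbacks)
    return CVMetrics(
        pooled=pooled,
        per_fold=pd.DataFrame(fold_rows),
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        degenerate=degenerate,
        prior_fallbacks=fallbacks,
    )
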