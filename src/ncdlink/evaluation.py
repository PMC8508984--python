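"""Cross-validation with balanced negative sampling, metrics, and ranking.

The evaluation protocol: verified positives are shuffled into k near-equal
parts; each part in turn is the test positive set, paired with an equal
number of unverified (ncRNA, drug) pairs sampled without replacement as
test negatives. A fresh model is trained on the remaining positives — with
BPR negatives drawn only outside the full positive set and outside the test
pairs, so nothing from the test fold leaks into training — and scored on
the balanced test set.

Metrics: AUC (rank statistic, mid-rank ties), AUPR (step-function
precision-recall integral), and thresholded Accuracy, Precision = TP/(TP+FP),
Recall = TP/(TP+FN), F1 = 2PR/(P+R). The default threshold calls a pair
positive when its raw score is >= 0, i.e. logistic(score) >= 0.5.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .data_io import AssociationDataset
from .model import Hyperparameters, LinearResidualGCN, ModelState, score

METRIC_NAMES = ("AUC", "AUPR", "Acc", "P", "R", "F1")


@dataclass
class FoldSplit:
    """One cross-validation fold: positives partitioned, negatives sampled."""

    train_pos: list[tuple[int, int]]
    test_pos: list[tuple[int, int]]
    train_neg: list[tuple[int, int]]
    test_neg: list[tuple[int, int]]


@dataclass
class EvalReport:
    """Per-fold and averaged metrics plus ROC/PR curve points."""

    per_fold: list[dict[str, float]]
    averages: dict[str, float]
    roc_curves: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    pr_curves: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "averages": self.averages,
        }


def average_folds(per_fold: Sequence[dict[str, float]]) -> dict[str, float]:
    """Arithmetic mean of each metric across folds."""
    return {name: float(np.mean([m[name] for m in per_fold]))
            for name in METRIC_NAMES}


def make_folds(
    ds: AssociationDataset,
    k: int,
    seed: int,
) -> list[FoldSplit]:
    """Partition positives into k folds with balanced sampled negatives.

    Positives are split into near-equal parts by a seeded shuffle (sizes
    differ by at most one). For each fold, negatives equal in count to the
    train and test positive sets are sampled uniformly without replacement
    from pairs absent from the *full* positive set; a fold's train and test
    negatives are disjoint.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pos = sorted(ds.pairs)
    if len(pos) < k:
        raise ValueError(f"need at least k={k} positives, have {len(pos)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pos))
    parts = [sorted(pos[t] for t in chunk) for chunk in np.array_split(order, k)]

    all_pos = set(pos)
    unverified = [(i, j) for i in range(ds.m) for j in range(ds.n)
                  if (i, j) not in all_pos]
    folds: list[FoldSplit] = []
    for f in range(k):
        test_pos = parts[f]
        train_pos = sorted(p for g, part in enumerate(parts) if g != f for p in part)
        needed = len(test_pos) + len(train_pos)
        if len(unverified) < needed:
            raise ValueError(
                f"fold {f}: {needed} negatives needed but only "
                f"{len(unverified)} unverified pairs exist"
            )
        pick = rng.choice(len(unverified), size=needed, replace=False)
        neg = [unverified[t] for t in pick]
        folds.append(FoldSplit(
            train_pos=train_pos,
            test_pos=test_pos,
            train_neg=neg[len(test_pos):],
            test_neg=neg[:len(test_pos)],
        ))
    return folds


def compute_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.0,
    with_curves: bool = False,
) -> dict:
    """AUC, AUPR, and thresholded Accuracy/Precision/Recall/F1.

    AUC uses the rank statistic with mid-rank tie handling; AUPR is the
    non-interpolated step integral of the precision-recall curve. The
    thresholded metrics call a pair positive when ``score >= threshold``.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC/AUPR undefined: labels contain a single class")

    auc = float(roc_auc_score(y, s))
    aupr = float(average_precision_score(y, s))

    pred = (s >= threshold).astype(np.int64)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    acc = (tp + tn) / len(y)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        warnings.warn("precision + recall = 0; defining F1 = 0", stacklevel=2)
        f1 = 0.0

    out = {"AUC": auc, "AUPR": aupr, "Acc": acc,
           "P": precision, "R": recall, "F1": f1}
    if with_curves:
        fpr, tpr, _ = roc_curve(y, s)
        prec, rec, _ = precision_recall_curve(y, s)
        out["roc"] = (fpr, tpr)
        out["pr"] = (rec, prec)
    return out


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _fit_threshold_max_f1(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing F1 over the candidate scores."""
    best_t, best_f1 = 0.0, -1.0
    for t in np.unique(scores):
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        fn = np.sum(~pred & (labels == 1))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return best_t


def cross_validate(
    ds: AssociationDataset,
    hp: Hyperparameters | None = None,
    k: int = 5,
    seed: int = 0,
    threshold_rule: str = "zero",
) -> EvalReport:
    """k-fold cross-validation of the link predictor.

    Per fold, a fresh model is trained on the training positives only; BPR
    negative sampling excludes the full positive set and the fold's test
    negatives. The fitted model scores the balanced test set.

    ``threshold_rule``: "zero" classifies at raw score >= 0;
    "max_f1_train" picks the threshold maximizing F1 on the training pairs
    (train positives vs the fold's sampled train negatives).
    """
    if hp is None:
        hp = Hyperparameters()
    if threshold_rule not in ("zero", "max_f1_train"):
        raise ValueError(f"unknown threshold_rule: {threshold_rule!r}")
    folds = make_folds(ds, k, seed)
    per_fold: list[dict[str, float]] = []
    roc_curves, pr_curves = [], []
    for f, fold in enumerate(folds):
        train_ds = ds.subset(fold.train_pos)
        exclude = set(ds.pairs) | set(fold.test_neg)
        model = LinearResidualGCN(
            n_layers=hp.n_layers,
            embedding_dim=hp.embedding_dim,
            init_std=hp.init_std,
            reg_lambda=hp.reg_lambda,
            learning_rate=hp.learning_rate,
            n_epochs=hp.epochs,
            negatives_per_positive=hp.negatives_per_positive,
            include_layer0=hp.include_layer0,
            shared_weights=hp.shared_weights,
            random_state=hp.seed + f,
        ).fit(train_ds, negative_exclude=exclude)

        threshold = 0.0
        if threshold_rule == "max_f1_train":
            tr_pairs = fold.train_pos + fold.train_neg
            tr_scores = model.decision_function(tr_pairs)
            tr_labels = np.array([1] * len(fold.train_pos)
                                 + [0] * len(fold.train_neg))
            threshold = _fit_threshold_max_f1(tr_scores, tr_labels)

        test_pairs = fold.test_pos + fold.test_neg
        scores = model.decision_function(test_pairs)
        labels = [1] * len(fold.test_pos) + [0] * len(fold.test_neg)
        metrics = compute_metrics(scores, labels, threshold=threshold,
                                  with_curves=True)
        roc_curves.append(metrics.pop("roc"))
        pr_curves.append(metrics.pop("pr"))
        per_fold.append(metrics)

    averages = average_folds(per_fold)
    return EvalReport(per_fold=per_fold, averages=averages,
                      roc_curves=roc_curves, pr_curves=pr_curves)


def rank_candidates(
    model: LinearResidualGCN | np.ndarray,
    ds: AssociationDataset,
    drug_id: str,
    top_n: int = 15,
) -> list[tuple[int, str, float]]:
    """Top novel ncRNA candidates for one drug.

    Known associated ncRNAs are removed, the rest are sorted by descending
    predicted score (ties broken by ascending ncRNA index), and the top
    ``top_n`` are returned as (rank, ncRNA label, score).
    """
    if drug_id not in ds.drugs:
        close = difflib.get_close_matches(drug_id, ds.drugs, n=3)
        hint = f"; closest matches: {close}" if close else ""
        raise KeyError(f"unknown drug {drug_id!r}{hint}")
    j = ds.drugs.index(drug_id)
    O = model if isinstance(model, np.ndarray) else model.predict_scores()
    known = ds.ncrnas_of(j)
    candidates = [i for i in range(ds.m) if i not in known]
    candidates.sort(key=lambda i: (-O[i, j], i))
    return [(rank + 1, ds.ncrnas[i], float(O[i, j]))
            for rank, i in enumerate(candidates[:top_n])]
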