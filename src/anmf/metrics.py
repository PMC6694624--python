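"""Ranking metrics and evaluation protocols.

Metrics follow the implicit-feedback recommendation convention: verified
associations are positives, every unverified (drug, disease) pair is a
candidate (negative).  AUC and AUPR are computed over the pooled test
scores; the hit ratio ranks each test positive against the candidate pairs
of its own drug (the GMF/NCF lineage convention), with pessimistic tie
breaking.

Protocols:

* ten-fold cross-validation over verified associations, with all candidate
  pairs added to every fold's test set;
* the new-drug (cold-start) split, which holds out the single association
  of every drug that has exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import Dataset

__all__ = [
    "EvalSplit", "MetricReport",
    "auc", "aupr", "hit_ratio",
    "make_cv_splits", "make_new_drug_split", "evaluate",
]


@dataclass
class EvalSplit:
    """Pair lists for one evaluation fold; each array is (N, 2) int [drug, disease]."""

    train_positives: np.ndarray
    test_positives: np.ndarray
    candidates: np.ndarray

    def validate(self, shape: tuple[int, int] | None = None) -> "EvalSplit":
        sets = [set(map(tuple, a)) for a in
                (self.train_positives, self.test_positives, self.candidates)]
        if sets[0] & sets[1]:
            raise ValueError("train and test positives overlap")
        if sets[2] & (sets[0] | sets[1]):
            raise ValueError("candidates overlap verified associations")
        return self


@dataclass
class MetricReport:
    auc: float
    aupr: float
    hr: dict[int, float]


def _check_scores(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(pos, dtype=float).ravel()
    neg = np.asarray(neg, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    return pos, neg


def _roc_points(pos: np.ndarray, neg: np.ndarray):
    """Cumulative TP/FP counts at each distinct threshold, descending scores."""
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    # indices of the last element of each tied-score group
    last = np.flatnonzero(np.diff(scores) != 0)
    last = np.append(last, scores.size - 1)
    tp = np.cumsum(labels)[last]
    fp = (last + 1) - tp
    return tp, fp


def roc_curve(pos_scores: np.ndarray, neg_scores: np.ndarray):
    """(fpr, tpr) points of the ROC curve, one per distinct threshold."""
    pos, neg = _check_scores(pos_scores, neg_scores)
    tp, fp = _roc_points(pos, neg)
    return (np.concatenate([[0.0], fp / neg.size]),
            np.concatenate([[0.0], tp / pos.size]))


def pr_curve(pos_scores: np.ndarray, neg_scores: np.ndarray):
    """(recall, precision) points, one per distinct threshold, descending scores."""
    pos, neg = _check_scores(pos_scores, neg_scores)
    tp, fp = _roc_points(pos, neg)
    return tp / pos.size, tp / (tp + fp)


def auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Area under the ROC curve via a threshold sweep; ties contribute 1/2."""
    pos, neg = _check_scores(pos_scores, neg_scores)
    tp, fp = _roc_points(pos, neg)
    tpr = np.concatenate([[0.0], tp / pos.size])
    fpr = np.concatenate([[0.0], fp / neg.size])
    return float(np.trapezoid(tpr, fpr))


def aupr(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Area under precision-recall by non-interpolated step summation."""
    pos, neg = _check_scores(pos_scores, neg_scores)
    tp, fp = _roc_points(pos, neg)
    recall = tp / pos.size
    precision = tp / (tp + fp)
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def hit_ratio(score_matrix: np.ndarray, split: EvalSplit, n: int,
              per_drug: bool = True) -> float:
    """Fraction of test positives ranked in the top ``n`` of their pool.

    With ``per_drug=True`` (default) the pool of a test positive (i, j) is
    its own score plus the scores of the candidate pairs of drug ``i``;
    with ``per_drug=False`` every positive competes against all candidate
    pairs globally.  Tied candidates rank above the positive (pessimistic).
    """
    scores = np.asarray(score_matrix, dtype=float)
    cand_scores = scores[split.candidates[:, 0], split.candidates[:, 1]]
    cand_by_drug: dict[int, list[float]] = {}
    if per_drug:
        for (i, _), s in zip(split.candidates, cand_scores):
            cand_by_drug.setdefault(int(i), []).append(s)
    hits = 0
    for i, j in split.test_positives:
        pool = (np.asarray(cand_by_drug.get(int(i), ()), dtype=float)
                if per_drug else cand_scores)
        rank = 1 + int(np.sum(pool >= scores[i, j]))
        hits += rank <= n
    return hits / len(split.test_positives)


def make_cv_splits(dataset: Dataset, n_folds: int = 10, seed: int = 0) -> list[EvalSplit]:
    """Partition verified associations into near-equal folds (sizes differ <= 1).

    Fold ``f``'s split uses subset ``f`` as test positives, the remaining
    subsets as training positives, and every unverified pair as candidates.
    """
    positives = np.argwhere(dataset.R == 1)
    if len(positives) < n_folds:
        raise ValueError(f"{n_folds} folds requested but only {len(positives)} positives")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(positives))
    folds = np.array_split(perm, n_folds)
    candidates = np.argwhere(dataset.R == 0)
    splits = []
    for f in range(n_folds):
        test_idx = folds[f]
        train_idx = np.concatenate([folds[g] for g in range(n_folds) if g != f])
        splits.append(EvalSplit(positives[train_idx], positives[test_idx], candidates))
    return splits


def make_new_drug_split(dataset: Dataset) -> EvalSplit:
    """Cold-start split: hold out the association of every single-association drug."""
    row_counts = dataset.R.sum(axis=1)
    single = np.flatnonzero(row_counts == 1)
    if single.size == 0:
        raise ValueError("no drug with exactly one verified association")
    positives = np.argwhere(dataset.R == 1)
    is_test = np.isin(positives[:, 0], single)
    return EvalSplit(
        train_positives=positives[~is_test],
        test_positives=positives[is_test],
        candidates=np.argwhere(dataset.R == 0),
    )


def evaluate(model, train_dataset: Dataset, split: EvalSplit,
             cutoffs: tuple[int, ...] = (1, 5, 10)) -> MetricReport:
    """Score all pairs in inference mode and compute AUC / AUPR / HR@n.

    ``train_dataset.R`` must be the training matrix (test positives zeroed),
    since the encoder consumes interaction profiles.  Training pairs are
    excluded from every ranking pool by construction (pools are test
    positives plus candidates only).
    """
    from .model import predict_matrix

    scores = predict_matrix(model, train_dataset)
    pos = scores[split.test_positives[:, 0], split.test_positives[:, 1]]
    neg = scores[split.candidates[:, 0], split.candidates[:, 1]]
    return MetricReport(
        auc=auc(pos, neg),
        aupr=aupr(pos, neg),
        hr={n: hit_ratio(scores, split, n) for n in cutoffs},
    )
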