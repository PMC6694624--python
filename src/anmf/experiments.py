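"""End-to-end evaluation protocols: cross-validation and cold start.

Each protocol retrains the model from scratch per split on a training
matrix with the held-out positives zeroed, so negatives are only ever
sampled from pairs unverified in that split's training matrix (held-out
positives remain eligible candidates, as the candidate-set convention
requires).
"""

from __future__ import annotations

import numpy as np

from .data_io import Dataset
from .metrics import EvalSplit, MetricReport, evaluate, make_cv_splits, make_new_drug_split
from .training import HyperParams, fit

__all__ = ["train_split_dataset", "run_split", "run_cv", "run_new_drug", "summarize"]


def train_split_dataset(dataset: Dataset, split: EvalSplit) -> Dataset:
    """The dataset seen during training: test positives removed from R."""
    R = np.zeros_like(dataset.R)
    tp = split.train_positives
    R[tp[:, 0], tp[:, 1]] = 1.0
    return Dataset(dataset.drug_ids, dataset.disease_ids, R,
                   dataset.drug_sim, dataset.disease_sim)


def run_split(dataset: Dataset, split: EvalSplit, hp: HyperParams,
              use_similarity: bool = True,
              cutoffs: tuple[int, ...] = (1, 5, 10)) -> MetricReport:
    """Train on the split's training matrix and evaluate on its test set."""
    split.validate()
    train_ds = train_split_dataset(dataset, split)
    model, _ = fit(train_ds, hp, use_similarity=use_similarity)
    return evaluate(model, train_ds, split, cutoffs=cutoffs)


def run_cv(dataset: Dataset, hp: HyperParams, n_folds: int = 10, seed: int = 0,
           use_similarity: bool = True,
           cutoffs: tuple[int, ...] = (1, 5, 10)) -> list[MetricReport]:
    """Ten-fold (by default) cross-validation, retraining per fold."""
    splits = make_cv_splits(dataset, n_folds=n_folds, seed=seed)
    return [run_split(dataset, s, hp, use_similarity, cutoffs) for s in splits]


def run_new_drug(dataset: Dataset, hp: HyperParams, use_similarity: bool = True,
                 cutoffs: tuple[int, ...] = (1, 5, 10)) -> MetricReport:
    """Cold-start protocol: hold out the association of single-association drugs."""
    return run_split(dataset, make_new_drug_split(dataset), hp, use_similarity, cutoffs)


def summarize(reports: list[MetricReport]) -> dict:
    """Mean and standard deviation of each metric over folds."""
    aucs = np.array([r.auc for r in reports])
    auprs = np.array([r.aupr for r in reports])
    cutoffs = sorted(reports[0].hr)
    hrs = {n: np.array([r.hr[n] for r in reports]) for n in cutoffs}
    return {
        "auc_mean": float(aucs.mean()), "auc_sd": float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        "aupr_mean": float(auprs.mean()), "aupr_sd": float(auprs.std(ddof=1)) if len(auprs) > 1 else 0.0,
        "hr_mean": {n: float(v.mean()) for n, v in hrs.items()},
    }
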