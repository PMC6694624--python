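"""Generalized matrix factorization predictor.

A drug hidden feature and a disease hidden feature are fused by elementwise
product and a single-layer perceptron:

    r^ = F_out(h . (z_drug * z_disease))

With the default sigmoid output activation the score is a treatment
probability in (0, 1), scored against the binary target with cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activations import get_activation

__all__ = ["PredictorParams", "predict", "prediction_loss", "EPS"]

EPS = 1e-12  # score clipping for log safety


@dataclass
class PredictorParams:
    """Fusion weight vector ``h`` and the output activation name."""

    h: np.ndarray
    out_activation: str = "sigmoid"

    @property
    def k(self) -> int:
        return self.h.shape[0]


def predict(pred: PredictorParams, drug_z: np.ndarray, disease_z: np.ndarray) -> float | np.ndarray:
    """Predicted treatment score ``F_out(h . (drug_z * disease_z))``.

    Accepts single ``k``-vectors (returns a scalar) or batches of matching
    shape (returns a vector).
    """
    drug_z = np.asarray(drug_z, dtype=float)
    disease_z = np.asarray(disease_z, dtype=float)
    if drug_z.shape != disease_z.shape or drug_z.shape[-1] != pred.k:
        raise ValueError(
            f"hidden-feature shapes {drug_z.shape} / {disease_z.shape} "
            f"incompatible with k={pred.k}"
        )
    F, _ = get_activation(pred.out_activation)
    out = F((drug_z * disease_z) @ pred.h)
    return float(out) if out.ndim == 0 else out


def prediction_loss(score: float | np.ndarray, target: float | np.ndarray) -> float:
    """Binary cross-entropy ``-[r log r^ + (1-r) log(1-r^)]``, summed.

    Scores are clipped to ``[EPS, 1-EPS]`` before the logs; targets must be
    0 or 1.
    """
    score = np.clip(np.asarray(score, dtype=float), EPS, 1.0 - EPS)
    target = np.asarray(target, dtype=float)
    if not np.isin(target, (0.0, 1.0)).all():
        raise ValueError("targets must be 0 or 1")
    return float(-np.sum(target * np.log(score) + (1.0 - target) * np.log(1.0 - score)))
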