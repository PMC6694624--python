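"""Planted-factor synthetic datasets.

The generator draws low-dimensional drug and disease factors, turns them
into treatment probabilities through a logistic link, sparsifies to a
target density, and derives similarity matrices from the same factors so
that the side information genuinely carries signal about the planted
structure.  The result has the statistical shape of real repositioning
data — a very sparse binary association matrix plus bounded, symmetric,
unit-diagonal similarity matrices — without modeling any chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activations import sigmoid
from .data_io import Dataset

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate"]


@dataclass
class SyntheticSpec:
    """Shape and signal parameters of a planted dataset.

    sim_signal
        Mixing weight in [0, 1] between factor-derived cosine similarity
        (1.0) and random symmetric noise (0.0).
    noise_sd
        Standard deviation of Gaussian noise added to the planted logits.
    mode
        ``"bernoulli"`` samples each cell from its true probability;
        ``"top"`` marks the highest-probability cells deterministically.
    """

    m: int = 200
    n: int = 100
    k_true: int = 8
    density: float = 0.05
    sim_signal: float = 0.8
    noise_sd: float = 0.1
    seed: int = 0
    mode: str = "bernoulli"

    def __post_init__(self) -> None:
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must be in (0, 1)")
        if not 0.0 <= self.sim_signal <= 1.0:
            raise ValueError("sim_signal must be in [0, 1]")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.mode not in ("bernoulli", "top"):
            raise ValueError("mode must be 'bernoulli' or 'top'")
        if self.density * self.m * self.n < 1:
            raise ValueError("density too low: expected positives < 1")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset (for tests and diagnostics)."""

    U: np.ndarray        # m x k_true drug factors
    V: np.ndarray        # n x k_true disease factors
    T: np.ndarray        # m x n true treatment probabilities


def _cosine01(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of rows, affinely mapped from [-1,1] to [0,1]."""
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    Xn = X / np.where(norms == 0, 1.0, norms)
    C = Xn @ Xn.T
    C = (C + C.T) / 2.0            # exact symmetry
    return np.clip((C + 1.0) / 2.0, 0.0, 1.0)


def _mixed_similarity(factors: np.ndarray, w: float, rng: np.random.Generator) -> np.ndarray:
    size = factors.shape[0]
    noise = rng.uniform(0.0, 1.0, size=(size, size))
    noise = (noise + noise.T) / 2.0
    S = w * _cosine01(factors) + (1.0 - w) * noise
    np.fill_diagonal(S, 1.0)
    return S


def generate(spec: SyntheticSpec) -> tuple[Dataset, SyntheticTruth]:
    """Draw one dataset and its ground truth; deterministic given the seed."""
    ss = np.random.SeedSequence(spec.seed)
    factor_rng, noise_rng, assoc_rng, sim_rng = (np.random.default_rng(s)
                                                 for s in ss.spawn(4))
    U = factor_rng.standard_normal((spec.m, spec.k_true))
    V = factor_rng.standard_normal((spec.n, spec.k_true))
    logits = U @ V.T                           # planted scores, sd ~ sqrt(k_true)
    if spec.noise_sd > 0:
        logits = logits + noise_rng.normal(0.0, spec.noise_sd, size=logits.shape)

    # shift the logits so the mean probability hits the target density
    lo, hi = logits.min() - 40.0, logits.max() + 40.0
    for _ in range(200):
        c = (lo + hi) / 2.0
        if sigmoid(logits - c).mean() > spec.density:
            lo = c
        else:
            hi = c
    T = sigmoid(logits - (lo + hi) / 2.0)

    if spec.mode == "bernoulli":
        R = (assoc_rng.random(T.shape) < T).astype(float)
    else:
        n_pos = int(round(spec.density * spec.m * spec.n))
        R = np.zeros_like(T)
        flat = np.argsort(-T, axis=None)[:n_pos]
        R.ravel()[flat] = 1.0

    dataset = Dataset(
        drug_ids=[f"DR{i:04d}" for i in range(spec.m)],
        disease_ids=[f"DZ{j:04d}" for j in range(spec.n)],
        R=R,
        drug_sim=_mixed_similarity(U, spec.sim_signal, sim_rng),
        disease_sim=_mixed_similarity(V, spec.sim_signal, sim_rng),
    ).validate()
    return dataset, SyntheticTruth(U, V, T)
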