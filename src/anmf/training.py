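"""Joint training of the two autoencoders and the GMF predictor.

The objective summed over a training pair set (positives ``R+`` plus
sampled negatives ``R-``) is

    Loss = sum_{(i,j)}  CE(r_ij, r^_ij)
           + phi * LossOfDrug_i
           + psi * LossOfDisease_j

where ``LossOfDrug_i`` / ``LossOfDisease_j`` are the autoencoder
reconstruction objectives of the drug/disease occurring in the pair
(re-evaluated per occurrence, so frequently interacting entities are
reconstructed more often).  All parameters are learned jointly by
mini-batch SGD; negatives and input corruption are resampled every epoch.

Every source of randomness (initialization, corruption, negative sampling,
shuffling, splits) derives from one seed through independent named streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .activations import get_activation
from .data_io import Dataset
from .encoder import CorruptionSpec, corrupt
from .metrics import EvalSplit, auc
from .model import ANMFModel, init_model, predict_matrix
from .predictor import EPS

__all__ = [
    "HyperParams", "TrainingSet", "TrainReport",
    "sample_negatives", "make_validation_split",
    "joint_loss", "joint_loss_and_grads",
    "fit", "fit_gmf_baseline",
]


@dataclass
class HyperParams:
    """All tunable quantities of the model and its optimizer.

    Defaults follow the validated configuration: reconstruction balances
    alpha=0.7 (drugs) and beta=0.3 (diseases), weight decay lam=0.001 /
    delta=0.01, reconstruction weights phi=psi=0.5, hidden dimension k=128,
    10 negatives per positive, masking noise at level 0.3.  Optimizer
    settings (plain SGD, lr=0.3, batch 64) and the tanh encoder activation
    were chosen for reliable convergence of the joint objective; see the
    methods notes for the rationale.
    """

    alpha: float = 0.7
    beta: float = 0.3
    lam: float = 0.001
    delta: float = 0.01
    phi: float = 0.5
    psi: float = 0.5
    k: int = 128
    n_neg: int = 10
    noise: CorruptionSpec = field(default_factory=lambda: CorruptionSpec("masking", 0.3))
    lr: float = 0.3
    epochs: int = 100
    batch_size: int = 64
    patience: int = 10
    g: str = "tanh"
    f: str = "sigmoid"
    out_activation: str = "sigmoid"
    resample_negatives: bool = True   # False: one static draw for all epochs
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must be in [0, 1]")
        if min(self.lam, self.delta, self.phi, self.psi, self.lr) < 0:
            raise ValueError("weights and rates must be >= 0")
        if min(self.k, self.epochs, self.batch_size) < 1 or self.n_neg < 0:
            raise ValueError("k, epochs, batch_size must be positive; n_neg >= 0")


@dataclass
class TrainingSet:
    positives: np.ndarray   # (P, 2) int pairs with target 1
    negatives: np.ndarray   # (N, 2) int pairs with target 0


@dataclass
class TrainReport:
    """Per-epoch loss components and the validation-metric trace."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int | None = None

    @property
    def total_loss(self) -> list[float]:
        return [e["total"] for e in self.epochs]

    @property
    def val_auc(self) -> list[float | None]:
        return [e.get("val_auc") for e in self.epochs]


def sample_negatives(train_R: np.ndarray, n_neg: int,
                     rng: np.random.Generator | int | None = 0) -> np.ndarray:
    """Draw ``n_neg`` unobserved pairs per positive, without replacement.

    If fewer unobserved cells exist than requested, all of them are
    returned with a warning.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    train_R = np.asarray(train_R)
    n_pos = int(train_R.sum())
    zero_flat = np.flatnonzero(train_R.ravel() == 0)
    want = n_neg * n_pos
    if want == 0:
        return np.empty((0, 2), dtype=int)
    if zero_flat.size < want:
        warnings.warn(
            f"only {zero_flat.size} unobserved pairs available, "
            f"requested {want}; using all of them")
        chosen = zero_flat
    else:
        chosen = rng.choice(zero_flat, size=want, replace=False)
    return np.column_stack(np.unravel_index(chosen, train_R.shape))


def make_validation_split(train_positives: np.ndarray, shape: tuple[int, int],
                          seed: int = 0) -> EvalSplit:
    """Hold out one training positive per drug for validation.

    Drugs with a single training positive keep it (so cold-start
    experiments stay intact); if every drug is single-positive the
    validation set is empty and a warning is issued.
    """
    rng = np.random.default_rng(seed)
    train_positives = np.asarray(train_positives)
    held, kept = [], []
    order = np.argsort(train_positives[:, 0], kind="mergesort")
    sorted_pos = train_positives[order]
    for drug in np.unique(sorted_pos[:, 0]):
        rows = sorted_pos[sorted_pos[:, 0] == drug]
        if len(rows) >= 2:
            pick = rng.integers(len(rows))
            held.append(rows[pick])
            kept.extend(np.delete(rows, pick, axis=0))
        else:
            kept.extend(rows)
    if not held:
        warnings.warn("every drug has a single positive; validation set is empty")
    R_mask = np.zeros(shape, dtype=bool)
    all_pos = np.asarray(train_positives)
    R_mask[all_pos[:, 0], all_pos[:, 1]] = True
    candidates = np.argwhere(~R_mask)
    return EvalSplit(
        train_positives=np.asarray(kept, dtype=int).reshape(-1, 2),
        test_positives=np.asarray(held, dtype=int).reshape(-1, 2),
        candidates=candidates,
    )


def _corrupted_inputs(dataset: Dataset, noise: CorruptionSpec,
                      rng: np.random.Generator | None):
    """One epoch's corrupted copies of the four input matrices."""
    if rng is None:  # inference / clean mode
        return dataset.R, dataset.drug_sim, dataset.R.T.copy(), dataset.disease_sim
    return (
        corrupt(dataset.R, noise, rng),
        corrupt(dataset.drug_sim, noise, rng),
        corrupt(dataset.R.T, noise, rng),
        corrupt(dataset.disease_sim, noise, rng),
    )


def _batch_pass(model: ANMFModel, dataset: Dataset, pairs: np.ndarray,
                targets: np.ndarray, hp: HyperParams, corrupted,
                compute_grads: bool):
    """Loss components (and optionally gradients) of one mini-batch.

    Returns ``(total, components, grads_or_None)`` where components are the
    *unweighted* sums of the prediction, drug-reconstruction and
    disease-reconstruction losses, so that
    ``total = pred + phi * drug + psi * disease`` exactly.
    """
    S_t, DS_t, ST_t, ZS_t = corrupted
    I = pairs[:, 0]
    J = pairs[:, 1]
    B = len(pairs)
    de, ze, h = model.drug_encoder, model.disease_encoder, model.predictor.h
    g, gp = get_activation(de.g)
    f, fp = get_activation(de.f)
    F, Fp = get_activation(model.predictor.out_activation)
    alpha = 1.0 if not model.use_similarity else hp.alpha
    beta = 1.0 if not model.use_similarity else hp.beta

    # drug side forward
    s_d, sim_d = dataset.R[I], dataset.drug_sim[I]
    st_d, simt_d = S_t[I], DS_t[I]
    A_d = st_d @ de.W1.T + simt_d @ de.V1.T + de.b_enc
    Z_d = g(A_d)
    preP_d = Z_d @ de.W2.T + de.b_dec_profile
    Phat_d = f(preP_d)
    preS_d = Z_d @ de.V2.T + de.b_dec_sim
    Shat_d = f(preS_d)

    # disease side forward (profiles are columns of R)
    s_z, sim_z = dataset.R.T[J], dataset.disease_sim[J]
    st_z, simt_z = ST_t[J], ZS_t[J]
    A_z = st_z @ ze.W1.T + simt_z @ ze.V1.T + ze.b_enc
    Z_z = g(A_z)
    preP_z = Z_z @ ze.W2.T + ze.b_dec_profile
    Phat_z = f(preP_z)
    preS_z = Z_z @ ze.V2.T + ze.b_dec_sim
    Shat_z = f(preS_z)

    # predictor
    u = Z_d * Z_z
    logit = u @ h
    rhat = F(logit)
    rhat_c = np.clip(rhat, EPS, 1.0 - EPS)
    L_pred = float(-np.sum(targets * np.log(rhat_c) + (1 - targets) * np.log(1 - rhat_c)))

    reg_d = de.weight_sq_norm()
    reg_z = ze.weight_sq_norm()
    L_drug = float(alpha * np.sum((s_d - Phat_d) ** 2)
                   + (1 - alpha) * np.sum((sim_d - Shat_d) ** 2)
                   + B * hp.lam * reg_d)
    L_dis = float(beta * np.sum((s_z - Phat_z) ** 2)
                  + (1 - beta) * np.sum((sim_z - Shat_z) ** 2)
                  + B * hp.delta * reg_z)
    components = {"pred": L_pred, "drug": L_drug, "disease": L_dis}
    total = L_pred + hp.phi * L_drug + hp.psi * L_dis
    if not compute_grads:
        return total, components, None

    # backward: cross-entropy through the output activation
    dL_drhat = (rhat_c - targets) / (rhat_c * (1 - rhat_c))
    dlogit = dL_drhat * Fp(logit)
    grads: dict[str, np.ndarray] = {"h": u.T @ dlogit}
    dZ_d = dlogit[:, None] * (h * Z_z)
    dZ_z = dlogit[:, None] * (h * Z_d)

    def encoder_back(enc, prefix, w_recon, bal, reg_w, s, sim, st, simt,
                     A, Z, preP, Phat, preS, Shat, dZ_pred):
        dpreP = w_recon * bal * 2.0 * (Phat - s) * fp(preP)
        dpreS = w_recon * (1 - bal) * 2.0 * (Shat - sim) * fp(preS)
        dZ = dZ_pred + dpreP @ enc.W2 + dpreS @ enc.V2
        dA = dZ * gp(A)
        grads[f"{prefix}_W2"] = dpreP.T @ Z + 2.0 * w_recon * reg_w * B * enc.W2
        grads[f"{prefix}_b_dec_profile"] = dpreP.sum(0)
        grads[f"{prefix}_W1"] = dA.T @ st + 2.0 * w_recon * reg_w * B * enc.W1
        grads[f"{prefix}_b_enc"] = dA.sum(0)
        if model.use_similarity:
            grads[f"{prefix}_V2"] = dpreS.T @ Z + 2.0 * w_recon * reg_w * B * enc.V2
            grads[f"{prefix}_b_dec_sim"] = dpreS.sum(0)
            grads[f"{prefix}_V1"] = dA.T @ simt + 2.0 * w_recon * reg_w * B * enc.V1
        else:
            grads[f"{prefix}_V2"] = np.zeros_like(enc.V2)
            grads[f"{prefix}_b_dec_sim"] = np.zeros_like(enc.b_dec_sim)
            grads[f"{prefix}_V1"] = np.zeros_like(enc.V1)

    encoder_back(de, "drug", hp.phi, alpha, hp.lam, s_d, sim_d, st_d, simt_d,
                 A_d, Z_d, preP_d, Phat_d, preS_d, Shat_d, dZ_d)
    encoder_back(ze, "disease", hp.psi, beta, hp.delta, s_z, sim_z, st_z, simt_z,
                 A_z, Z_z, preP_z, Phat_z, preS_z, Shat_z, dZ_z)
    return total, components, grads


def joint_loss(model: ANMFModel, dataset: Dataset, pairs: np.ndarray,
               targets: np.ndarray, hp: HyperParams,
               corrupted=None) -> tuple[float, dict]:
    """Total training loss of a pair batch, with its component breakdown.

    ``corrupted`` may supply the epoch's corrupted input matrices
    ``(R~, DrugSim~, R.T~, DiseaseSim~)``; by default clean inputs are used
    (inference-style evaluation of the objective).
    """
    if len(pairs) == 0:
        raise ValueError("batch must be non-empty")
    if corrupted is None:
        corrupted = _corrupted_inputs(dataset, hp.noise, None)
    total, comps, _ = _batch_pass(model, dataset, np.asarray(pairs),
                                  np.asarray(targets, dtype=float), hp,
                                  corrupted, compute_grads=False)
    return total, comps


def joint_loss_and_grads(model: ANMFModel, dataset: Dataset, pairs: np.ndarray,
                         targets: np.ndarray, hp: HyperParams,
                         corrupted=None):
    """As :func:`joint_loss` but also returns analytic gradients by tensor name."""
    if corrupted is None:
        corrupted = _corrupted_inputs(dataset, hp.noise, None)
    return _batch_pass(model, dataset, np.asarray(pairs),
                       np.asarray(targets, dtype=float), hp,
                       corrupted, compute_grads=True)


def _validation_auc(model: ANMFModel, train_dataset: Dataset, split: EvalSplit) -> float:
    scores = predict_matrix(model, train_dataset)
    pos = scores[split.test_positives[:, 0], split.test_positives[:, 1]]
    neg = scores[split.candidates[:, 0], split.candidates[:, 1]]
    return auc(pos, neg)


def fit(dataset: Dataset, hp: HyperParams,
        validation: EvalSplit | str | None = "auto",
        use_similarity: bool = True) -> tuple[ANMFModel, TrainReport]:
    """Train a model by mini-batch SGD on the joint objective.

    ``validation="auto"`` holds out one positive per multi-positive drug
    from ``dataset.R`` for early stopping (patience ``hp.patience`` on
    validation AUC); pass an :class:`EvalSplit` to supply your own, or
    ``None`` to train for the full ``hp.epochs``.  Deterministic given
    ``hp.seed``.
    """
    ss = np.random.SeedSequence(hp.seed)
    init_rng, corrupt_rng, neg_rng, shuffle_rng, split_rng = (
        np.random.default_rng(s) for s in ss.spawn(5))

    positives = np.argwhere(dataset.R == 1)
    if validation == "auto":
        validation = make_validation_split(
            positives, dataset.R.shape, seed=int(split_rng.integers(2**31)))
        if len(validation.test_positives) == 0:
            validation = None
    if validation is not None:
        train_pos = validation.train_positives
        train_R = np.zeros_like(dataset.R)
        train_R[train_pos[:, 0], train_pos[:, 1]] = 1.0
        train_dataset = Dataset(dataset.drug_ids, dataset.disease_ids, train_R,
                                dataset.drug_sim, dataset.disease_sim)
    else:
        train_pos = positives
        train_dataset = dataset

    m, n = dataset.R.shape
    model = init_model(init_rng, m, n, hp.k, g=hp.g, f=hp.f,
                       out_activation=hp.out_activation, use_similarity=use_similarity)
    report = TrainReport()
    best_auc, best_state, since_best = -np.inf, None, 0

    static_negatives = (None if hp.resample_negatives
                        else sample_negatives(train_dataset.R, hp.n_neg, neg_rng))
    for epoch in range(hp.epochs):
        negatives = (static_negatives if static_negatives is not None
                     else sample_negatives(train_dataset.R, hp.n_neg, neg_rng))
        if negatives.size:
            # sampling hygiene: a negative must never be a training positive
            assert not train_dataset.R[negatives[:, 0], negatives[:, 1]].any(), \
                "negative sample collides with a training positive"
        pairs = np.vstack([train_pos, negatives.reshape(-1, 2)])
        targets = np.concatenate([np.ones(len(train_pos)), np.zeros(len(negatives))])
        perm = shuffle_rng.permutation(len(pairs))
        pairs, targets = pairs[perm], targets[perm]
        corrupted = _corrupted_inputs(train_dataset, hp.noise, corrupt_rng)

        tot = np.zeros(3)
        for start in range(0, len(pairs), hp.batch_size):
            sl = slice(start, start + hp.batch_size)
            total, comps, grads = _batch_pass(
                model, train_dataset, pairs[sl], targets[sl], hp, corrupted, True)
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch start {start}: {comps}")
            decomposed = comps["pred"] + hp.phi * comps["drug"] + hp.psi * comps["disease"]
            assert abs(total - decomposed) <= 1e-8 * max(1.0, abs(total)), \
                "loss decomposition identity violated"
            scale = hp.lr / (min(start + hp.batch_size, len(pairs)) - start)
            tensors = model.tensors()
            for name, grad in grads.items():
                tensors[name] -= scale * grad
            tot += (comps["pred"], comps["drug"], comps["disease"])

        entry = {"epoch": epoch, "pred": tot[0], "drug": tot[1], "disease": tot[2],
                 "total": tot[0] + hp.phi * tot[1] + hp.psi * tot[2]}
        if validation is not None:
            val = _validation_auc(model, train_dataset, validation)
            entry["val_auc"] = val
            if val > best_auc + 1e-12:
                best_auc, since_best = val, 0
                best_state = {k: v.copy() for k, v in model.tensors().items()}
                report.best_epoch = epoch
            else:
                since_best += 1
                if since_best >= hp.patience:
                    report.epochs.append(entry)
                    break
        report.epochs.append(entry)

    if best_state is not None:
        tensors = model.tensors()
        for name, value in best_state.items():
            tensors[name][...] = value
    return model, report


def fit_gmf_baseline(dataset: Dataset, hp: HyperParams,
                     validation: EvalSplit | str | None = "auto"):
    """Train the GMF ablation: the same pipeline with the similarity pathway off."""
    return fit(dataset, hp, validation=validation, use_similarity=False)
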