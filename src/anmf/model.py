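"""Full model state: two additional autoencoders plus the GMF predictor.

The drug encoder consumes drug interaction profiles (length ``n``) and drug
similarity rows (length ``m``); the disease encoder consumes disease
profiles (length ``m``) and disease similarity rows (length ``n``).  The
predictor fuses the two hidden features into a treatment probability.

With ``use_similarity=False`` the similarity pathway is disabled (V weights
frozen at zero, similarity reconstruction dropped), which reduces the model
to a generalized-matrix-factorization (GMF) baseline trained on interaction
profiles alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .activations import get_activation
from .data_io import Dataset
from .encoder import EncoderParams, encode, init_encoder, glorot_uniform
from .predictor import PredictorParams

__all__ = ["ANMFModel", "init_model", "hidden_features", "predict_matrix",
           "save_model", "load_model"]


@dataclass
class ANMFModel:
    drug_encoder: EncoderParams
    disease_encoder: EncoderParams
    predictor: PredictorParams
    use_similarity: bool = True

    @property
    def k(self) -> int:
        return self.predictor.k

    def tensors(self) -> dict[str, np.ndarray]:
        """Flat name -> array view of every learnable tensor."""
        out = {f"drug_{k}": v for k, v in self.drug_encoder.tensors().items()}
        out.update({f"disease_{k}": v for k, v in self.disease_encoder.tensors().items()})
        out["h"] = self.predictor.h
        return out


def init_model(rng: np.random.Generator, m: int, n: int, k: int,
               g: str = "sigmoid", f: str = "sigmoid", out_activation: str = "sigmoid",
               use_similarity: bool = True) -> ANMFModel:
    """Glorot-initialized model for an ``m`` drugs x ``n`` diseases dataset."""
    drug_enc = init_encoder(rng, k, p=n, q=m, g=g, f=f)
    disease_enc = init_encoder(rng, k, p=m, q=n, g=g, f=f)
    if not use_similarity:
        drug_enc.V1[:] = 0.0
        drug_enc.V2[:] = 0.0
        disease_enc.V1[:] = 0.0
        disease_enc.V2[:] = 0.0
    h = glorot_uniform(rng, (k, 1))[:, 0]
    return ANMFModel(drug_enc, disease_enc, PredictorParams(h, out_activation),
                     use_similarity=use_similarity)


def hidden_features(model: ANMFModel, dataset: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Corruption-free hidden features for all drugs (m x k) and diseases (n x k)."""
    z_drug = encode(model.drug_encoder, dataset.R, dataset.drug_sim)
    z_dis = encode(model.disease_encoder, dataset.R.T, dataset.disease_sim)
    return z_drug, z_dis


def predict_matrix(model: ANMFModel, dataset: Dataset) -> np.ndarray:
    """Score every (drug, disease) pair in inference mode (no corruption)."""
    z_drug, z_dis = hidden_features(model, dataset)
    F, _ = get_activation(model.predictor.out_activation)
    # (i, j) entry: h . (z_drug[i] * z_dis[j]) = sum_k z_drug[i,k] h[k] z_dis[j,k]
    return F((z_drug * model.predictor.h) @ z_dis.T)


def top_recommendations(model: ANMFModel, dataset: Dataset, n: int = 10):
    """Ranked top-``n`` unverified diseases per drug as a tidy DataFrame.

    Verified pairs are excluded; columns are drug_id, disease_id, score,
    rank (1-based, best first).
    """
    import pandas as pd

    scores = predict_matrix(model, dataset)
    rows = []
    for i, drug in enumerate(dataset.drug_ids):
        unverified = np.flatnonzero(dataset.R[i] == 0)
        order = unverified[np.argsort(-scores[i, unverified], kind="mergesort")][:n]
        for rank, j in enumerate(order, start=1):
            rows.append((drug, dataset.disease_ids[j], scores[i, j], rank))
    return pd.DataFrame(rows, columns=["drug_id", "disease_id", "score", "rank"])


def save_model(model: ANMFModel, out_dir: str | Path) -> None:
    """Write parameters as an .npz archive plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez(out_dir / "model.npz", **model.tensors())
    manifest = {
        "k": model.k,
        "use_similarity": model.use_similarity,
        "activations": {
            "g": model.drug_encoder.g,
            "f": model.drug_encoder.f,
            "out": model.predictor.out_activation,
        },
        "shapes": {name: list(t.shape) for name, t in model.tensors().items()},
    }
    (out_dir / "model_manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(out_dir: str | Path) -> ANMFModel:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "model_manifest.json").read_text())
    arrays = dict(np.load(out_dir / "model.npz"))
    acts = manifest["activations"]

    def enc(prefix: str) -> EncoderParams:
        return EncoderParams(
            W1=arrays[f"{prefix}_W1"], V1=arrays[f"{prefix}_V1"],
            b_enc=arrays[f"{prefix}_b_enc"], W2=arrays[f"{prefix}_W2"],
            b_dec_profile=arrays[f"{prefix}_b_dec_profile"],
            V2=arrays[f"{prefix}_V2"], b_dec_sim=arrays[f"{prefix}_b_dec_sim"],
            g=acts["g"], f=acts["f"],
        )

    return ANMFModel(enc("drug"), enc("disease"),
                     PredictorParams(arrays["h"], acts["out"]),
                     use_similarity=manifest["use_similarity"])
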