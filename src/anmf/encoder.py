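"""Additional denoising autoencoder for hidden-feature extraction.

One encoder instance serves one entity side (drugs or diseases).  Its input
is a corrupted interaction profile (length ``p``) together with a corrupted
similarity vector (length ``q``); both are mapped into a shared hidden
feature of dimension ``k``:

    z = g(W1 @ profile~ + V1 @ sim~ + b_enc)

and decoded back to reconstructions of the *clean* inputs:

    profile^ = f(W2 @ z + b_dec_profile)
    sim^     = f(V2 @ z + b_dec_sim)

The reconstruction objective balances the two errors with a weight
``alpha`` and penalizes the squared Frobenius norms of the four weight
matrices (biases are not regularized):

    alpha * ||profile - profile^||^2
      + (1 - alpha) * ||sim - sim^||^2
      + lam * (||W1||^2 + ||W2||^2 + ||V1||^2 + ||V2||^2)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activations import get_activation

__all__ = [
    "EncoderParams",
    "CorruptionSpec",
    "corrupt",
    "init_encoder",
    "encode",
    "decode_profile",
    "decode_similarity",
    "reconstruction_loss",
    "encoder_loss_and_grads",
    "glorot_uniform",
]


@dataclass
class CorruptionSpec:
    """How to corrupt an input vector before encoding.

    kind
        ``"masking"`` zeroes each coordinate independently with probability
        ``level`` (no rescaling of survivors), ``"gaussian"`` adds
        ``N(0, level^2)`` noise, ``"none"`` is the identity.
    """

    kind: str = "masking"
    level: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("masking", "gaussian", "none"):
            raise ValueError(f"unknown corruption kind {self.kind!r}")
        if self.level < 0:
            raise ValueError("corruption level must be >= 0")
        if self.kind == "masking" and self.level > 1:
            raise ValueError("masking level must be <= 1")


def corrupt(x: np.ndarray, spec: CorruptionSpec,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Return a corrupted copy of ``x`` (any shape); deterministic given seed."""
    x = np.asarray(x, dtype=float)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.kind == "none" or spec.level == 0:
        return x.copy()
    if spec.kind == "masking":
        keep = rng.random(x.shape) >= spec.level
        return x * keep
    return x + rng.normal(0.0, spec.level, size=x.shape)


@dataclass
class EncoderParams:
    """Weights of one additional autoencoder (see module docstring)."""

    W1: np.ndarray          # k x p
    V1: np.ndarray          # k x q
    b_enc: np.ndarray       # k
    W2: np.ndarray          # p x k
    b_dec_profile: np.ndarray  # p
    V2: np.ndarray          # q x k
    b_dec_sim: np.ndarray   # q
    g: str = "sigmoid"      # encoder activation
    f: str = "sigmoid"      # decoder activation

    @property
    def k(self) -> int:
        return self.W1.shape[0]

    @property
    def p(self) -> int:
        return self.W1.shape[1]

    @property
    def q(self) -> int:
        return self.V1.shape[1]

    def weight_sq_norm(self) -> float:
        """Sum of squared Frobenius norms of W1, W2, V1, V2."""
        return float(sum(np.sum(M * M) for M in (self.W1, self.W2, self.V1, self.V2)))

    def tensors(self) -> dict[str, np.ndarray]:
        return {
            "W1": self.W1, "V1": self.V1, "b_enc": self.b_enc,
            "W2": self.W2, "b_dec_profile": self.b_dec_profile,
            "V2": self.V2, "b_dec_sim": self.b_dec_sim,
        }


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Uniform init in +-sqrt(6 / (fan_in + fan_out))."""
    bound = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-bound, bound, size=shape)


def init_encoder(rng: np.random.Generator, k: int, p: int, q: int,
                 g: str = "sigmoid", f: str = "sigmoid") -> EncoderParams:
    """Glorot-uniform weights, zero biases."""
    return EncoderParams(
        W1=glorot_uniform(rng, (k, p)),
        V1=glorot_uniform(rng, (k, q)),
        b_enc=np.zeros(k),
        W2=glorot_uniform(rng, (p, k)),
        b_dec_profile=np.zeros(p),
        V2=glorot_uniform(rng, (q, k)),
        b_dec_sim=np.zeros(q),
        g=g, f=f,
    )


def encode(params: EncoderParams, profile_corrupted: np.ndarray,
           sim_corrupted: np.ndarray) -> np.ndarray:
    """Hidden feature ``g(W1 @ profile + V1 @ sim + b_enc)``.

    Accepts a single vector or a batch (rows = entities).
    """
    profile_corrupted = np.asarray(profile_corrupted, dtype=float)
    sim_corrupted = np.asarray(sim_corrupted, dtype=float)
    if profile_corrupted.shape[-1] != params.p or sim_corrupted.shape[-1] != params.q:
        raise ValueError(
            f"expected profile length {params.p} and similarity length {params.q}, "
            f"got {profile_corrupted.shape[-1]} and {sim_corrupted.shape[-1]}"
        )
    g, _ = get_activation(params.g)
    pre = profile_corrupted @ params.W1.T + sim_corrupted @ params.V1.T + params.b_enc
    return g(pre)


def decode_profile(params: EncoderParams, z: np.ndarray) -> np.ndarray:
    """Reconstructed interaction profile ``f(W2 @ z + b_dec_profile)``."""
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != params.k:
        raise ValueError(f"hidden feature length {z.shape[-1]} != k={params.k}")
    f, _ = get_activation(params.f)
    return f(z @ params.W2.T + params.b_dec_profile)


def decode_similarity(params: EncoderParams, z: np.ndarray) -> np.ndarray:
    """Reconstructed similarity vector ``f(V2 @ z + b_dec_sim)``."""
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != params.k:
        raise ValueError(f"hidden feature length {z.shape[-1]} != k={params.k}")
    f, _ = get_activation(params.f)
    return f(z @ params.V2.T + params.b_dec_sim)


def reconstruction_loss(params: EncoderParams, profile: np.ndarray, sim: np.ndarray,
                        profile_hat: np.ndarray, sim_hat: np.ndarray,
                        alpha: float, reg: float) -> float:
    """Weighted reconstruction error plus weight-decay penalty (scalar).

    ``alpha`` balances profile vs. similarity reconstruction and must lie in
    [0, 1]; ``reg`` (lambda) scales the squared-norm penalty on the weight
    matrices only.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if reg < 0:
        raise ValueError("regularization must be >= 0")
    e_profile = float(np.sum((np.asarray(profile) - np.asarray(profile_hat)) ** 2))
    e_sim = float(np.sum((np.asarray(sim) - np.asarray(sim_hat)) ** 2))
    return alpha * e_profile + (1.0 - alpha) * e_sim + reg * params.weight_sq_norm()


def encoder_loss_and_grads(params: EncoderParams, profile: np.ndarray, sim: np.ndarray,
                           profile_tilde: np.ndarray, sim_tilde: np.ndarray,
                           alpha: float, reg: float):
    """Forward + backward pass of the reconstruction objective for one entity.

    Returns ``(loss, grads)`` where ``grads`` maps tensor names (as in
    :meth:`EncoderParams.tensors`) to arrays of matching shape.
    """
    g, gp = get_activation(params.g)
    f, fp = get_activation(params.f)
    a = params.W1 @ profile_tilde + params.V1 @ sim_tilde + params.b_enc
    z = g(a)
    pre_p = params.W2 @ z + params.b_dec_profile
    p_hat = f(pre_p)
    pre_s = params.V2 @ z + params.b_dec_sim
    s_hat = f(pre_s)
    loss = reconstruction_loss(params, profile, sim, p_hat, s_hat, alpha, reg)

    d_pre_p = alpha * 2.0 * (p_hat - profile) * fp(pre_p)
    d_pre_s = (1.0 - alpha) * 2.0 * (s_hat - sim) * fp(pre_s)
    dz = params.W2.T @ d_pre_p + params.V2.T @ d_pre_s
    da = dz * gp(a)
    grads = {
        "W2": np.outer(d_pre_p, z) + 2.0 * reg * params.W2,
        "b_dec_profile": d_pre_p,
        "V2": np.outer(d_pre_s, z) + 2.0 * reg * params.V2,
        "b_dec_sim": d_pre_s,
        "W1": np.outer(da, profile_tilde) + 2.0 * reg * params.W1,
        "V1": np.outer(da, sim_tilde) + 2.0 * reg * params.V1,
        "b_enc": da,
    }
    return loss, grads
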