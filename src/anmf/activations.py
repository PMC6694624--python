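"""Activation functions and their derivatives.

Both the encoder/decoder nonlinearities and the output activation of the
predictor are configurable; each entry maps a pre-activation array to the
activation value and, for backpropagation, the derivative evaluated at the
pre-activation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ACTIVATIONS", "get_activation", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _sigmoid_deriv(x: np.ndarray) -> np.ndarray:
    s = sigmoid(x)
    return s * (1.0 - s)


ACTIVATIONS: dict[str, tuple] = {
    "sigmoid": (sigmoid, _sigmoid_deriv),
    "identity": (lambda x: np.asarray(x, dtype=float), lambda x: np.ones_like(x, dtype=float)),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(float)),
}


def get_activation(name: str):
    """Return ``(f, f_prime)`` for a named activation.

    Raises
    ------
    KeyError
        If the name is not registered.
    """
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}"
        ) from None
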