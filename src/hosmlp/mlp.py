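"""Single-hidden-layer sigmoid MLP with a flat parameter encoding.

The network is a classical feedforward perceptron: an input layer of ``n``
features, one hidden layer of ``h`` sigmoid units, and ``k`` sigmoid output
units (one per class, trained against one-hot targets).  All weights and
biases live in a single flat vector so that a derivative-free optimizer can
search them directly; the layout is fixed as ``W1`` (h x n, row-major by
hidden neuron), ``b1`` (h), ``W2`` (k x h, row-major by output neuron),
``b2`` (k).

The hidden width follows the Kolmogorov sizing rule ``h = 2 n + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "EncodingError",
    "MLPArchitecture",
    "decode",
    "encode",
    "forward",
    "hidden_size",
    "load_params",
    "mse_fitness",
    "predict",
    "save_params",
]


class EncodingError(ValueError):
    """Parameter vector length does not match the architecture."""


@dataclass(frozen=True)
class MLPArchitecture:
    """Layer sizes of a single-hidden-layer network."""

    n_input: int
    n_hidden: int
    n_output: int

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ValueError("all layer sizes must be >= 1")

    @property
    def parameter_count(self) -> int:
        """Total number of weights and biases in the flat encoding."""
        return self.n_hidden * (self.n_input + 1) + self.n_output * (self.n_hidden + 1)


def hidden_size(n_input: int) -> int:
    """Kolmogorov sizing rule for the hidden layer: ``2 * n_input + 1``."""
    if n_input < 1:
        raise ValueError("n_input must be >= 1")
    return 2 * n_input + 1


def encode(
    W1: np.ndarray, b1: np.ndarray, W2: np.ndarray, b2: np.ndarray
) -> np.ndarray:
    """Flatten weight matrices and bias vectors into one parameter vector."""
    return np.concatenate(
        [np.ravel(W1), np.ravel(b1), np.ravel(W2), np.ravel(b2)]
    ).astype(float)


def decode(
    params: np.ndarray, arch: MLPArchitecture
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split a flat parameter vector into (W1, b1, W2, b2).

    Shapes are (h, n), (h,), (k, h), (k,).  Raises :class:`EncodingError`
    naming the expected and actual lengths on mismatch.
    """
    v = np.ravel(np.asarray(params, dtype=float))
    if v.size != arch.parameter_count:
        raise EncodingError(
            f"parameter vector has length {v.size}, architecture "
            f"{arch.n_input}-{arch.n_hidden}-{arch.n_output} requires "
            f"{arch.parameter_count}"
        )
    n, h, k = arch.n_input, arch.n_hidden, arch.n_output
    i = 0
    W1 = v[i : i + h * n].reshape(h, n)
    i += h * n
    b1 = v[i : i + h]
    i += h
    W2 = v[i : i + k * h].reshape(k, h)
    i += k * h
    b2 = v[i : i + k]
    return W1, b1, W2, b2


def forward(
    arch: MLPArchitecture, params: np.ndarray, features: np.ndarray
) -> np.ndarray:
    """Forward pass: sigmoid hidden layer followed by sigmoid outputs.

    ``features`` is a (samples, n_input) matrix; the result is a
    (samples, n_output) matrix of values in (0, 1).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != arch.n_input:
        raise ValueError(
            f"features have {X.shape[1]} columns, architecture expects {arch.n_input}"
        )
    W1, b1, W2, b2 = decode(params, arch)
    hidden = expit(X @ W1.T + b1)
    return expit(hidden @ W2.T + b2)


def predict(
    arch: MLPArchitecture, params: np.ndarray, features: np.ndarray
) -> np.ndarray:
    """Class labels from the network outputs.

    Multi-output networks take the argmax over output neurons (ties go to the
    lowest index).  A single-output network uses the 0.5 threshold: label 0
    when the output is below 0.5, label 1 otherwise.
    """
    out = forward(arch, params, features)
    if arch.n_output == 1:
        return (out[:, 0] >= 0.5).astype(int)
    return np.argmax(out, axis=1)


def mse_fitness(
    arch: MLPArchitecture,
    params: np.ndarray,
    features: np.ndarray,
    targets_onehot: np.ndarray,
) -> float:
    """Mean squared error between outputs and one-hot targets.

    The mean runs over both samples and output neurons so the fitness scale
    is comparable across architectures.
    """
    T = np.atleast_2d(np.asarray(targets_onehot, dtype=float))
    out = forward(arch, params, features)
    if out.shape != T.shape:
        raise ValueError(f"targets have shape {T.shape}, outputs {out.shape}")
    diff = out - T
    return float(np.mean(diff * diff))


def save_params(path, params: np.ndarray, arch: MLPArchitecture) -> None:
    """Checkpoint a parameter vector as delimited text.

    The first line records the architecture so the checkpoint is
    self-describing.
    """
    v = np.ravel(np.asarray(params, dtype=float))
    if v.size != arch.parameter_count:
        raise EncodingError(
            f"parameter vector has length {v.size}, expected {arch.parameter_count}"
        )
    header = f"architecture {arch.n_input} {arch.n_hidden} {arch.n_output}"
    np.savetxt(path, v, header=header, fmt="%.17g")


def load_params(path) -> tuple[np.ndarray, MLPArchitecture]:
    """Load a checkpoint written by :func:`save_params`."""
    with open(path) as fh:
        first = fh.readline().strip()
    tokens = first.lstrip("#").split()
    if len(tokens) != 4 or tokens[0] != "architecture":
        raise EncodingError(f"malformed checkpoint header: {first!r}")
    arch = MLPArchitecture(int(tokens[1]), int(tokens[2]), int(tokens[3]))
    v = np.loadtxt(path)
    v = np.atleast_1d(v)
    if v.size != arch.parameter_count:
        raise EncodingError(
            f"checkpoint has {v.size} parameters, header implies {arch.parameter_count}"
        )
    return v, arch
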