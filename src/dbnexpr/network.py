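"""Feedforward network model: forward pass, MSE, output decoding.

The network is a multilayer perceptron with logistic activation on every
layer (hidden and output), the form a deep belief network takes after
unrolling its pretrained RBM stack:

    a^(1) = x,    a^(l) = σ(w^(l) a^(l−1) + b^(l)),  l = 2..L

Architectures are written as dash-separated strings, e.g. "A-500-100-1",
where "A" stands for the input dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rbm import RBMModel, sigmoid

__all__ = [
    "NetworkModel",
    "OutputEncoding",
    "feedforward",
    "forward_batch",
    "mse_error",
    "predict_class",
    "init_from_pretrained",
    "init_random",
    "parse_architecture",
    "encode_targets",
]


@dataclass
class NetworkModel:
    """Stacked layer weights and biases with logistic activation.

    ``weights[i]`` maps layer i to layer i+1 and has shape
    (size_{i+1}, size_i) — the convention w^(l) a^(l−1) + b^(l).
    """

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        sizes = [int(s) for s in self.layer_sizes]
        if len(sizes) < 2:
            raise ValueError("network needs at least input and output layers")
        if len(self.weights) != len(sizes) - 1 or len(self.biases) != len(sizes) - 1:
            raise ValueError("need one weight matrix and bias per non-input layer")
        self.layer_sizes = sizes
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        self.biases = [np.asarray(b, dtype=float) for b in self.biases]
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[l + 1], sizes[l]):
                raise ValueError(
                    f"weight {l} has shape {w.shape}, expected "
                    f"{(sizes[l + 1], sizes[l])}"
                )
            if b.shape != (sizes[l + 1],):
                raise ValueError(f"bias {l} has shape {b.shape}")
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise ValueError("network parameters must be finite")

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)

    @property
    def input_size(self) -> int:
        return self.layer_sizes[0]

    @property
    def output_size(self) -> int:
        return self.layer_sizes[-1]

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            list(self.layer_sizes),
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
        )


@dataclass(frozen=True)
class OutputEncoding:
    """How class labels map to network targets.

    ``single-node`` uses one output with hard targets {0, 1}; ``two-node``
    (and its k-class generalization) uses one node per class with softened
    one-hot targets: p for the true class, 1 − p elsewhere.
    """

    mode: str = "single-node"
    p: float = 0.9

    def __post_init__(self) -> None:
        if self.mode not in ("single-node", "two-node"):
            raise ValueError(f"unknown encoding mode {self.mode!r}")
        if not 0.5 < self.p <= 1.0:
            raise ValueError("soft target p must lie in (0.5, 1]")

    def output_size(self, n_classes: int) -> int:
        if self.mode == "single-node":
            if n_classes != 2:
                raise ValueError("single-node encoding requires 2 classes")
            return 1
        return n_classes


def encode_targets(labels, classes: list[str], enc: OutputEncoding) -> np.ndarray:
    """Encode class labels as network target vectors (n_samples × n_out)."""
    index = {c: i for i, c in enumerate(classes)}
    idx = np.array([index[l] for l in labels], dtype=int)
    if enc.mode == "single-node":
        return idx.astype(float).reshape(-1, 1)
    T = np.full((len(idx), len(classes)), 1.0 - enc.p)
    T[np.arange(len(idx)), idx] = enc.p
    return T


def feedforward(m: NetworkModel, x: np.ndarray) -> list[np.ndarray]:
    """All layer activations a^(1..L) for one input vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (m.input_size,):
        raise ValueError(f"input length {x.shape} != {m.input_size}")
    activations = [x]
    for w, b in zip(m.weights, m.biases):
        activations.append(sigmoid(w @ activations[-1] + b))
    return activations


def forward_batch(m: NetworkModel, X: np.ndarray) -> list[np.ndarray]:
    """Vectorized forward pass; returns per-layer (n_samples × size) arrays."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.input_size:
        raise ValueError(f"input width {X.shape[1]} != {m.input_size}")
    activations = [X]
    for w, b in zip(m.weights, m.biases):
        activations.append(sigmoid(activations[-1] @ w.T + b))
    return activations


def mse_error(outputs, targets) -> float:
    """Mean squared error E = (1/n) Σ_i ‖o_i − t_i‖²."""
    O = np.atleast_2d(np.asarray(outputs, dtype=float))
    T = np.atleast_2d(np.asarray(targets, dtype=float))
    if O.size == 0:
        raise ValueError("mse_error needs at least one output/target pair")
    if O.shape != T.shape:
        raise ValueError(f"shape mismatch {O.shape} vs {T.shape}")
    return float(np.mean(np.sum((O - T) ** 2, axis=1)))


def predict_class(output: np.ndarray, enc: OutputEncoding) -> int:
    """Decode a network output vector to a class index.

    Single-node outputs are rounded to {0, 1}; multi-node outputs take the
    index of the highest value, ties broken toward the lowest index.
    """
    out = np.asarray(output, dtype=float).ravel()
    if enc.mode == "single-node":
        if out.shape != (1,):
            raise ValueError("single-node encoding expects 1 output")
        return int(out[0] >= 0.5)
    return int(np.argmax(out))  # argmax returns the first (lowest) max index


def parse_architecture(spec: str, input_size: int) -> list[int]:
    """Expand an architecture string like "A-500-100-1" to layer sizes.

    "A" (first token only by convention, but accepted anywhere) stands for
    ``input_size``.  All sizes must be positive integers.
    """
    sizes: list[int] = []
    for token in spec.split("-"):
        token = token.strip()
        if token == "A":
            sizes.append(int(input_size))
            continue
        try:
            size = int(token)
        except ValueError:
            raise ValueError(f"invalid architecture token {token!r} in {spec!r}") from None
        if size <= 0:
            raise ValueError(f"layer size must be positive, got {size} in {spec!r}")
        sizes.append(size)
    if len(sizes) < 2:
        raise ValueError(f"architecture {spec!r} needs at least 2 layers")
    return sizes


def init_random(layer_sizes: list[int], seed: int) -> NetworkModel:
    """Random initialization: weights ~ N(0, 0.01), zero biases."""
    rng = np.random.default_rng(seed)
    weights = [
        rng.normal(0.0, 0.01, size=(layer_sizes[l + 1], layer_sizes[l]))
        for l in range(len(layer_sizes) - 1)
    ]
    biases = [np.zeros(layer_sizes[l + 1]) for l in range(len(layer_sizes) - 1)]
    return NetworkModel(list(layer_sizes), weights, biases)


def init_from_pretrained(
    stack: list[RBMModel], output_size: int, seed: int,
    input_size: int | None = None,
) -> NetworkModel:
    """Unroll a pretrained RBM stack into a feedforward classifier.

    Hidden layers copy the RBM weights (transposed to the w^(l) convention)
    and hidden biases; the output layer is freshly initialized
    N(0, 0.01) with zero biases.  With an empty stack, ``input_size`` must be
    given and the result is a single-layer logistic model.
    """
    if not stack:
        if input_size is None:
            raise ValueError("empty stack requires explicit input_size")
        return init_random([input_size, output_size], seed)
    sizes = [stack[0].n_visible]
    for i, rbm in enumerate(stack):
        if rbm.n_visible != sizes[-1]:
            raise ValueError(
                f"stack inconsistent: RBM {i} has {rbm.n_visible} visible "
                f"units, previous layer has {sizes[-1]}"
            )
        sizes.append(rbm.n_hidden)
    sizes.append(int(output_size))
    rng = np.random.default_rng(seed)
    weights = [rbm.weights.T.copy() for rbm in stack]
    biases = [rbm.hidden_bias.copy() for rbm in stack]
    weights.append(rng.normal(0.0, 0.01, size=(output_size, sizes[-2])))
    biases.append(np.zeros(output_size))
    return NetworkModel(sizes, weights, biases)
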