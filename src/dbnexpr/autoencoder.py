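"""Autoencoders unfolded from a pretrained RBM stack.

Unfolding mirrors the encoder: a stack m → h₁ → … → h_c becomes the
palindromic network m - h₁ - … - h_c - … - h₁ - m, with decoder weights
initialized to the transposed encoder weights and the RBMs' visible biases
(untied thereafter).  The central bottleneck — the code layer — is the
learned representation; fine-tuning minimizes reconstruction error with
targets equal to the ([0, 1]-scaled) inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .finetune import TrainConfig, TrainingHistory, train
from .network import NetworkModel, forward_batch
from .rbm import RBMModel

__all__ = ["AutoencoderModel", "build_autoencoder", "train_autoencoder", "encode"]


@dataclass
class AutoencoderModel:
    """A NetworkModel with palindromic layer sizes and a marked code layer."""

    network: NetworkModel
    code_layer_index: int  # index into the layer list (0-based)

    def __post_init__(self) -> None:
        sizes = self.network.layer_sizes
        if sizes != sizes[::-1]:
            raise ValueError(f"autoencoder layer sizes must be palindromic: {sizes}")
        if self.code_layer_index != (len(sizes) - 1) // 2:
            raise ValueError("code layer must be the middle layer")

    @property
    def code_size(self) -> int:
        return self.network.layer_sizes[self.code_layer_index]


def build_autoencoder(stack: list[RBMModel]) -> AutoencoderModel:
    """Unfold a pretrained stack into an encoder/decoder network."""
    if not stack:
        raise ValueError("cannot unfold an empty RBM stack")
    sizes = [stack[0].n_visible] + [r.n_hidden for r in stack]
    full_sizes = sizes + sizes[-2::-1]
    enc_w = [r.weights.T.copy() for r in stack]
    enc_b = [r.hidden_bias.copy() for r in stack]
    dec_w = [r.weights.copy() for r in reversed(stack)]
    dec_b = [r.visible_bias.copy() for r in reversed(stack)]
    net = NetworkModel(full_sizes, enc_w + dec_w, enc_b + dec_b)
    return AutoencoderModel(net, code_layer_index=len(stack))


def train_autoencoder(
    m: AutoencoderModel, X: np.ndarray, cfg: TrainConfig
) -> tuple[AutoencoderModel, TrainingHistory]:
    """Fine-tune for reconstruction: targets are the inputs themselves.

    Uses the supervised trainer with targets = X, so either optimizer
    (bprop or rprop) applies; the history's error column is the
    reconstruction MSE per epoch.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    net, history = train(m.network, X, X, cfg)
    return AutoencoderModel(net, m.code_layer_index), history


def encode(m: AutoencoderModel, X: np.ndarray) -> np.ndarray:
    """Code-layer activations for each sample (n_samples × code size)."""
    return forward_batch(m.network, X)[m.code_layer_index]
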