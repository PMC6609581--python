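"""Hybrid classifiers: a learned representation feeding an SVM.

The network (a fine-tuned DBN, a pretrained RBM stack, or an autoencoder)
acts as a representation learner; the activations of a chosen hidden layer
(the code layer for autoencoders) become the SVM's input features.  A
passthrough source skips extraction, reducing the hybrid exactly to a plain
SVM on the raw features — a useful correctness law.

The SVM is scikit-learn's LIBSVM-backed :class:`~sklearn.svm.SVC`,
a pluggable downstream component behind a fit/predict contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.svm import SVC

from .autoencoder import AutoencoderModel, encode
from .network import NetworkModel, forward_batch
from .rbm import RBMModel, stack_transform

__all__ = [
    "SVMSpec",
    "RepresentationExtractor",
    "HybridClassifier",
    "extract",
    "train_hybrid",
    "predict_hybrid",
    "grid_search_svm",
]


@dataclass(frozen=True)
class SVMSpec:
    """SVM hyperparameters: kernel ∈ {linear, rbf}, cost C, RBF width γ."""

    kernel: str = "linear"
    C: float = 1.0
    gamma: float | str = "auto"  # "auto" = 1 / n_features

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be 'linear' or 'rbf', got {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be > 0")

    def build(self) -> SVC:
        return SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)


@dataclass(frozen=True)
class RepresentationExtractor:
    """A trained model plus the layer whose activations become features.

    ``source`` is one of ``finetuned-dbn``, ``pretrained-stack``,
    ``autoencoder`` or ``passthrough``.  ``layer_index`` is the 1-based
    hidden-layer ordinal (for DBNs and stacks); autoencoders always use
    their code layer and passthrough ignores it.
    """

    source: str
    model: object = None
    layer_index: int | None = None

    def __post_init__(self) -> None:
        if self.source not in (
            "finetuned-dbn", "pretrained-stack", "autoencoder", "passthrough"
        ):
            raise ValueError(f"unknown representation source {self.source!r}")
        if self.source == "finetuned-dbn":
            net: NetworkModel = self.model  # type: ignore[assignment]
            n_hidden_layers = net.n_layers - 2
            idx = self.layer_index or n_hidden_layers
            if not 1 <= idx <= n_hidden_layers:
                raise ValueError(
                    f"layer_index {idx} invalid for a network with "
                    f"{n_hidden_layers} hidden layers"
                )
            object.__setattr__(self, "layer_index", idx)
        elif self.source == "pretrained-stack":
            stack: list[RBMModel] = self.model  # type: ignore[assignment]
            idx = self.layer_index or len(stack)
            if not 1 <= idx <= len(stack):
                raise ValueError(
                    f"layer_index {idx} invalid for a stack of {len(stack)} RBMs"
                )
            object.__setattr__(self, "layer_index", idx)


def extract(e: RepresentationExtractor, X: np.ndarray) -> np.ndarray:
    """Feature matrix for X under the extractor's source/layer."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if e.source == "passthrough":
        return X
    if e.source == "finetuned-dbn":
        return forward_batch(e.model, X)[e.layer_index]
    if e.source == "pretrained-stack":
        return stack_transform(e.model, X, upto=e.layer_index)
    return encode(e.model, X)  # autoencoder code layer


@dataclass
class HybridClassifier:
    """A representation extractor bound to a trained SVM."""

    extractor: RepresentationExtractor
    svm: SVC
    degenerate_features: bool = False  # all-constant representation flag
    classes: list[str] = field(default_factory=list)


def train_hybrid(
    X: np.ndarray,
    labels,
    e: RepresentationExtractor,
    svm_spec: SVMSpec = SVMSpec(),
) -> HybridClassifier:
    """Fit an SVM on extracted features (Algorithm-2 steps 2–3).

    The extractor's model must already be trained on the same training data.
    A constant-feature representation is flagged on the returned classifier
    (the SVM then degenerates toward the majority class).
    """
    labels = np.asarray(labels, dtype=object)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training labels contain a single class")
    F = extract(e, X)
    degenerate = bool(np.all(F.std(axis=0) < 1e-12))
    if degenerate:
        warnings.warn(
            "extracted representation is constant across samples; the SVM "
            "will degenerate to the majority class", stacklevel=2,
        )
    svm = svm_spec.build()
    svm.fit(F, labels)
    return HybridClassifier(e, svm, degenerate_features=degenerate,
                            classes=sorted(set(labels.tolist())))


def predict_hybrid(h: HybridClassifier, X: np.ndarray) -> np.ndarray:
    """Predicted labels: extract features, then the SVM decision."""
    return h.svm.predict(extract(h.extractor, X))


def grid_search_svm(
    X: np.ndarray,
    labels,
    e: RepresentationExtractor,
    kernel: str = "rbf",
    C_grid=(0.1, 1.0, 10.0, 100.0),
    gamma_grid=(1e-4, 1e-3, 1e-2, 1e-1, 1.0),
    n_folds: int = 5,
    seed: int = 0,
) -> SVMSpec:
    """Pick (C, γ) by simple cross-validated accuracy on extracted features."""
    from .data_model import kfold_split

    labels = np.asarray(labels, dtype=object)
    F = extract(e, X)
    folds = kfold_split(len(labels), n_folds, labels=labels, seed=seed)
    gammas = gamma_grid if kernel == "rbf" else ("auto",)
    best, best_acc = None, -1.0
    for C, gamma in product(C_grid, gammas):
        spec = SVMSpec(kernel=kernel, C=C, gamma=gamma)
        correct = 0
        for f in range(1, n_folds + 1):
            tr, te = folds.train_indices(f), folds.test_indices(f)
            svm = spec.build()
            svm.fit(F[tr], labels[tr])
            correct += int(np.sum(svm.predict(F[te]) == labels[te]))
        acc = correct / len(labels)
        if acc > best_acc:
            best, best_acc = spec, acc
    return best
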