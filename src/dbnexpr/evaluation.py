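"""Confusion-matrix metrics and the cross-validated evaluation harness.

Metrics follow the standard contingency-table definitions:

    Acc = (TP + TN) / (TP + FP + FN + TN)
    TPR = TP / (TP + FN)          (sensitivity)
    TNR = TN / (TN + FP)          (specificity)
    E   = (FP + FN) / (TP + FP + FN + TN)

so Acc + E = 1 holds exactly per fold.  The harness runs k-fold
cross-validation (k = 10 by default in configs): folds are stratified,
undersampling — when requested — touches training folds only, feature
selection and input scaling are fit on the training portion of each fold
(optionally globally, for comparison), the full learner (pretraining +
fine-tuning, an SVM, or a hybrid) is retrained per fold, and per-fold
metrics are aggregated as mean ± standard error (sd over folds / √k).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autoencoder import build_autoencoder, train_autoencoder
from .data_model import (
    ExpressionDataset,
    FoldAssignment,
    kfold_split,
    select_top_variance,
    undersample,
)
from .finetune import TrainConfig, train
from .hybrid import (
    RepresentationExtractor,
    SVMSpec,
    predict_hybrid,
    train_hybrid,
)
from .network import (
    NetworkModel,
    OutputEncoding,
    encode_targets,
    forward_batch,
    init_from_pretrained,
    init_random,
    parse_architecture,
)
from .rbm import CDConfig, MinMaxScaler, pretrain_stack

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "LearnerSpec",
    "confusion",
    "metrics",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts for one binary (or one-vs-rest) comparison."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(predicted, truth, positive) -> ConfusionCounts:
    """Contingency-table counts treating ``positive`` as the positive label."""
    pred = np.asarray(predicted, dtype=object)
    true = np.asarray(truth, dtype=object)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if pred.size == 0:
        raise ValueError("empty prediction/truth lists")
    p_pos, t_pos = pred == positive, true == positive
    return ConfusionCounts(
        tp=int(np.sum(p_pos & t_pos)),
        tn=int(np.sum(~p_pos & ~t_pos)),
        fp=int(np.sum(p_pos & ~t_pos)),
        fn=int(np.sum(~p_pos & t_pos)),
    )


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Acc, TPR, TNR and error rate; undefined ratios are None, never 0."""
    if c.total == 0:
        raise ValueError("metrics need at least one count")
    acc = (c.tp + c.tn) / c.total
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    tnr = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return {"acc": acc, "tpr": tpr, "tnr": tnr, "e": (c.fp + c.fn) / c.total}


# ---------------------------------------------------------------------------
# learner specification


@dataclass(frozen=True)
class LearnerSpec:
    """Everything needed to train one classifier inside a CV fold.

    ``classifier`` ∈ {dbn, svm, hybrid, rbm-svm, autoencoder-svm}.  The
    architecture string (e.g. "A-50-10-1") fixes hidden sizes and, for the
    DBN, the output layer; its hidden part also sizes the stacks behind
    rbm-svm and autoencoder-svm.  ``feature_k`` enables top-variance
    selection; ``selection_scope`` is "fold" (training folds only, the
    leakage-safe default) or "global".
    """

    classifier: str = "dbn"
    architecture: str = "A-50-10-1"
    train_config: TrainConfig = field(default_factory=TrainConfig)
    cd_config: CDConfig = field(default_factory=CDConfig)
    pretrain: bool = True
    encoding: OutputEncoding = field(default_factory=OutputEncoding)
    feature_k: int | None = None
    selection_scope: str = "fold"
    svm: SVMSpec = field(default_factory=SVMSpec)
    hybrid_layer: int | None = None  # default: last hidden layer

    def __post_init__(self) -> None:
        if self.classifier not in (
            "dbn", "svm", "hybrid", "rbm-svm", "autoencoder-svm"
        ):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.selection_scope not in ("fold", "global"):
            raise ValueError("selection_scope must be 'fold' or 'global'")


@dataclass
class MetricReport:
    """Per-fold and aggregate CV metrics for one learner."""

    k: int
    fold_metrics: list[dict[str, float | None]]
    fold_confusions: list[ConfusionCounts | None]
    mean: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("acc", "tpr", "tnr", "e"):
            vals = [fm[name] for fm in self.fold_metrics if fm[name] is not None]
            if not vals:
                continue
            arr = np.asarray(vals, dtype=float)
            self.mean[name] = float(arr.mean())
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            self.se[name] = sd / np.sqrt(len(arr))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tfold\tvalue\n")
            for f, fm in enumerate(self.fold_metrics, start=1):
                for name, val in fm.items():
                    v = "NA" if val is None else format(val, ".10g")
                    fh.write(f"{name}\t{f}\t{v}\n")
            for name in self.mean:
                fh.write(f"{name}\tmean\t{self.mean[name]:.10g}\n")
                fh.write(f"{name}\tse\t{self.se[name]:.10g}\n")

    def table(self) -> str:
        lines = ["metric   mean     se"]
        for name in ("acc", "tpr", "tnr", "e"):
            if name in self.mean:
                lines.append(f"{name:6s}  {self.mean[name]:.4f}  {self.se[name]:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# fold-level training


def _derive_seed(seed: int, *parts: int) -> int:
    mixed = np.random.SeedSequence([int(seed)] + [int(p) for p in parts])
    return int(mixed.generate_state(1)[0] % (2**31))


def _hidden_sizes(spec: LearnerSpec, input_size: int) -> tuple[list[int], int]:
    sizes = parse_architecture(spec.architecture, input_size)
    return sizes[1:-1], sizes[-1]


def fit_learner(spec: LearnerSpec, X: np.ndarray, labels, classes: list[str],
                seed: int):
    """Train the configured classifier on already-selected, scaled features.

    Returns a ``predict(X) -> labels`` closure; ``X`` must already be on the
    training scale (the caller handles selection and scaling so no test
    information leaks in).
    """
    labels = np.asarray(labels, dtype=object)
    hidden, output_size = _hidden_sizes(spec, X.shape[1])

    def dbn_network() -> NetworkModel:
        expected = spec.encoding.output_size(len(classes))
        if output_size != expected:
            raise ValueError(
                f"architecture output size {output_size} does not match "
                f"{spec.encoding.mode} encoding for {len(classes)} classes"
            )
        if spec.pretrain and hidden:
            cd = replace(spec.cd_config, seed=_derive_seed(seed, 1))
            stack = pretrain_stack(X, hidden, cd)
            net = init_from_pretrained(stack, output_size,
                                       seed=_derive_seed(seed, 2))
        else:
            net = init_random([X.shape[1], *hidden, output_size],
                              seed=_derive_seed(seed, 2))
        T = encode_targets(labels, classes, spec.encoding)
        tc = replace(spec.train_config, seed=_derive_seed(seed, 3))
        net, _ = train(net, X, T, tc, enc=spec.encoding)
        return net

    if spec.classifier == "dbn":
        net = dbn_network()

        def predict(Xt: np.ndarray) -> np.ndarray:
            out = forward_batch(net, Xt)[-1]
            if spec.encoding.mode == "single-node":
                idx = (out[:, 0] >= 0.5).astype(int)
            else:
                idx = np.argmax(out, axis=1)
            return np.asarray([classes[i] for i in idx], dtype=object)

        return predict

    if spec.classifier == "svm":
        extractor = RepresentationExtractor("passthrough")
    elif spec.classifier == "hybrid":
        extractor = RepresentationExtractor(
            "finetuned-dbn", dbn_network(), spec.hybrid_layer
        )
    elif spec.classifier == "rbm-svm":
        cd = replace(spec.cd_config, seed=_derive_seed(seed, 1))
        stack = pretrain_stack(X, hidden, cd)
        extractor = RepresentationExtractor(
            "pretrained-stack", stack, spec.hybrid_layer
        )
    else:  # autoencoder-svm
        cd = replace(spec.cd_config, seed=_derive_seed(seed, 1))
        stack = pretrain_stack(X, hidden, cd)
        ae = build_autoencoder(stack)
        tc = replace(spec.train_config, seed=_derive_seed(seed, 3))
        ae, _ = train_autoencoder(ae, X, tc)
        extractor = RepresentationExtractor("autoencoder", ae)

    h = train_hybrid(X, labels, extractor, spec.svm)
    return lambda Xt: predict_hybrid(h, Xt)


def cross_validate(
    learner_spec: LearnerSpec,
    ds: ExpressionDataset,
    k: int = 10,
    balance: bool = False,
    seed: int = 0,
    positive: str | None = None,
    folds: FoldAssignment | None = None,
) -> MetricReport:
    """k-fold cross-validated evaluation of one learner specification.

    Per fold: optional undersampling of the training portion, top-variance
    feature selection (per ``selection_scope``), min-max scaling fit on
    training data, full retraining, evaluation on the untouched held-out
    fold.  For binary tasks TPR/TNR treat ``positive`` (default: the
    lexicographically larger class) as the positive label; for three-class
    tasks only accuracy and error rate are reported per fold.
    Deterministic given ``seed``.
    """
    if not ds.labels:
        raise ValueError("cross-validation requires a labeled dataset")
    if k < 2:
        raise ValueError("k must be >= 2")
    classes = ds.classes
    binary = len(classes) == 2
    if positive is None and binary:
        positive = classes[1]
    if folds is None:
        folds = kfold_split(ds.n_samples, k, labels=ds.labels,
                            seed=_derive_seed(seed, 0))

    global_selection = None
    if learner_spec.feature_k is not None and learner_spec.selection_scope == "global":
        global_selection = select_top_variance(ds, learner_spec.feature_k).indices

    fold_metrics, fold_confusions = [], []
    for f in range(1, k + 1):
        tr_idx, te_idx = folds.train_indices(f), folds.test_indices(f)
        ds_train, ds_test = ds.subset_samples(tr_idx), ds.subset_samples(te_idx)
        if len(set(ds_train.labels)) < len(classes):
            raise ValueError(
                f"fold {f}: a class is absent from the training portion; "
                "use stratified folds or fewer folds"
            )
        if balance:
            ds_train = undersample(ds_train, seed=_derive_seed(seed, f, 1))
        if global_selection is not None:
            sel = global_selection
        elif learner_spec.feature_k is not None:
            sel = select_top_variance(ds_train, learner_spec.feature_k).indices
        else:
            sel = None
        Xtr, Xte = ds_train.expression, ds_test.expression
        if sel is not None:
            Xtr, Xte = Xtr[:, sel], Xte[:, sel]
        scaler = MinMaxScaler().fit(Xtr)
        Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)

        predict = fit_learner(learner_spec, Xtr, ds_train.labels, classes,
                              seed=_derive_seed(seed, f, 2))
        pred = predict(Xte)
        true = ds_test.label_array()
        if binary:
            c = confusion(pred, true, positive)
            fold_metrics.append(metrics(c))
            fold_confusions.append(c)
        else:
            acc = float(np.mean(pred == true))
            fold_metrics.append({"acc": acc, "tpr": None, "tnr": None,
                                 "e": 1.0 - acc})
            fold_confusions.append(None)

    return MetricReport(k=k, fold_metrics=fold_metrics,
                        fold_confusions=fold_confusions)
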