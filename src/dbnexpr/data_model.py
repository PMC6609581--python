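"""Expression-dataset container and the data-side operations of the pipeline.

The central object is :class:`ExpressionDataset`, a samples × genes matrix of
log-scale intensities with sample identifiers, gene identifiers and (optionally)
class labels.  Around it live the operations every downstream classifier needs:
loading delimited text in either orientation, attaching labels, log
transformation, top-variance feature selection, class-balancing undersampling
and (stratified) k-fold partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "FoldAssignment",
    "FeatureSelection",
    "load_expression_matrix",
    "save_expression_matrix",
    "load_label_table",
    "save_label_table",
    "attach_labels",
    "log_transform",
    "select_top_variance",
    "undersample",
    "kfold_split",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class ExpressionDataset:
    """Samples × genes expression matrix with identifiers and class labels.

    Parameters
    ----------
    expression
        Real matrix, one row per sample, one column per gene, log2-intensity
        units by convention.
    sample_ids, gene_ids
        Identifier lists matching the matrix axes; gene ids must be unique.
    labels
        One categorical class label per sample, or an empty list when the
        dataset is unlabeled.
    """

    expression: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        X = np.asarray(self.expression, dtype=float)
        object.__setattr__(self, "expression", X)
        if X.ndim != 2:
            raise ValueError("expression must be a 2-D matrix")
        if X.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"{X.shape[0]} matrix rows but {len(self.sample_ids)} sample ids"
            )
        if X.shape[1] != len(self.gene_ids):
            raise ValueError(
                f"{X.shape[1]} matrix columns but {len(self.gene_ids)} gene ids"
            )
        if self.labels and len(self.labels) != len(self.sample_ids):
            raise ValueError("labels must be empty or one per sample")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            raise ValueError(
                "duplicate gene ids: "
                + ", ".join(sorted(set(dupes[dupes.duplicated()])))
            )
        if not np.all(np.isfinite(X)):
            i, j = np.argwhere(~np.isfinite(X))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def classes(self) -> list[str]:
        """Distinct labels in sorted order (empty for unlabeled data)."""
        return sorted(set(self.labels))

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def subset_samples(self, indices: np.ndarray | list[int]) -> "ExpressionDataset":
        idx = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            expression=self.expression[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            labels=[self.labels[i] for i in idx] if self.labels else [],
        )

    def subset_genes(self, indices: np.ndarray | list[int]) -> "ExpressionDataset":
        idx = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            expression=self.expression[:, idx],
            sample_ids=list(self.sample_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            labels=list(self.labels),
        )


@dataclass(frozen=True)
class FoldAssignment:
    """Assignment of each sample to one of ``k`` disjoint folds (1-based)."""

    fold_index: np.ndarray  # int array, values in 1..k
    k: int

    def __post_init__(self) -> None:
        f = np.asarray(self.fold_index, dtype=int)
        object.__setattr__(self, "fold_index", f)
        if f.size and (f.min() < 1 or f.max() > self.k):
            raise ValueError("fold indices must lie in 1..k")
        sizes = np.bincount(f, minlength=self.k + 1)[1:]
        if sizes.size and sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes may differ by at most 1")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


@dataclass(frozen=True)
class FeatureSelection:
    """Ordered gene indices chosen by a selection criterion."""

    indices: np.ndarray
    criterion: str
    k: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selected indices must be unique")


# ---------------------------------------------------------------------------
# loading / saving


def load_expression_matrix(
    path,
    orientation: str = "samples-as-rows",
    delimiter: str = "\t",
) -> ExpressionDataset:
    """Read a delimited expression matrix into an (unlabeled) dataset.

    The first row and first column hold identifiers; the body must be fully
    numeric.  ``orientation`` names what the file's *rows* are: GEO
    series-matrix-style files store genes as rows and are transposed on load so
    the returned dataset is always samples × genes with identifiers preserved
    in file order.
    """
    if orientation not in ("samples-as-rows", "genes-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    # pandas mangles duplicate header names; check the raw header first so a
    # duplicated gene column is reported instead of silently renamed
    with open(path) as fh:
        header_ids = fh.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(header_ids)) != len(header_ids):
        seen: set[str] = set()
        dup = next(h for h in header_ids if h in seen or seen.add(h))
        raise ValueError(f"duplicate identifier {dup!r} in header of {path}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise ValueError("empty cell")
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"missing or non-numeric value at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r} in {path}"
                ) from None
    if orientation == "genes-as-rows":
        values = values.T
        sample_ids, gene_ids = col_ids, row_ids
    else:
        sample_ids, gene_ids = row_ids, col_ids
    return ExpressionDataset(values, sample_ids, gene_ids)


def save_expression_matrix(ds: ExpressionDataset, path, delimiter: str = "\t") -> None:
    """Write samples-as-rows delimited text at full float precision."""
    with open(path, "w") as fh:
        fh.write("sample_id" + delimiter + delimiter.join(ds.gene_ids) + "\n")
        for i, sid in enumerate(ds.sample_ids):
            row = delimiter.join(format(v, ".17g") for v in ds.expression[i])
            fh.write(sid + delimiter + row + "\n")


def load_label_table(path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>label`` table into a mapping."""
    df = pd.read_csv(path, sep=delimiter, header=None, names=["sample_id", "label"],
                     dtype=str, comment="#")
    return dict(zip(df["sample_id"], df["label"]))


def save_label_table(ds: ExpressionDataset, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for sid, lab in zip(ds.sample_ids, ds.labels):
            fh.write(f"{sid}{delimiter}{lab}\n")


def attach_labels(ds: ExpressionDataset, label_table: dict[str, str]) -> ExpressionDataset:
    """Attach class labels, aligned to sample order.

    Every sample id must be present in the mapping and the labeled dataset
    must contain two or three classes.
    """
    missing = [s for s in ds.sample_ids if s not in label_table]
    if missing:
        raise ValueError("unmapped sample ids: " + ", ".join(missing))
    labels = [str(label_table[s]) for s in ds.sample_ids]
    n_classes = len(set(labels))
    if n_classes < 2:
        raise ValueError("labeled dataset must contain at least 2 classes")
    if n_classes > 3:
        raise ValueError(f"at most 3 classes supported, got {n_classes}")
    return replace(ds, labels=labels)


# ---------------------------------------------------------------------------
# transforms


def log_transform(ds: ExpressionDataset) -> ExpressionDataset:
    """Replace every value v by log2(v + 1); requires nonnegative input."""
    if np.any(ds.expression < 0):
        i, j = np.argwhere(ds.expression < 0)[0]
        raise ValueError(
            f"negative value at sample {ds.sample_ids[i]!r}, "
            f"gene {ds.gene_ids[j]!r}; log transform needs v >= 0"
        )
    return replace(ds, expression=np.log2(ds.expression + 1.0))


def select_top_variance(ds: ExpressionDataset, k: int) -> FeatureSelection:
    """Indices of the ``k`` genes with the largest sample variance.

    Ordered descending by variance; ties broken by ascending gene index so
    the selection is reproducible.  ``k`` past the gene count selects all.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    variances = ds.expression.var(axis=0, ddof=1)
    # stable sort on -variance keeps ascending index order within ties
    order = np.argsort(-variances, kind="stable")
    k_eff = min(k, ds.n_genes)
    return FeatureSelection(indices=order[:k_eff], criterion="variance", k=k)


def undersample(ds: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Balance classes by random undersampling without replacement.

    Every class is reduced to n_< , the size of the smallest class; samples
    of the smallest class are all retained and sample order is preserved
    within the retained set.  Deterministic given ``seed``.
    """
    if len(ds.classes) < 2:
        raise ValueError("undersampling needs at least 2 classes")
    rng = np.random.default_rng(seed)
    labels = ds.label_array()
    counts = {c: int(np.sum(labels == c)) for c in ds.classes}
    n_min = min(counts.values())
    keep: list[int] = []
    for c in ds.classes:
        members = np.flatnonzero(labels == c)
        if len(members) > n_min:
            members = rng.choice(members, size=n_min, replace=False)
        keep.extend(members.tolist())
    keep_sorted = np.sort(np.asarray(keep, dtype=int))
    return ds.subset_samples(keep_sorted)


def kfold_split(
    n: int,
    k: int,
    labels=None,
    seed: int = 0,
    stratified: bool = True,
) -> FoldAssignment:
    """Randomly partition ``n`` samples into ``k`` folds of near-equal size.

    With ``labels`` given and ``stratified`` true (the default), each class is
    shuffled and dealt round-robin across folds so per-class proportions are
    preserved as closely as integer counts allow.  Deterministic given seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    assignment = np.zeros(n, dtype=int)
    if labels is not None and stratified:
        labels = np.asarray(labels, dtype=object)
        # rotate the starting fold between classes so small classes do not
        # all pile their remainders into fold 1
        start = 0
        for c in sorted(set(labels.tolist())):
            members = rng.permutation(np.flatnonzero(labels == c))
            for pos, idx in enumerate(members):
                assignment[idx] = (start + pos) % k + 1
            start += len(members)
        # round-robin keeps global fold sizes within 1 of each other only if
        # the starts chain; the rotation above guarantees that
    else:
        perm = rng.permutation(n)
        for pos, idx in enumerate(perm):
            assignment[idx] = pos % k + 1
    return FoldAssignment(fold_index=assignment, k=k)


# ---------------------------------------------------------------------------
# versioned dataset container

_DATASET_FORMAT_VERSION = 1


def save_dataset(ds: ExpressionDataset, path) -> None:
    """Serialize matrix, ids and labels to a versioned .npz container.

    Round-trips values bit-exactly (float64 arrays stored as-is).
    """
    np.savez(
        path,
        format_version=np.int64(_DATASET_FORMAT_VERSION),
        expression=ds.expression,
        sample_ids=np.asarray(ds.sample_ids, dtype=object),
        gene_ids=np.asarray(ds.gene_ids, dtype=object),
        labels=np.asarray(ds.labels, dtype=object),
    )


def load_dataset(path) -> ExpressionDataset:
    with np.load(path, allow_pickle=True) as z:
        version = int(z["format_version"])
        if version != _DATASET_FORMAT_VERSION:
            raise ValueError(f"unsupported dataset container version {version}")
        return ExpressionDataset(
            expression=z["expression"],
            sample_ids=[str(s) for s in z["sample_ids"]],
            gene_ids=[str(g) for g in z["gene_ids"]],
            labels=[str(l) for l in z["labels"]] if z["labels"].size else [],
        )
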