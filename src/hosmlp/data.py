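"""Tabular dataset handling: CSV ingestion, min-max scaling, stratified
splitting, one-hot targets, and a synthetic two-class-style generator.

The synthetic generator emulates small medical-style benchmark tables:
a few hundred samples, a handful of numeric features, balanced classes,
Gaussian class clusters with a controllable separation (in within-class
standard-deviation units) and a controllable fraction of flipped labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "DatasetError",
    "MinMaxRecord",
    "SplitDataset",
    "StratificationError",
    "make_synthetic",
    "minmax_scale",
    "one_hot",
    "read_csv_dataset",
    "stratified_split",
    "write_csv_dataset",
]

RngLike = Union[int, np.random.Generator, None]


class DatasetError(ValueError):
    """The table violates a dataset invariant (missing values, one class...)."""


class StratificationError(ValueError):
    """A class is too small to be split at the requested fraction."""


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class Dataset:
    """A numeric feature matrix with 0-based integer class labels."""

    features: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.shape[0] != self.labels.shape[0]:
            raise DatasetError(
                f"{self.features.shape[0]} feature rows vs {self.labels.shape[0]} labels"
            )
        if not np.all(np.isfinite(self.features)):
            raise DatasetError("features contain missing or non-finite values")
        k = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= k):
            raise DatasetError("labels fall outside [0, n_classes)")
        if len(self.feature_names) != self.features.shape[1]:
            raise DatasetError("feature_names length does not match feature columns")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


@dataclass
class SplitDataset:
    """A stratified train/test partition of one dataset."""

    train: Dataset
    test: Dataset
    train_fraction: float


@dataclass
class MinMaxRecord:
    """Per-feature minima and maxima fixing an affine [0, 1] rescaling.

    Storing the fit allows the identical transform to be replayed on new
    data; values outside the fitted range map outside [0, 1] (no clamping).
    Constant features (zero range) map to 0.
    """

    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        rng = self.maxs - self.mins
        safe = np.where(rng > 0, rng, 1.0)
        out = (X - self.mins) / safe
        return np.where(rng > 0, out, 0.0)

    def inverse(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        rng = self.maxs - self.mins
        return np.where(rng > 0, X * rng + self.mins, self.mins)


def read_csv_dataset(path, label_column: Union[str, int] = -1) -> Dataset:
    """Read a headered CSV with numeric features and one label column.

    Labels are mapped to 0-based indices in order of first appearance; the
    mapping is preserved in ``class_names``.
    """
    frame = pd.read_csv(path)
    if isinstance(label_column, int):
        label_name = frame.columns[label_column]
    else:
        if label_column not in frame.columns:
            raise DatasetError(f"label column {label_column!r} not found")
        label_name = label_column
    raw_labels = frame[label_name]
    if raw_labels.isna().any():
        row = int(raw_labels.isna().idxmax())
        raise DatasetError(f"missing label at row {row}")
    feat_frame = frame.drop(columns=[label_name])
    for col in feat_frame.columns:
        numeric = pd.to_numeric(feat_frame[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise DatasetError(f"non-numeric feature value at row {row}, column {col!r}")
        feat_frame[col] = numeric
    class_names: list[str] = []
    index: dict[str, int] = {}
    labels = np.empty(len(frame), dtype=int)
    for i, lab in enumerate(raw_labels.astype(str)):
        if lab not in index:
            index[lab] = len(class_names)
            class_names.append(lab)
        labels[i] = index[lab]
    if len(class_names) < 2:
        raise DatasetError("dataset must contain at least 2 classes")
    return Dataset(
        features=feat_frame.to_numpy(dtype=float),
        labels=labels,
        class_names=class_names,
        feature_names=list(feat_frame.columns),
    )


def write_csv_dataset(data: Dataset, path, label_column: str = "label") -> None:
    """Write a dataset as headered CSV with the label column last."""
    frame = pd.DataFrame(data.features, columns=data.feature_names)
    frame[label_column] = [data.class_names[i] for i in data.labels]
    frame.to_csv(path, index=False, float_format="%.10g")


def minmax_scale(
    data: Dataset, record: Optional[MinMaxRecord] = None
) -> tuple[Dataset, MinMaxRecord]:
    """Rescale every feature to [0, 1] via (x - min) / (max - min).

    When ``record`` is given, its stored minima/maxima are applied instead of
    refitting, so a transform fitted on training data can be replayed on test
    data.
    """
    if record is None:
        record = MinMaxRecord(
            mins=data.features.min(axis=0), maxs=data.features.max(axis=0)
        )
    scaled = Dataset(
        features=record.transform(data.features),
        labels=data.labels.copy(),
        class_names=list(data.class_names),
        feature_names=list(data.feature_names),
    )
    return scaled, record


def stratified_split(
    data: Dataset, train_fraction: float, rng: RngLike = None
) -> SplitDataset:
    """Random per-class partition preserving class proportions.

    Each class contributes ``round(train_fraction * class_size)`` samples
    (round half up) to the training set and the rest to the test set.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    gen = _as_rng(rng)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in range(data.n_classes):
        members = np.flatnonzero(data.labels == c)
        if members.size < 2:
            raise StratificationError(
                f"class {data.class_names[c]!r} has {members.size} sample(s); "
                "stratified splitting needs at least 2 per class"
            )
        n_train = int(np.floor(train_fraction * members.size + 0.5))  # round half up
        if n_train == 0 or n_train == members.size:
            raise StratificationError(
                f"class {data.class_names[c]!r} would be empty on one side of the "
                f"split at fraction {train_fraction}"
            )
        perm = gen.permutation(members)
        train_idx.append(np.sort(perm[:n_train]))
        test_idx.append(np.sort(perm[n_train:]))
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))

    def subset(idx: np.ndarray) -> Dataset:
        return Dataset(
            features=data.features[idx],
            labels=data.labels[idx],
            class_names=list(data.class_names),
            feature_names=list(data.feature_names),
        )

    return SplitDataset(train=subset(tr), test=subset(te), train_fraction=train_fraction)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """One-hot target matrix; row i has a single 1 at column labels[i]."""
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError("label out of range for one-hot encoding")
    return np.eye(n_classes, dtype=float)[labels]


def make_synthetic(
    n_samples: int = 300,
    n_features: int = 4,
    n_classes: int = 2,
    separation: float = 6.0,
    label_noise: float = 0.0,
    seed: Optional[int] = None,
) -> Dataset:
    """Gaussian-cluster classification table with controllable difficulty.

    Each class is a unit-variance spherical Gaussian; class centers are
    placed so that every pair is ``separation`` standard deviations apart
    (along mutually orthogonal random directions when the feature space
    allows it).  Classes are balanced up to rounding.  A ``label_noise``
    fraction of samples has its label flipped to a uniformly chosen other
    class, so ``label_noise = 0.5`` with two classes destroys essentially
    all label information.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n_samples < 2 * n_classes:
        raise ValueError("n_samples must be at least 2 per class")
    if not 0.0 <= label_noise <= 1.0:
        raise ValueError("label_noise must lie in [0, 1]")
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    gen = _as_rng(seed)

    if n_classes <= n_features:
        # orthonormal directions: pairwise center distance is exactly
        # separation after scaling by separation / sqrt(2)
        basis, _ = np.linalg.qr(gen.standard_normal((n_features, n_classes)))
        centers = (separation / np.sqrt(2.0)) * basis.T
    else:
        dirs = gen.standard_normal((n_classes, n_features))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        centers = (separation / np.sqrt(2.0)) * dirs

    base = n_samples // n_classes
    counts = np.full(n_classes, base)
    counts[: n_samples - base * n_classes] += 1
    labels = np.repeat(np.arange(n_classes), counts)
    features = centers[labels] + gen.standard_normal((n_samples, n_features))

    order = gen.permutation(n_samples)
    features, labels = features[order], labels[order]

    n_flip = int(round(label_noise * n_samples))
    if n_flip:
        flip = gen.choice(n_samples, size=n_flip, replace=False)
        offsets = gen.integers(1, n_classes, size=n_flip)
        labels = labels.copy()
        labels[flip] = (labels[flip] + offsets) % n_classes

    return Dataset(
        features=features,
        labels=labels,
        class_names=[f"class_{c}" for c in range(n_classes)],
        feature_names=[f"f{j}" for j in range(n_features)],
    )
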