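"""Tabular case data: loading, synthesis, and stratified resampling.

The prediction target throughout the package is a binary outcome per
delivery record (1 = postpartum hemorrhage present). Real cohorts of this
kind are rarely shareable, so :func:`generate_pph_like` emulates their
shape — a wide numeric feature matrix, strong class imbalance, and a small
planted subset of genuinely informative features — which makes wrapper
feature selection and classifier performance measurable against known
ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.model_selection import train_test_split as _sk_split

__all__ = [
    "Dataset",
    "SynthConfig",
    "FoldAssignment",
    "load_csv",
    "write_csv",
    "generate_pph_like",
    "stratified_kfold",
    "train_test_split",
]


@dataclass(frozen=True)
class Dataset:
    """A numeric feature matrix with binary outcome labels.

    Rows are delivery records, columns are (unitless) clinical
    measurements. Labels are 0/1 with 1 marking the positive (hemorrhage)
    class. Invariants are checked at construction: no missing or
    non-finite entries, strictly binary labels, consistent shapes.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
            raise ValueError("features must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain missing or non-finite values")
        if y.shape != (X.shape[0],):
            raise ValueError("labels length must match number of rows")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must contain only 0 and 1")
        names = tuple(str(n) for n in self.feature_names)
        if len(names) != X.shape[1]:
            raise ValueError("feature_names length must match number of columns")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y.astype(np.int64))
        object.__setattr__(self, "feature_names", names)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())

    def subset_rows(self, idx: np.ndarray) -> "Dataset":
        return Dataset(self.features[idx], self.labels[idx], self.feature_names)

    def subset_columns(self, mask: np.ndarray) -> "Dataset":
        mask = np.asarray(mask, dtype=bool)
        names = tuple(n for n, m in zip(self.feature_names, mask) if m)
        return Dataset(self.features[:, mask], self.labels, names)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.feature_names == other.feature_names
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.features, other.features)
        )


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort generator.

    ``effect_size`` is the mean shift of informative features in the
    positive class, expressed in units of ``noise_sd``. Defaults mirror
    the cohort shape the package targets: ~11,000 records, 149 features,
    prevalence 1042/11000 ≈ 9.47%, 15 informative features.
    """

    n_samples: int = 11000
    n_features: int = 149
    n_informative: int = 15
    prevalence: float = 1042 / 11000
    effect_size: float = 1.5
    noise_sd: float = 1.0
    seed: int = 0
    fixed_count: bool = False  # exact round(n·prevalence) positives instead of Bernoulli draws

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_features <= 0 or self.n_informative <= 0:
            raise ValueError("sizes must be positive")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")


@dataclass(frozen=True)
class FoldAssignment:
    """A stratified k-fold partition of sample indices."""

    fold_index: np.ndarray
    k: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.fold_index, dtype=np.int64)
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if idx.min() < 0 or idx.max() >= self.k:
            raise ValueError("fold indices must lie in 0..k-1")
        object.__setattr__(self, "fold_index", idx)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)

    def to_json(self) -> str:
        return json.dumps({"k": self.k, "fold_index": self.fold_index.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "FoldAssignment":
        obj = json.loads(text)
        return cls(np.asarray(obj["fold_index"], dtype=np.int64), int(obj["k"]))


def load_csv(path: str | Path, label_column: str = "pph") -> Dataset:
    """Read a Dataset from a CSV file with a header row.

    All non-label columns must be numeric and finite; the label column
    must contain only 0 and 1. Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError("empty table")
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found")
    labels = df[label_column].to_numpy()
    feats = df.drop(columns=[label_column])
    values = feats.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.all(np.isfinite(values.astype(float))):
        raise ValueError("non-numeric or missing feature cell")
    return Dataset(values.astype(float), labels, tuple(feats.columns))


def write_csv(dataset: Dataset, path: str | Path, label_column: str = "pph") -> Path:
    """Write a Dataset to CSV so that :func:`load_csv` inverts it."""
    path = Path(path)
    df = pd.DataFrame(dataset.features, columns=list(dataset.feature_names))
    df[label_column] = dataset.labels
    df.to_csv(path, index=False)
    return path


def generate_pph_like(config: SynthConfig) -> tuple[Dataset, np.ndarray]:
    """Generate an imbalanced cohort with a planted informative subset.

    Labels are Bernoulli(prevalence) (or an exact shuffled count in
    ``fixed_count`` mode). Informative columns are drawn
    Normal(effect_size·noise_sd·label, noise_sd²); the rest are pure
    Normal(0, noise_sd²) noise. Returns the dataset and the sorted index
    array of the truly informative columns.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_features
    if config.fixed_count:
        n_pos = int(round(n * config.prevalence))
        labels = np.zeros(n, dtype=np.int64)
        labels[rng.permutation(n)[:n_pos]] = 1
    else:
        labels = (rng.random(n) < config.prevalence).astype(np.int64)
    informative = np.sort(rng.choice(p, size=config.n_informative, replace=False))
    X = rng.normal(0.0, config.noise_sd, size=(n, p))
    shift = config.effect_size * config.noise_sd
    X[:, informative] += shift * labels[:, None]
    names = tuple(f"f{j:03d}" for j in range(p))
    return Dataset(X, labels, names), informative


def stratified_kfold(labels: np.ndarray, k: int, seed: int = 0) -> FoldAssignment:
    """Partition samples into k mutually exclusive, stratified folds.

    Fold sizes differ by at most one and each fold's class balance
    matches the global balance as closely as the counts allow.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    counts = np.bincount(labels.astype(int), minlength=2)
    if counts.min() < k:
        raise ValueError(f"k={k} exceeds the minority-class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.empty(labels.shape[0], dtype=np.int64)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros_like(labels)[:, None], labels)):
        fold_index[test_idx] = f
    return FoldAssignment(fold_index, k)


def train_test_split(
    dataset: Dataset, test_fraction: float = 0.3, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Stratified disjoint train/test split of a Dataset."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    idx = np.arange(dataset.n_samples)
    train_idx, test_idx = _sk_split(
        idx,
        test_size=test_fraction,
        random_state=seed,
        stratify=dataset.labels,
        shuffle=True,
    )
    return dataset.subset_rows(np.sort(train_idx)), dataset.subset_rows(np.sort(test_idx))
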