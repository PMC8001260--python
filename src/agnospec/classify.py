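"""PCA + multinomial logistic regression under stratified k-fold CV.

The statistical protocol: flattened feature images are reduced with an
N-component PCA fitted on the training rows of each fold only, both
train and test rows are projected, and a multinomial logistic regression
(L2 penalty at default strength) is fitted on the training scores and
scored on the held-out scores.  Folds come from a seeded stratified
k-fold split; sweeping the number of components reuses one set of fold
assignments so the accuracy curve varies only with dimensionality.

Each physical sample contributes two data points (even- and odd-mass
halves).  Because those halves are near-duplicates, ``grouped=True``
keeps both in the same fold to rule out leakage; the default is
ungrouped stratification over data points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .featurize import FeatureImage, HistogramConfig, featurize_spectrum, flatten
from .peaklist import Spectrum, filter_peaks, split_parity

__all__ = [
    "LabeledDataset",
    "CVResult",
    "build_dataset",
    "fit_feature_pca",
    "make_folds",
    "cross_validate",
    "sweep_components",
    "permutation_baseline",
]


@dataclass
class LabeledDataset:
    """Stacked flattened feature vectors with labels and sample grouping."""

    features: np.ndarray  # (n_points, n_features)
    labels: np.ndarray  # (n_points,) class names
    groups: np.ndarray  # (n_points,) sample ids

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.groups = np.asarray(self.groups)
        n = self.features.shape[0]
        if not (len(self.labels) == len(self.groups) == n):
            raise ValueError("features, labels and groups must align")
        _, counts = np.unique(self.groups, return_counts=True)
        if counts.max(initial=0) > 2:
            raise ValueError("a sample may contribute at most two points")

    def __len__(self) -> int:
        return self.features.shape[0]


@dataclass
class CVResult:
    """Per-fold and summary accuracy for one PCA dimensionality."""

    n_components: int
    fold_accuracies: list[float]
    seed: int
    mean_accuracy: float = field(init=False)
    std_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        acc = np.asarray(self.fold_accuracies, dtype=float)
        if np.any(acc < 0) or np.any(acc > 1):
            raise ValueError("fold accuracies must lie in [0, 1]")
        self.mean_accuracy = float(acc.mean())
        self.std_accuracy = float(acc.std())


def build_dataset(
    spectra: Sequence[Spectrum],
    cfg: HistogramConfig = HistogramConfig(),
    snr_min: float = 2.0,
) -> LabeledDataset:
    """Filter, parity-split and featurize labeled spectra into a dataset.

    Every input spectrum must carry a class label; each yields two rows
    (even and odd nominal-mass halves).
    """
    feats, labels, groups = [], [], []
    for s in spectra:
        if s.label is None:
            raise ValueError(f"spectrum {s.sample_id!r} has no class label")
        s = filter_peaks(s, cfg.mz_range[0], cfg.mz_range[1], snr_min)
        for half in split_parity(s):
            feats.append(flatten(featurize_spectrum(half, cfg)))
            labels.append(s.label)
            groups.append(s.sample_id)
    return LabeledDataset(np.vstack(feats), np.array(labels), np.array(groups))


def fit_feature_pca(train: np.ndarray, n_components: int) -> PCA:
    """Centered PCA fitted on training rows only (no per-feature scaling)."""
    train = np.asarray(train, dtype=float)
    max_rank = min(train.shape[0] - 1, train.shape[1])
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds max usable rank {max_rank}"
        )
    return PCA(n_components=n_components, svd_solver="full").fit(train)


def make_folds(
    ds: LabeledDataset, k: int = 5, seed: int = 0, grouped: bool = False
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold assignments, optionally group-aware."""
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(ds.labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= k={k} members")
    if grouped:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(ds.features, ds.labels, groups=ds.groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(ds.features, ds.labels)
    return [(tr.copy(), te.copy()) for tr, te in split]


def _fold_accuracy(
    ds: LabeledDataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    n_components: int,
) -> float:
    pca = fit_feature_pca(ds.features[train_idx], n_components)
    z_train = pca.transform(ds.features[train_idx])
    z_test = pca.transform(ds.features[test_idx])
    clf = LogisticRegression(max_iter=5000)
    clf.fit(z_train, ds.labels[train_idx])
    return float(np.mean(clf.predict(z_test) == ds.labels[test_idx]))


def cross_validate(
    ds: LabeledDataset,
    n_components: int,
    k: int = 5,
    seed: int = 0,
    grouped: bool = False,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVResult:
    """Stratified k-fold CV accuracy at one PCA dimensionality.

    PCA is refitted inside every fold on the training rows only.
    Accuracy is micro-averaged over each fold's test points.  Explicit
    ``folds`` may be passed to reuse assignments across calls.
    """
    if folds is None:
        folds = make_folds(ds, k=k, seed=seed, grouped=grouped)
    accs = [_fold_accuracy(ds, tr, te, n_components) for tr, te in folds]
    return CVResult(n_components=n_components, fold_accuracies=accs, seed=seed)


def sweep_components(
    ds: LabeledDataset,
    component_grid: Sequence[int],
    k: int = 5,
    seed: int = 0,
    grouped: bool = False,
) -> list[CVResult]:
    """CV accuracy across a grid of PCA dimensionalities.

    One set of fold assignments is drawn up front and reused for every
    grid value, so the curve varies only with dimensionality.
    """
    grid = list(component_grid)
    if not grid:
        raise ValueError("component grid must be non-empty")
    if grid != sorted(grid):
        raise ValueError("component grid must be ascending")
    folds = make_folds(ds, k=k, seed=seed, grouped=grouped)
    return [
        cross_validate(ds, n, k=k, seed=seed, grouped=grouped, folds=folds)
        for n in grid
    ]


def permutation_baseline(
    ds: LabeledDataset,
    n_components: int,
    k: int = 5,
    seed: int = 0,
    n_permutations: int = 3,
) -> list[float]:
    """Mean CV accuracies after seeded random label permutations.

    Destroying the label-feature association should drive accuracy to
    the majority-class rate; this is the negative control for the CV
    protocol.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(ds))
        shuffled = LabeledDataset(ds.features, ds.labels[perm], ds.groups)
        out.append(
            cross_validate(shuffled, n_components, k=k, seed=seed).mean_accuracy
        )
    return out
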