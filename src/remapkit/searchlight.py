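"""Cross-validated environment decoding in local voxel neighborhoods.

A classifier is trained to tell the four retrieval environments apart from
single-trial voxel patterns inside a small ellipsoidal neighborhood around
each voxel (31 voxels for an interior center by default).  Training uses the
correct trials of one block half per city and testing the other half's
trials, then the halves swap; the two folds' confusion counts are pooled.
Per-center accuracy maps feed the group inference stage; the pooled confusion
table supports the interference analyses (how often interference-city trials
are labeled as one of the similar cities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import CITIES, PatternDataset

__all__ = [
    "Neighborhood",
    "ConfusionTable",
    "SearchlightResult",
    "make_neighborhoods",
    "split_half_folds",
    "balance_training",
    "classify_neighborhood",
    "run_searchlight",
    "misclassification_rate",
    "behavior_classifier_correlation",
]

# Semi-axes (voxel units) of the searchlight ellipsoid.  On an unmasked grid
# an interior center collects exactly 31 lattice points: 13 in the center
# plane and 9 in each adjacent plane.  With anisotropic 1.6 x 1.6 x 2 mm
# voxels these axes (3.2, 3.2, 3 mm) are near-spherical in scanner space.
DEFAULT_SEMI_AXES = (2.0, 2.0, 1.5)


@dataclass(frozen=True)
class Neighborhood:
    """A searchlight neighborhood: center voxel plus member voxel indices."""

    center: int
    members: np.ndarray

    def __post_init__(self) -> None:
        members = np.asarray(self.members, dtype=int)
        if self.center not in members:
            raise ValueError("neighborhood center must be among its members")
        if len(np.unique(members)) != len(members):
            raise ValueError("neighborhood members must be unique")
        object.__setattr__(self, "members", members)

    @property
    def size(self) -> int:
        return len(self.members)


def make_neighborhoods(
    voxel_coords: np.ndarray,
    semi_axes: tuple[float, float, float] = DEFAULT_SEMI_AXES,
    target_size: int = 31,
    voxel_size_mm: tuple[float, float, float] | None = None,
) -> list[Neighborhood]:
    """One ellipsoidal neighborhood per in-mask voxel.

    ``voxel_coords`` holds the integer grid coordinates of the in-mask voxels
    (the searchlight domain); members are the in-mask voxels inside the
    ellipsoid centered on each voxel.  ``semi_axes`` are in voxel units
    unless ``voxel_size_mm`` is given, in which case they are interpreted in
    millimeters.  ``target_size`` documents the intended interior count and
    is validated against the default axes; edge centers may collect fewer.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    coords = np.asarray(voxel_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("voxel_coords must be (n_voxels, 3)")
    if coords.shape[0] == 0:
        raise ValueError("empty mask")
    axes = np.asarray(semi_axes, dtype=float)
    if voxel_size_mm is not None:
        coords = coords * np.asarray(voxel_size_mm, dtype=float)
    # normalized squared distances, (centers, voxels)
    d2 = np.zeros((coords.shape[0], coords.shape[0]))
    for k in range(3):
        diff = coords[:, k][:, None] - coords[:, k][None, :]
        d2 += (diff / axes[k]) ** 2
    inside = d2 <= 1.0 + 1e-9
    return [
        Neighborhood(center=i, members=np.flatnonzero(inside[i]))
        for i in range(coords.shape[0])
    ]


@dataclass
class Fold:
    """One train/test split: train on one block half, test on the other."""

    train: np.ndarray  # trial indices (correct trials of the training half)
    test: np.ndarray  # trial indices (all trials of the testing half)
    train_half: str


def split_half_folds(dataset: PatternDataset) -> list[Fold]:
    """Two folds: train on all A halves / test on B, then the reverse.

    Only correct trials enter training; every trial of the held-out half is
    scored at test (incorrect trials are flagged in the metadata and can be
    excluded downstream).  Raises if any city lacks correct trials in either
    half, naming the city.
    """
    for city in CITIES:
        for half in ("A", "B"):
            idx = dataset.trial_indices(city=city, block_half=half, correct=True)
            if len(idx) == 0:
                raise ValueError(
                    f"City {city} has no correct trials in block half {half}"
                )
    folds = []
    for train_half, test_half in (("A", "B"), ("B", "A")):
        train = dataset.trial_indices(block_half=train_half, correct=True)
        test = dataset.trial_indices(block_half=test_half)
        folds.append(Fold(train=train, test=test, train_half=train_half))
    return folds


def balance_training(
    labels: np.ndarray, indices: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Random per-city subset so every city contributes equally many trials.

    ``labels`` are city labels aligned with ``indices``; each city is
    downsampled without replacement to the minimum per-city count.
    """
    labels = np.asarray(labels)
    indices = np.asarray(indices)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cities, counts = np.unique(labels, return_counts=True)
    if np.any(counts == 0) or len(cities) == 0:
        raise ValueError("every class needs at least one training trial")
    n_min = int(counts.min())
    keep = []
    for c in cities:
        pool = indices[labels == c]
        keep.append(rng.choice(pool, size=n_min, replace=False))
    return np.sort(np.concatenate(keep))


@dataclass
class ConfusionTable:
    """4x4 confusion counts: rows = true city, columns = predicted city."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros((4, 4), dtype=int))
    degenerate: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (4, 4) or np.any(c < 0):
            raise ValueError("confusion counts must be a nonnegative 4x4 table")
        self.counts = c

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            counts=self.counts + other.counts,
            degenerate=self.degenerate or other.degenerate,
        )

    @property
    def overall_accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else np.nan

    def per_city_accuracy(self) -> np.ndarray:
        row_sums = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                row_sums > 0, np.diag(self.counts) / row_sums, np.nan
            )


def misclassification_rate(
    conf: ConfusionTable, source: int, targets: tuple[int, ...],
    of_errors_only: bool = False,
) -> float:
    """Fraction of ``source``-city trials labeled as any city in ``targets``.

    By default the denominator is all tested source-city trials; with
    ``of_errors_only`` it is only the misclassified ones.
    """
    row = conf.counts[source - 1]
    num = sum(int(row[t - 1]) for t in targets)
    denom = int(row.sum())
    if of_errors_only:
        denom -= int(row[source - 1])
    if denom == 0:
        raise ValueError(f"no (counted) City {source} trials in the confusion table")
    return num / denom


def _make_model(model: str, seed: int | None):
    from sklearn.linear_model import LogisticRegression
    from sklearn.neural_network import MLPClassifier

    if model == "logistic":
        return LogisticRegression(max_iter=1000)
    if model == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(24, 24, 24),
            max_iter=800,
            random_state=seed if seed is not None else 0,
        )
    raise ValueError(f"unknown model {model!r}")


def classify_neighborhood(
    dataset: PatternDataset,
    neighborhood: Neighborhood | np.ndarray,
    folds: list[Fold] | None = None,
    model: str = "logistic",
    balanced: bool = False,
    seed: int | None = None,
    shuffle_rng: np.random.Generator | None = None,
) -> ConfusionTable:
    """Train/test the environment classifier on one neighborhood's voxels.

    Pools confusion counts over both block-half folds.  ``balanced`` equates
    per-city training counts by random subsampling (seeded).  A training set
    whose features are all constant marks the table degenerate (zero counts)
    instead of failing.  ``shuffle_rng``, if given, permutes training labels
    within each fold — the label-shuffled null used for calibration.
    """
    members = (
        neighborhood.members
        if isinstance(neighborhood, Neighborhood)
        else np.asarray(neighborhood, dtype=int)
    )
    if folds is None:
        folds = split_half_folds(dataset)
    labels = np.array([t.city for t in dataset.meta])
    X = dataset.matrix[:, members]
    rng = np.random.default_rng(seed)
    pooled = ConfusionTable()
    for fold in folds:
        train_idx = fold.train
        if balanced:
            train_idx = balance_training(labels[train_idx], train_idx, seed=rng)
        y_train = labels[train_idx]
        if len(np.unique(y_train)) < 2:
            raise ValueError("training fold must contain at least 2 classes")
        X_train = X[train_idx]
        if np.allclose(X_train.std(axis=0), 0.0):
            return ConfusionTable(degenerate=True)
        if shuffle_rng is not None:
            y_train = shuffle_rng.permutation(y_train)
        clf = _make_model(model, seed)
        clf.fit(X_train, y_train)
        scores = clf.predict_proba(X[fold.test])
        # ties resolve to the lowest city index (classes_ is sorted)
        pred = clf.classes_[np.argmax(scores, axis=1)]
        counts = np.zeros((4, 4), dtype=int)
        for true, p in zip(labels[fold.test], pred):
            counts[true - 1, p - 1] += 1
        pooled = pooled + ConfusionTable(counts=counts)
    return pooled


@dataclass
class SearchlightResult:
    """Per-center accuracies plus the confusion table pooled over centers."""

    neighborhoods: list[Neighborhood]
    accuracy: np.ndarray  # (n_centers,)
    per_city_accuracy: np.ndarray  # (n_centers, 4)
    pooled: ConfusionTable

    def accuracy_map(self, dataset: PatternDataset, fill: float = np.nan) -> np.ndarray:
        """Project per-center accuracy back onto the dataset's voxel grid."""
        vol = np.full(dataset.grid_shape(), fill)
        for nb, acc in zip(self.neighborhoods, self.accuracy):
            # neighborhoods index the searchlight-domain voxels of `dataset`
            x, y, z = dataset.voxel_coords[nb.center]
            vol[x, y, z] = acc
        return vol


def run_searchlight(
    dataset: PatternDataset,
    neighborhoods: list[Neighborhood] | None = None,
    model: str = "logistic",
    balanced: bool = False,
    seed: int | None = None,
    roi_label: int | None = None,
    shuffle_rng: np.random.Generator | None = None,
) -> SearchlightResult:
    """Classify every neighborhood; restricts to ROI voxels if requested.

    When ``neighborhoods`` is None they are built over the dataset's in-mask
    (ROI-labeled) voxels with the default 31-voxel ellipsoid.  Returns
    per-center overall and per-city accuracies and the pooled confusion.
    NOTE: when ``roi_label`` is given the dataset is first restricted to
    those voxels, so neighborhood indices refer to the restricted dataset.
    """
    if roi_label is not None or np.any(dataset.roi_labels == 0):
        dataset = dataset.subset_voxels(dataset.roi_voxels(roi_label))
    if neighborhoods is None:
        neighborhoods = make_neighborhoods(dataset.voxel_coords)
    folds = split_half_folds(dataset)
    acc = np.empty(len(neighborhoods))
    per_city = np.empty((len(neighborhoods), 4))
    pooled = ConfusionTable()
    for i, nb in enumerate(neighborhoods):
        conf = classify_neighborhood(
            dataset, nb, folds=folds, model=model, balanced=balanced, seed=seed,
            shuffle_rng=shuffle_rng,
        )
        acc[i] = conf.overall_accuracy
        per_city[i] = conf.per_city_accuracy()
        pooled = pooled + conf
    return SearchlightResult(
        neighborhoods=neighborhoods,
        accuracy=acc,
        per_city_accuracy=per_city,
        pooled=pooled,
    )


def behavior_classifier_correlation(
    behavioral: np.ndarray, decoding: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) across subjects, df = n - 2."""
    behavioral = np.asarray(behavioral, dtype=float)
    decoding = np.asarray(decoding, dtype=float)
    if behavioral.shape != decoding.shape or behavioral.ndim != 1:
        raise ValueError("inputs must be 1-D and aligned")
    if len(behavioral) < 3:
        raise ValueError("need at least 3 subjects")
    if np.std(behavioral) == 0 or np.std(decoding) == 0:
        raise ValueError("constant input has no defined correlation")
    r, p = stats.pearsonr(behavioral, decoding)
    return float(r), float(p)
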