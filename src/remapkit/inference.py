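"""Group-level statistics: t-maps, cluster formation, and FWE correction.

Two family-wise-error procedures are provided.  For voxelwise accuracy maps,
a one-sample t-map against chance is thresholded and clustered, and the
observed maximum cluster size is referred to the distribution of maximum
cluster sizes over sign-flipping permutations (the exchangeable null for a
one-sample test).  For small families of condition-wise t-tests (e.g. ROI x
city remapping indices), a bootstrap max-|t| distribution over sign-flipped
data yields a corrected t threshold at a given percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "GroupMap",
    "Cluster",
    "ClusterReport",
    "one_sample_tmap",
    "cluster_forming_threshold",
    "form_clusters",
    "max_cluster_permutation",
    "bootstrap_fwe_tthreshold",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}
DEFAULT_CONNECTIVITY = 18


def _tmap(data: np.ndarray) -> np.ndarray:
    """Voxelwise one-sample t of (subjects, voxels) data against zero.

    Zero-variance voxels come back NaN.
    """
    n = data.shape[0]
    m = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    # values identical across subjects leave rounding-noise variance
    tol = 1e-9 * (1.0 + np.abs(data).max(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > tol, m / (sd / np.sqrt(n)), np.nan)
    return t


@dataclass
class GroupMap:
    """Voxelwise group t statistic (against chance) with its df."""

    t: np.ndarray  # 3-D
    df: int
    chance: float

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.t)


def one_sample_tmap(subject_maps: np.ndarray, chance: float) -> GroupMap:
    """Voxelwise one-sample t-map of subject maps against ``chance``.

    ``subject_maps`` is (n_subjects, nx, ny, nz); all subjects share a grid
    (maps are assumed already aligned).  Voxels with zero between-subject
    variance are undefined and masked out (NaN) with a warning.
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("subject_maps must be (n_subjects, nx, ny, nz)")
    n = maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a group t-map")
    flat = maps.reshape(n, -1) - chance
    t = _tmap(flat).reshape(maps.shape[1:])
    n_bad = int(np.sum(~np.isfinite(t)))
    if n_bad:
        warnings.warn(
            f"{n_bad} zero-variance voxels masked out of the group t-map",
            RuntimeWarning,
            stacklevel=2,
        )
    return GroupMap(t=t, df=n - 1, chance=chance)


def cluster_forming_threshold(df: int, alpha: float = 0.05, tail: str = "two") -> float:
    """Student-t quantile used to binarize the group map before clustering."""
    if tail == "two":
        return float(stats.t.ppf(1 - alpha / 2, df))
    if tail == "one":
        return float(stats.t.ppf(1 - alpha, df))
    raise ValueError("tail must be 'one' or 'two'")


@dataclass
class Cluster:
    voxels: np.ndarray  # (size, 3) integer coordinates
    size: int
    peak_t: float
    p_corrected: float | None = None


def form_clusters(
    tmap: np.ndarray,
    t_threshold: float,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> list[Cluster]:
    """Connected components of supra-threshold voxels (t >= threshold)."""
    if not np.isfinite(t_threshold):
        raise ValueError("threshold must be finite")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    supra = np.nan_to_num(tmap, nan=-np.inf) >= t_threshold
    labeled, n = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    clusters = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labeled == lab)
        ts = tmap[tuple(vox.T)]
        clusters.append(Cluster(voxels=vox, size=len(vox), peak_t=float(np.max(ts))))
    clusters.sort(key=lambda c: c.size, reverse=True)
    return clusters


@dataclass
class ClusterReport:
    clusters: list[Cluster]  # all observed clusters, largest first
    surviving: list[Cluster]  # clusters at or above the corrected size
    corrected_size: int
    t_threshold: float
    n_perm: int
    null_max_sizes: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))


def _max_cluster_sizes(
    tmaps: np.ndarray, t_threshold: float, connectivity: int
) -> np.ndarray:
    """Max supra-threshold cluster size for each 3-D map in (n, nx, ny, nz)."""
    out = np.zeros(tmaps.shape[0], dtype=int)
    structure = _STRUCTURES[connectivity]
    for i in range(tmaps.shape[0]):
        supra = np.nan_to_num(tmaps[i], nan=-np.inf) >= t_threshold
        labeled, n = ndimage.label(supra, structure=structure)
        if n:
            out[i] = int(np.bincount(labeled.reshape(-1))[1:].max())
    return out


def max_cluster_permutation(
    subject_maps: np.ndarray,
    chance: float,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    tail: str = "two",
    connectivity: int = DEFAULT_CONNECTIVITY,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterReport:
    """Max-cluster-size permutation correction for a one-sample group map.

    Each permutation randomly sign-flips every subject's (map - chance),
    recomputes the t-map, thresholds it at the cluster-forming quantile, and
    records the maximum cluster size.  The corrected size threshold is the
    ``1 - alpha`` quantile of that null distribution; observed clusters are
    assigned permutation p-values (1 + #{null >= size}) / (n_perm + 1) and
    survive if p <= alpha.
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("subject_maps must be (n_subjects, nx, ny, nz)")
    n_subj = maps.shape[0]
    if n_subj < 5:
        raise ValueError("need at least 5 subjects for meaningful sign-flips")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is small; the corrected threshold will be coarse",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    shape = maps.shape[1:]
    flat = maps.reshape(n_subj, -1) - chance
    df = n_subj - 1
    t_thr = cluster_forming_threshold(df, alpha=cluster_alpha, tail=tail)

    sd_ok = flat.std(axis=0, ddof=1) > 1e-9 * (1.0 + np.abs(flat).max(axis=0))
    obs_t = _tmap(flat).reshape(shape)
    observed = form_clusters(obs_t, t_thr, connectivity=connectivity)

    # vectorized sign-flip t-maps: means via matmul, variance from fixed E[x^2]
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    m = flips @ flat / n_subj  # (n_perm, n_vox)
    msq = np.mean(flat**2, axis=0)  # invariant under sign flips
    var = (msq[None, :] - m**2) * n_subj / df
    with np.errstate(invalid="ignore", divide="ignore"):
        t_perm = np.where(sd_ok[None, :], m / np.sqrt(var / n_subj), np.nan)
    null_max = _max_cluster_sizes(t_perm.reshape(n_perm, *shape), t_thr, connectivity)

    # smallest size whose permutation p-value (1 + #{null >= s}) / (n_perm + 1)
    # is <= alpha; consistent with the per-cluster survival rule below
    k = int(np.floor(alpha * (n_perm + 1))) - 1
    if k < 0:
        corrected_size = int(null_max.max()) + 1
    else:
        corrected_size = int(np.sort(null_max)[::-1][k]) + 1
    surviving = []
    for c in observed:
        c.p_corrected = float((1 + np.sum(null_max >= c.size)) / (n_perm + 1))
        if c.p_corrected <= alpha:
            surviving.append(c)
    return ClusterReport(
        clusters=observed,
        surviving=surviving,
        corrected_size=corrected_size,
        t_threshold=t_thr,
        n_perm=n_perm,
        null_max_sizes=null_max,
    )


def bootstrap_fwe_tthreshold(
    table: np.ndarray,
    n_iter: int = 10000,
    percentile: float = 95.0,
    seed: int = 0,
) -> float:
    """Corrected |t| threshold from a max-|t| distribution over sign flips.

    ``table`` is (n_conditions, n_subjects) — e.g. remapping indices for each
    ROI-by-city condition.  Each iteration flips the sign of every subject's
    values (the same flip across conditions, preserving their dependence),
    computes each condition's one-sample t, and takes the maximum |t|; the
    corrected threshold is the requested percentile of that distribution.
    With a single condition this reduces to the ordinary Student quantile up
    to Monte-Carlo error.
    """
    data = np.atleast_2d(np.asarray(table, dtype=float))
    n_cond, n_subj = data.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_iter, n_subj))
    m = flips @ data.T / n_subj  # (n_iter, n_cond)
    msq = np.mean(data**2, axis=1)
    var = (msq[None, :] - m**2) * n_subj / (n_subj - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.abs(m) / np.sqrt(var / n_subj)
    max_t = np.nanmax(t, axis=1)
    return float(np.percentile(max_t, percentile))
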