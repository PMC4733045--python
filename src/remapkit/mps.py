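"""Trial-matched multivariate pattern similarity (MPS) and remapping.

MPS is the mean correlation of voxelwise response patterns across matched
trial pairs.  Within-city similarity pairs each stimulus triad's trial in
retrieval half A with the same triad's trial in half B (never the same
block, and — because response sides swap between halves — never the same
motor response).  Between-city similarity matches triads across cities where
the stimulus sets are shared (Cities 1-3); comparisons involving the
distinct-stimulus City 4 use all pairwise combinations instead.  Pairwise
correlations are Fisher z-transformed before averaging.

The remapping index for a city is its within-city similarity minus the
average of its three between-city similarities, on the Fisher-z scale: a
positive index means the city's voxel code is reinstated within and
reorganized between environments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats

from .core import CITIES, DISTINCT_CITY, INTERFERENCE_CITY, SIMILAR_CITIES, PatternDataset

__all__ = [
    "fisher_z",
    "match_trial_pairs",
    "pair_similarities",
    "mps",
    "SimilarityMatrix",
    "similarity_matrix",
    "remapping_index",
    "remapping_indices",
    "interference_trial_analysis",
    "interference_group_test",
    "univariate_control",
]

R_CLIP = 1.0 - 1e-7


def fisher_z(r):
    """Fisher z transform, z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher z transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def match_trial_pairs(
    dataset: PatternDataset,
    city_a: int,
    city_b: int,
    scheme: str = "triad_matched",
    correct_a: bool | None = True,
    correct_b: bool | None = True,
) -> list[tuple[int, int]]:
    """Trial index pairs for an MPS cell.

    ``triad_matched``: pairs share a stimulus triad and come from opposite
    block halves (city A's half-A trial with city B's half-B trial and vice
    versa; within-city this is the A x B pairing).  ``all_pairwise``: the
    full cross product of the two cities' (filtered) trials — within-city
    still restricted to opposite halves.  ``correct_a``/``correct_b`` filter
    each side by correctness (None = no filter; the interference analysis
    pairs incorrect City 3 trials with correct trials of other cities).
    """
    if scheme not in ("triad_matched", "all_pairwise"):
        raise ValueError(f"unknown scheme {scheme!r}")
    within = city_a == city_b
    pairs: list[tuple[int, int]] = []
    half_combos = [("A", "B")] if within else [("A", "B"), ("B", "A")]
    if scheme == "all_pairwise" and not within:
        # between-city all-pairwise ignores halves entirely
        ia = dataset.trial_indices(city=city_a, correct=correct_a)
        ib = dataset.trial_indices(city=city_b, correct=correct_b)
        pairs = [(int(i), int(j)) for i, j in product(ia, ib)]
    else:
        for half_a, half_b in half_combos:
            ia = dataset.trial_indices(city=city_a, block_half=half_a, correct=correct_a)
            ib = dataset.trial_indices(city=city_b, block_half=half_b, correct=correct_b)
            if scheme == "all_pairwise":
                pairs.extend((int(i), int(j)) for i, j in product(ia, ib))
            else:
                tri_a = {dataset.meta[i].triad_id: i for i in ia}
                tri_b = {dataset.meta[j].triad_id: j for j in ib}
                for tid in sorted(set(tri_a) & set(tri_b)):
                    pairs.append((int(tri_a[tid]), int(tri_b[tid])))
    if not pairs:
        raise ValueError(
            f"no valid {scheme} pairs for cities {city_a} x {city_b} "
            f"(correct_a={correct_a}, correct_b={correct_b})"
        )
    return pairs


def pair_similarities(
    dataset: PatternDataset,
    pairs: list[tuple[int, int]],
    roi: int | np.ndarray | None = None,
) -> np.ndarray:
    """Fisher-z pattern correlation for each trial pair over ROI voxels.

    ``roi`` is an ROI label, an explicit voxel-index array, or None (all
    labeled voxels).  Constant patterns make a pair's correlation undefined;
    such pairs are dropped with a warning.  |r| values at 1 (possible in
    noise-free synthetic data) are clipped to 1 - 1e-7 before atanh.
    """
    if isinstance(roi, (int, np.integer)) or roi is None:
        voxels = dataset.roi_voxels(None if roi is None else int(roi))
    else:
        voxels = np.asarray(roi, dtype=int)
    if len(voxels) < 2:
        raise ValueError("ROI must contain at least 2 voxels")
    pats = dataset.matrix[:, voxels]
    centered = pats - pats.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    # constant patterns have a centered norm at rounding-noise level
    tol = 1e-9 * (1.0 + np.abs(pats).max(axis=1))
    i_idx = np.array([p[0] for p in pairs])
    j_idx = np.array([p[1] for p in pairs])
    ok = (norms[i_idx] > tol[i_idx]) & (norms[j_idx] > tol[j_idx])
    if not np.all(ok):
        warnings.warn(
            f"dropped {int(np.sum(~ok))} pairs with constant patterns",
            RuntimeWarning,
            stacklevel=2,
        )
        i_idx, j_idx = i_idx[ok], j_idx[ok]
    if len(i_idx) == 0:
        raise ValueError("no pairs with non-constant patterns")
    r = np.sum(centered[i_idx] * centered[j_idx], axis=1) / (norms[i_idx] * norms[j_idx])
    n_clipped = int(np.sum(np.abs(r) > R_CLIP))
    if n_clipped:
        warnings.warn(
            f"clipped {n_clipped} |r|>={R_CLIP} correlations before atanh",
            RuntimeWarning,
            stacklevel=2,
        )
    r = np.clip(r, -R_CLIP, R_CLIP)
    return np.arctanh(r)


def mps(
    dataset: PatternDataset,
    pairs: list[tuple[int, int]],
    roi: int | np.ndarray | None = None,
) -> float:
    """Mean Fisher-z pattern similarity over matched trial pairs."""
    return float(np.mean(pair_similarities(dataset, pairs, roi=roi)))


@dataclass
class SimilarityMatrix:
    """4x4 mean similarity (Fisher z): diagonal within-city, off-diagonal between."""

    z: np.ndarray  # (4, 4)
    counts: np.ndarray  # (4, 4) pair counts
    schemes: list[list[str]]
    roi: int | None = None

    def __post_init__(self) -> None:
        if np.asarray(self.z).shape != (4, 4):
            raise ValueError("similarity matrix must be 4x4")
        if np.any(np.asarray(self.counts) <= 0):
            raise ValueError("every reported cell needs at least one pair")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("similarity values must be finite")


def similarity_matrix(
    dataset: PatternDataset,
    roi: int | np.ndarray | None = None,
    scheme: str = "auto",
) -> SimilarityMatrix:
    """All-pairwise-city MPS matrix from correct trials.

    ``scheme='auto'`` follows the stimulus design: triad matching wherever
    both cities share a stimulus set (within-city cells and between cells of
    Cities 1-3), all pairwise combinations for between-city cells involving
    the distinct-stimulus City 4.  The matrix is computed on the upper
    triangle and mirrored (similarity is symmetric).
    """
    if scheme not in ("auto", "triad_matched", "all_pairwise"):
        raise ValueError(f"unknown scheme {scheme!r}")
    z = np.zeros((4, 4))
    counts = np.zeros((4, 4), dtype=int)
    schemes = [["" for _ in CITIES] for _ in CITIES]
    for a in CITIES:
        for b in CITIES:
            if b < a:
                continue
            if scheme == "auto":
                cell_scheme = (
                    "all_pairwise"
                    if (a != b and DISTINCT_CITY in (a, b))
                    else "triad_matched"
                )
            else:
                cell_scheme = scheme
            pairs = match_trial_pairs(dataset, a, b, scheme=cell_scheme)
            zs = pair_similarities(dataset, pairs, roi=roi)
            z[a - 1, b - 1] = z[b - 1, a - 1] = float(np.mean(zs))
            counts[a - 1, b - 1] = counts[b - 1, a - 1] = len(zs)
            schemes[a - 1][b - 1] = schemes[b - 1][a - 1] = cell_scheme
    return SimilarityMatrix(
        z=z,
        counts=counts,
        schemes=schemes,
        roi=roi if isinstance(roi, (int, type(None))) else None,
    )


def remapping_index(sim: SimilarityMatrix, city: int) -> float:
    """Within-city z minus the mean of the city's three between-city z values."""
    if city not in CITIES:
        raise ValueError(f"city must be one of {CITIES}")
    i = city - 1
    between = [sim.z[i, j] for j in range(4) if j != i]
    return float(sim.z[i, i] - np.mean(between))


def remapping_indices(sim: SimilarityMatrix) -> np.ndarray:
    """Remapping index for each of the four cities."""
    return np.array([remapping_index(sim, c) for c in CITIES])


INTERFERENCE_CONDITIONS = (
    "incorrect_c3_x_correct_c12",
    "correct_c3_x_correct_c12",
    "incorrect_c3_x_correct_c4",
    "correct_c3_x_correct_c4",
)


def interference_trial_analysis(
    dataset: PatternDataset, roi: int | np.ndarray | None = None
) -> dict[str, float]:
    """Mean similarity of City 3 trials to other cities, split by correctness.

    Four condition means: incorrect/correct interference-city (City 3)
    trials against correct similar-city (Cities 1 & 2 pooled, triad-matched)
    and against correct distinct-city (City 4, all-pairwise) trials.  If the
    attraction account holds, incorrect City 3 trials resemble the similar
    cities more than correct City 3 trials do, with no such difference for
    City 4.  Conditions with no valid pairs are reported as NaN by name via
    a warning.
    """
    if len(dataset.trial_indices(city=INTERFERENCE_CITY, correct=False)) == 0:
        raise ValueError("City 3 has no incorrect trials: condition "
                         "'incorrect_c3_x_correct_c12' is empty")
    if len(dataset.trial_indices(city=INTERFERENCE_CITY, correct=True)) == 0:
        raise ValueError("City 3 has no correct trials: condition "
                         "'correct_c3_x_correct_c12' is empty")
    out: dict[str, float] = {}
    for name in INTERFERENCE_CONDITIONS:
        c3_correct = name.startswith("correct")
        if name.endswith("c12"):
            others, cell_scheme = SIMILAR_CITIES, "triad_matched"
        else:
            others, cell_scheme = (DISTINCT_CITY,), "all_pairwise"
        zs = []
        try:
            for other in others:
                pairs = match_trial_pairs(
                    dataset,
                    INTERFERENCE_CITY,
                    other,
                    scheme=cell_scheme,
                    correct_a=c3_correct,
                    correct_b=True,
                )
                zs.append(pair_similarities(dataset, pairs, roi=roi))
            out[name] = float(np.mean(np.concatenate(zs)))
        except ValueError:
            warnings.warn(f"condition {name!r} has no valid pairs", RuntimeWarning,
                          stacklevel=2)
            out[name] = float("nan")
    return out


def interference_group_test(
    condition_table: np.ndarray | list[dict[str, float]],
) -> dict[str, tuple[float, float]]:
    """Paired t-tests of condition 1 against each other condition.

    Input: per-subject condition means, either a (n_subjects, 4) array in
    :data:`INTERFERENCE_CONDITIONS` order or a list of per-subject dicts.
    Returns {condition: (t, two-sided p)} for the contrast
    incorrect-C3-vs-similar minus that condition.  Subjects with a NaN in a
    condition are dropped from that contrast.
    """
    if isinstance(condition_table, list):
        table = np.array(
            [[d[c] for c in INTERFERENCE_CONDITIONS] for d in condition_table]
        )
    else:
        table = np.asarray(condition_table, dtype=float)
    results = {}
    ref = table[:, 0]
    for j, name in enumerate(INTERFERENCE_CONDITIONS[1:], start=1):
        ok = np.isfinite(ref) & np.isfinite(table[:, j])
        t, p = stats.ttest_rel(ref[ok], table[ok, j])
        results[name] = (float(t), float(p))
    return results


def univariate_control(
    datasets: list[PatternDataset],
    roi_labels: list[int] | None = None,
    correct_only: bool = True,
) -> tuple["object", "object"]:
    """Mean activation per ROI x city per subject, plus an RM-ANOVA.

    Computes, for each subject, the mean beta over an ROI's voxels and a
    city's (by default correct) trials, and tests for a city main effect and
    a city-by-ROI interaction with a repeated-measures ANOVA.  A flat table
    here supports the claim that multivariate effects are not explained by
    simple per-region activation differences.  Returns (long-format
    DataFrame, ANOVA table).
    """
    import pandas as pd
    from statsmodels.stats.anova import AnovaRM

    if roi_labels is None:
        labels = sorted(set(np.unique(datasets[0].roi_labels)) - {0})
    else:
        labels = list(roi_labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 ROIs for the interaction test")
    rows = []
    for s, ds in enumerate(datasets):
        for roi in labels:
            vox = ds.roi_voxels(roi)
            if len(vox) == 0:
                raise ValueError(f"subject {s}: ROI {roi} has no voxels")
            for city in CITIES:
                idx = ds.trial_indices(city=city, correct=True if correct_only else None)
                if len(idx) == 0:
                    raise ValueError(f"subject {s}: city {city} has no usable trials")
                rows.append(
                    {
                        "subject": s,
                        "roi": roi,
                        "city": city,
                        "mean_beta": float(ds.matrix[np.ix_(idx, vox)].mean()),
                    }
                )
    df = pd.DataFrame(rows)
    anova = AnovaRM(
        df, depvar="mean_beta", subject="subject", within=["roi", "city"]
    ).fit()
    return df, anova.anova_table
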