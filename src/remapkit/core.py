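"""Core domain types shared across the pipeline.

The experiment these types describe: participants learn four virtual cities
(two near-identical "similar" cities, one "interference" city sharing the
similar cities' landmarks in a new layout, and one fully "distinct" city) and
then retrieve spatial relations from each city in two scanner blocks per city
("A" and "B" halves, 20 trials each).  Every analysis stage exchanges data as
a trials-by-voxels pattern matrix plus per-trial metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CITIES = (1, 2, 3, 4)
SIMILAR_CITIES = (1, 2)
INTERFERENCE_CITY = 3
DISTINCT_CITY = 4
BLOCK_HALVES = ("A", "B")
RESPONSE_SIDES = ("left", "right")


@dataclass(frozen=True)
class TrialSpec:
    """Design metadata for a single retrieval trial.

    ``triad_id`` identifies the three-store stimulus; Cities 1-3 draw from a
    shared triad pool while City 4 has a disjoint pool.  ``attracted_to`` is
    set (to 1 or 2) only for interference-city trials whose retrieval pattern
    was captured by a similar-city representation; such trials are incorrect.
    ``response_side`` is the correct button side, swapped between the A and B
    halves of the same city so that within-city pattern comparisons never
    share a motor response.
    """

    city: int
    block_half: str
    triad_id: int
    correct: bool = True
    attracted_to: int | None = None
    response_side: str = "left"

    def __post_init__(self) -> None:
        if self.city not in CITIES:
            raise ValueError(f"city must be one of {CITIES}, got {self.city}")
        if self.block_half not in BLOCK_HALVES:
            raise ValueError(f"block_half must be 'A' or 'B', got {self.block_half!r}")
        if self.response_side not in RESPONSE_SIDES:
            raise ValueError(f"response_side must be left/right, got {self.response_side!r}")
        if self.attracted_to is not None:
            if self.city != INTERFERENCE_CITY:
                raise ValueError("attracted_to is only meaningful for City 3 trials")
            if self.attracted_to not in SIMILAR_CITIES:
                raise ValueError("attracted_to must be 1 or 2")


def meta_frame(meta: Sequence[TrialSpec]) -> pd.DataFrame:
    """Tabulate trial metadata as a DataFrame (one row per trial)."""
    return pd.DataFrame(
        {
            "city": [t.city for t in meta],
            "block_half": [t.block_half for t in meta],
            "triad_id": [t.triad_id for t in meta],
            "correct": [t.correct for t in meta],
            "attracted_to": [t.attracted_to for t in meta],
            "response_side": [t.response_side for t in meta],
        }
    )


@dataclass(frozen=True)
class CityTemplateSet:
    """Ground-truth per-city voxel patterns for the synthetic generator.

    ``separation`` is the expected correlation distance between different
    cities' templates (1 = independent/orthogonal, 0 = identical);
    ``attraction_mix`` is the fraction of City 3's template drawn from the
    average of the two similar cities' templates.
    """

    templates: np.ndarray  # (4, n_voxels)
    n_voxels: int
    separation: float
    attraction_mix: float
    seed: int

    def __post_init__(self) -> None:
        t = np.asarray(self.templates, dtype=float)
        if t.shape != (4, self.n_voxels):
            raise ValueError(f"templates must be (4, {self.n_voxels}), got {t.shape}")
        if not np.all(np.isfinite(t)):
            raise ValueError("templates contain non-finite values")
        object.__setattr__(self, "templates", t)

    def template(self, city: int) -> np.ndarray:
        return self.templates[city - 1]


@dataclass
class EventRow:
    onset: float
    duration: float
    trial: TrialSpec
    run: int


@dataclass
class EventTable:
    """Per-run trial timing driving both BOLD simulation and estimation."""

    rows: list[EventRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_run: dict[int, float] = {}
        for row in self.rows:
            if row.duration <= 0:
                raise ValueError("event durations must be positive")
            prev = by_run.get(row.run)
            if prev is not None and row.onset <= prev:
                raise ValueError(f"onsets must strictly increase within run {row.run}")
            by_run[row.run] = row.onset

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def runs(self) -> list[int]:
        seen: dict[int, None] = {}
        for row in self.rows:
            seen.setdefault(row.run, None)
        return list(seen)

    def for_run(self, run: int) -> "EventTable":
        return EventTable([r for r in self.rows if r.run == run])

    @property
    def onsets(self) -> np.ndarray:
        return np.array([r.onset for r in self.rows])

    @property
    def durations(self) -> np.ndarray:
        return np.array([r.duration for r in self.rows])

    @property
    def meta(self) -> list[TrialSpec]:
        return [r.trial for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        df = meta_frame(self.meta)
        df.insert(0, "duration", self.durations)
        df.insert(0, "onset", self.onsets)
        df["run"] = [r.run for r in self.rows]
        return df


@dataclass
class PatternDataset:
    """Trials-by-voxels response matrix plus aligned trial metadata.

    The central exchange object of the pipeline: produced either directly by
    the pattern-level generator or by single-trial GLM estimation from
    simulated BOLD runs.  ``voxel_coords`` are 0-based integer grid
    coordinates (one row per voxel) and ``roi_labels`` integer region tags
    (0 = outside any region of interest).
    """

    matrix: np.ndarray  # (n_trials, n_voxels)
    meta: list[TrialSpec]
    voxel_coords: np.ndarray  # (n_voxels, 3) int
    roi_labels: np.ndarray  # (n_voxels,) int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (trials x voxels)")
        if self.matrix.shape[0] != len(self.meta):
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} rows but metadata lists "
                f"{len(self.meta)} trials"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("pattern matrix contains non-finite entries")
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        self.roi_labels = np.asarray(self.roi_labels, dtype=int)
        n_vox = self.matrix.shape[1]
        if self.voxel_coords.shape != (n_vox, 3):
            raise ValueError("voxel_coords must be (n_voxels, 3)")
        if self.roi_labels.shape != (n_vox,):
            raise ValueError("roi_labels must be (n_voxels,)")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return meta_frame(self.meta)

    def trial_indices(
        self,
        city: int | None = None,
        block_half: str | None = None,
        correct: bool | None = None,
    ) -> np.ndarray:
        """Indices of trials matching the given filters (None = no filter)."""
        keep = np.ones(self.n_trials, dtype=bool)
        for i, t in enumerate(self.meta):
            if city is not None and t.city != city:
                keep[i] = False
            elif block_half is not None and t.block_half != block_half:
                keep[i] = False
            elif correct is not None and t.correct is not correct:
                keep[i] = False
        return np.flatnonzero(keep)

    def roi_voxels(self, label: int | None = None) -> np.ndarray:
        """Voxel indices carrying ``label`` (None = all in any ROI, label>0)."""
        if label is None:
            return np.flatnonzero(self.roi_labels > 0)
        return np.flatnonzero(self.roi_labels == label)

    def subset_voxels(self, voxel_idx: np.ndarray) -> "PatternDataset":
        voxel_idx = np.asarray(voxel_idx, dtype=int)
        return PatternDataset(
            matrix=self.matrix[:, voxel_idx],
            meta=list(self.meta),
            voxel_coords=self.voxel_coords[voxel_idx],
            roi_labels=self.roi_labels[voxel_idx],
        )

    def grid_shape(self) -> tuple[int, int, int]:
        """Smallest grid containing all voxel coordinates."""
        return tuple(int(m) + 1 for m in self.voxel_coords.max(axis=0))


def compact_grid_coords(n_voxels: int) -> np.ndarray:
    """Lay ``n_voxels`` voxels on a near-cubic integer grid (row-major fill)."""
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    nz = side
    ny = side
    nx = int(np.ceil(n_voxels / (ny * nz)))
    coords = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    return coords[:n_voxels]


def centered_block_mask(
    shape: tuple[int, int, int], block: tuple[int, int, int]
) -> np.ndarray:
    """Boolean mask of a centered rectangular block inside ``shape``."""
    if any(b > s for b, s in zip(block, shape)):
        raise ValueError(f"block {block} does not fit in grid {shape}")
    mask = np.zeros(shape, dtype=bool)
    starts = [(s - b) // 2 for s, b in zip(shape, block)]
    sl = tuple(slice(st, st + b) for st, b in zip(starts, block))
    mask[sl] = True
    return mask
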