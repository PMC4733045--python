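"""Readers and writers for the pipeline's on-disk formats.

Pattern matrices travel as TSV with a JSON sidecar holding trial metadata,
voxel coordinates and ROI labels; event tables as BIDS-style TSV; volumes
and statistic maps as NIfTI-1 (via nibabel) with an anisotropic-voxel affine
matching the acquisition (1.6 x 1.6 x 2 mm by default).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import EventRow, EventTable, PatternDataset, TrialSpec

__all__ = [
    "default_affine",
    "write_pattern_dataset",
    "read_pattern_dataset",
    "write_events",
    "read_events",
    "write_volume",
    "read_volume",
    "write_bold_run",
]

VOXEL_SIZE_MM = (1.6, 1.6, 2.0)


def default_affine(voxel_size: tuple[float, float, float] = VOXEL_SIZE_MM) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def write_pattern_dataset(dataset: PatternDataset, prefix: str | Path) -> None:
    """Write ``<prefix>.tsv`` (trials x voxels) and ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    pd.DataFrame(dataset.matrix).to_csv(
        prefix.with_suffix(".tsv"), sep="\t", index=False, header=False
    )
    sidecar = {
        "meta": [
            {
                "city": t.city,
                "block_half": t.block_half,
                "triad_id": t.triad_id,
                "correct": t.correct,
                "attracted_to": t.attracted_to,
                "response_side": t.response_side,
            }
            for t in dataset.meta
        ],
        "voxel_coords": dataset.voxel_coords.tolist(),
        "roi_labels": dataset.roi_labels.tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def read_pattern_dataset(prefix: str | Path) -> PatternDataset:
    prefix = Path(prefix)
    matrix = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", header=None).to_numpy()
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    meta = [TrialSpec(**row) for row in sidecar["meta"]]
    return PatternDataset(
        matrix=matrix,
        meta=meta,
        voxel_coords=np.array(sidecar["voxel_coords"]),
        roi_labels=np.array(sidecar["roi_labels"]),
    )


def write_events(events: EventTable, path: str | Path) -> None:
    """BIDS-style events TSV: onset, duration, trial metadata, run."""
    events.to_frame().to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path: str | Path) -> EventTable:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    rows = []
    for _, r in df.iterrows():
        rows.append(
            EventRow(
                onset=float(r["onset"]),
                duration=float(r["duration"]),
                trial=TrialSpec(
                    city=int(r["city"]),
                    block_half=str(r["block_half"]),
                    triad_id=int(r["triad_id"]),
                    correct=bool(r["correct"]),
                    attracted_to=None
                    if pd.isna(r["attracted_to"])
                    else int(r["attracted_to"]),
                    response_side=str(r["response_side"]),
                ),
                run=int(r["run"]),
            )
        )
    return EventTable(rows)


def write_volume(
    data: np.ndarray, path: str | Path, affine: np.ndarray | None = None
) -> None:
    """Write a 3-D map or 4-D series as NIfTI-1."""
    img = nib.Nifti1Image(
        np.asarray(data, dtype=np.float64),
        default_affine() if affine is None else affine,
    )
    nib.save(img, str(path))


def read_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_bold_run(
    run_data: np.ndarray,
    voxel_coords: np.ndarray,
    grid_shape: tuple[int, int, int],
    path: str | Path,
) -> None:
    """Scatter a (n_voxels, n_scans) run onto its grid and save as 4-D NIfTI."""
    run_data = np.asarray(run_data, dtype=float)
    vol = np.zeros((*grid_shape, run_data.shape[1]))
    x, y, z = np.asarray(voxel_coords, dtype=int).T
    vol[x, y, z, :] = run_data
    write_volume(vol, path)
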