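"""Single-trial voxel pattern estimation from BOLD time series.

Pattern-similarity and decoding analyses need one maximally orthogonalized
response estimate per trial.  The estimation scheme: (1) fit a finite impulse
response (FIR) model — ten per-scan indicator bins per trial — to obtain
assumption-free response time courses; (2) extract a single empirical HRF
shape from the pooled FIR profiles by logistic-infomax ICA (or the first
principal component), selecting the component whose back-projection explains
the most variance; (3) resample that kernel with a cubic spline to microtime
resolution (16 bins per scan by default); (4) build one convolved regressor
per trial and fit a single joint ordinary-least-squares model per run,
yielding a trials-by-voxels beta matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import gamma as gamma_dist

from .core import EventTable, PatternDataset, compact_grid_coords
from .synthetic import convolved_regressor

__all__ = [
    "FirEstimate",
    "HrfKernel",
    "build_fir_design",
    "fit_fir",
    "build_block_fir_design",
    "fit_block_fir",
    "extract_empirical_hrf",
    "resample_hrf",
    "canonical_hrf",
    "estimate_single_trial_betas",
]

DEFAULT_N_BINS = 10
DEFAULT_BINS_PER_SCAN = 16


@dataclass
class FirEstimate:
    """Per-trial, per-voxel FIR coefficients (n_trials, n_voxels, n_bins)."""

    coefficients: np.ndarray
    tr: float
    n_bins: int

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.ndim != 3 or c.shape[2] != self.n_bins:
            raise ValueError("coefficients must be (n_trials, n_voxels, n_bins)")
        if not np.all(np.isfinite(c)):
            raise ValueError("FIR coefficients contain non-finite values")
        self.coefficients = c

    def profiles(self) -> np.ndarray:
        """Flatten to (n_trials * n_voxels, n_bins) response profiles."""
        n_t, n_v, n_b = self.coefficients.shape
        return self.coefficients.reshape(n_t * n_v, n_b)


@dataclass
class HrfKernel:
    """A sampled hemodynamic response kernel."""

    samples: np.ndarray
    dt: float  # sampling interval, seconds
    variance_explained: float = 1.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.size < 2:
            raise ValueError("HRF kernel needs at least 2 samples")
        if not 0.0 <= self.variance_explained <= 1.0:
            raise ValueError("variance_explained must lie in [0, 1]")
        self.samples = s


def build_fir_design(
    events: EventTable,
    n_scans: int,
    tr: float,
    n_bins: int = DEFAULT_N_BINS,
) -> np.ndarray:
    """FIR design matrix: ``n_bins`` indicator columns per trial, trial-major.

    Column ``trial * n_bins + j`` has a 1 at the scan nearest each onset plus
    ``j`` scans (bins running over the first through n_bins-th scan after
    stimulus onset).  Bins falling past the run end are an error.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n_trials = len(events)
    if n_trials == 0:
        raise ValueError("empty event table")
    design = np.zeros((n_scans, n_trials * n_bins))
    for t, row in enumerate(events.rows):
        onset_scan = int(round(row.onset / tr))
        if onset_scan >= n_scans:
            raise ValueError(f"event at {row.onset}s falls after the run end")
        if onset_scan + n_bins > n_scans:
            raise ValueError(
                f"event at {row.onset}s: {n_bins} FIR bins exceed the run length"
            )
        for j in range(n_bins):
            design[onset_scan + j, t * n_bins + j] = 1.0
    return design


def fit_fir(
    run_data: np.ndarray,
    events: EventTable,
    tr: float,
    n_bins: int = DEFAULT_N_BINS,
) -> FirEstimate:
    """Least-squares FIR fit of one run: data is (n_voxels, n_scans)."""
    run_data = np.asarray(run_data, dtype=float)
    n_scans = run_data.shape[1]
    design = build_fir_design(events, n_scans, tr, n_bins)
    coef, *_ = np.linalg.lstsq(design, run_data.T, rcond=None)
    # (n_trials*n_bins, n_voxels) -> (n_trials, n_voxels, n_bins)
    n_trials = len(events)
    coef = coef.reshape(n_trials, n_bins, -1).transpose(0, 2, 1)
    return FirEstimate(coefficients=coef, tr=tr, n_bins=n_bins)


def build_block_fir_design(
    events: EventTable,
    n_scans: int,
    tr: float,
    n_bins: int = DEFAULT_N_BINS,
) -> np.ndarray:
    """Block-level FIR design: ``n_bins`` shared columns for all trials.

    Column j carries a 1 at scan onset+j of *every* trial, so the fit
    estimates one average stimulus-locked response shape per voxel per
    block.  Unlike the per-trial design this stays full rank at any SOA,
    which is what makes it the right input for empirical-HRF extraction.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(events) == 0:
        raise ValueError("empty event table")
    design = np.zeros((n_scans, n_bins))
    for row in events.rows:
        onset_scan = int(round(row.onset / tr))
        if onset_scan + n_bins > n_scans:
            raise ValueError(
                f"event at {row.onset}s: {n_bins} FIR bins exceed the run length"
            )
        for j in range(n_bins):
            design[onset_scan + j, j] += 1.0
    return design


def fit_block_fir(
    run_data: np.ndarray,
    events: EventTable,
    tr: float,
    n_bins: int = DEFAULT_N_BINS,
) -> np.ndarray:
    """Average response profile per voxel for one block: (n_voxels, n_bins)."""
    run_data = np.asarray(run_data, dtype=float)
    design = build_block_fir_design(events, run_data.shape[1], tr, n_bins)
    coef, *_ = np.linalg.lstsq(design, run_data.T, rcond=None)
    return coef.T


def _first_pc(profiles: np.ndarray) -> tuple[np.ndarray, float]:
    # SVD of the uncentered profile matrix: the mean response shape is signal
    # here, not a nuisance to remove.
    u, s, vt = np.linalg.svd(profiles, full_matrices=False)
    ve = float(s[0] ** 2 / np.sum(s**2))
    return vt[0], ve


def extract_empirical_hrf(
    fir: FirEstimate | np.ndarray,
    method: str = "infomax_ica",
    seed: int = 0,
    max_components: int | None = None,
) -> HrfKernel:
    """Extract a single HRF shape from pooled FIR response profiles.

    ``fir`` is a :class:`FirEstimate` or a (profiles, bins) matrix.  The
    profile matrix is decomposed (logistic-infomax ICA on an SVD-whitened
    basis, or plain first principal component) and the component whose
    back-projection explains the most variance of the profiles is returned,
    sign-aligned so its peak is positive, with that variance fraction
    reported.
    """
    profiles = fir.profiles() if isinstance(fir, FirEstimate) else np.asarray(fir, float)
    dt = fir.tr if isinstance(fir, FirEstimate) else 1.0
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise ValueError("need at least 2 FIR profiles")
    total_var = float(np.sum(profiles**2))
    if total_var == 0:
        raise ValueError("constant (all-zero) FIR profiles")
    if method not in ("infomax_ica", "first_pc"):
        raise ValueError(f"unknown method {method!r}")

    u, s, vt = np.linalg.svd(profiles, full_matrices=False)
    tol = max(profiles.shape) * np.finfo(float).eps * s[0]
    rank = int(np.sum(s > tol))
    if method == "infomax_ica" and rank >= 2:
        k = rank if max_components is None else min(rank, max_components)
        from mne.preprocessing import infomax

        n = profiles.shape[0]
        white = u[:, :k] * np.sqrt(n)  # unit-covariance projections
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            unmix = infomax(
                white, extended=False, rng=np.random.default_rng(seed), verbose="error"
            )
        sources = white @ unmix.T  # (n, k)
        # mixing back to bin space: profiles ~= sources @ mixing
        mixing = np.linalg.pinv(sources) @ profiles  # (k, n_bins)
        ve = np.array(
            [
                np.sum((np.outer(sources[:, j], mixing[j])) ** 2) / total_var
                for j in range(k)
            ]
        )
        best = int(np.argmax(ve))
        kernel, best_ve = mixing[best], float(ve[best])
    else:
        kernel, best_ve = _first_pc(profiles)

    peak = kernel[int(np.argmax(np.abs(kernel)))]
    if peak < 0:
        kernel = -kernel
    norm = np.linalg.norm(kernel)
    kernel = kernel / norm
    return HrfKernel(samples=kernel, dt=dt, variance_explained=min(best_ve, 1.0))


def resample_hrf(hrf: HrfKernel, bins_per_scan: int = DEFAULT_BINS_PER_SCAN) -> HrfKernel:
    """Cubic-spline upsample of an HRF kernel to microtime resolution.

    The interpolant passes through the original samples exactly; the output
    sampling interval is ``hrf.dt / bins_per_scan``.
    """
    if hrf.samples.size < 4:
        raise ValueError("cubic resampling needs at least 4 samples")
    if bins_per_scan < 1:
        raise ValueError("bins_per_scan must be >= 1")
    t = np.arange(hrf.samples.size) * hrf.dt
    spline = CubicSpline(t, hrf.samples)
    fine_dt = hrf.dt / bins_per_scan
    t_fine = np.arange((hrf.samples.size - 1) * bins_per_scan + 1) * fine_dt
    return HrfKernel(
        samples=spline(t_fine), dt=fine_dt, variance_explained=hrf.variance_explained
    )


def canonical_hrf(dt: float, duration: float = 30.0) -> HrfKernel:
    """Double-gamma canonical HRF (peak 6 s, undershoot 16 s, ratio 1/6)."""
    t = np.arange(0.0, duration + dt / 2, dt)
    peak = gamma_dist.pdf(t, 6.0)
    under = gamma_dist.pdf(t, 16.0)
    h = peak - under / 6.0
    return HrfKernel(samples=h / np.max(h), dt=dt)


def estimate_single_trial_betas(
    runs: list[np.ndarray],
    events: EventTable,
    hrf: HrfKernel,
    tr: float,
    voxel_coords: np.ndarray | None = None,
    roi_labels: np.ndarray | None = None,
    event_model: str = "boxcar",
) -> PatternDataset:
    """Per-trial GLM betas: one convolved regressor per trial, OLS per run.

    A single joint model is fit per run — every trial of that run gets its
    own regressor (trial-duration boxcar convolved with ``hrf`` at the
    kernel's resolution, read out on the scan grid) plus an intercept.
    Returns the trials-by-voxels beta matrix with metadata carried over from
    ``events`` (row order: runs in table order, trials in onset order).

    ``event_model="impulse"`` places the kernel at each onset without boxcar
    convolution — the right choice when ``hrf`` is an empirical *response*
    shape (e.g. a block-FIR profile) that already embodies the trial
    duration; convolving such a shape with the boxcar again would
    double-count the duration and misestimate overlapping trials.
    """
    if event_model not in ("boxcar", "impulse"):
        raise ValueError("event_model must be 'boxcar' or 'impulse'")
    run_ids = events.runs
    if len(runs) != len(run_ids):
        raise ValueError(f"got {len(runs)} runs but events describe {len(run_ids)}")
    betas = []
    meta = []
    for data, run in zip(runs, run_ids):
        run_events = events.for_run(run)
        data = np.asarray(data, dtype=float)
        n_vox, n_scans = data.shape
        regs = np.stack(
            [
                convolved_regressor(
                    r.onset,
                    r.duration if event_model == "boxcar" else hrf.dt,
                    hrf.samples,
                    hrf.dt,
                    n_scans,
                    tr,
                )
                for r in run_events.rows
            ]
        ).T  # (n_scans, n_trials_run)
        design = np.column_stack([regs, np.ones(n_scans)])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            corr = np.corrcoef(regs.T)
            np.fill_diagonal(corr, 0.0)
            bad = np.unique(np.argwhere(np.abs(corr) > 1 - 1e-10) % regs.shape[1])
            raise ValueError(
                f"singular trial design in run {run}; collinear trials: {bad.tolist()}"
            )
        coef, *_ = np.linalg.lstsq(design, data.T, rcond=None)
        betas.append(coef[:-1])  # (n_trials_run, n_voxels)
        meta.extend(run_events.meta)
    matrix = np.vstack(betas)
    n_vox = matrix.shape[1]
    if voxel_coords is None:
        voxel_coords = compact_grid_coords(n_vox)
    if roi_labels is None:
        roi_labels = np.ones(n_vox, dtype=int)
    return PatternDataset(
        matrix=matrix, meta=meta, voxel_coords=voxel_coords, roi_labels=roi_labels
    )
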