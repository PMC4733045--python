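"""Synthetic data with the statistical structure the analyses assume.

Generates (a) per-city ground-truth voxel templates, (b) trial-level pattern
datasets in which interference-city trials can be "attracted" toward the
similar cities' templates, (c) forward-modeled BOLD time series for testing
the estimation stage, and (d) multi-subject cohorts with behavior coupled to
the attraction rate.

Generative model
----------------
Templates are unit-norm Gaussian vectors; trial patterns are a template plus
i.i.d. Gaussian voxel noise.  An interference-city (City 3) trial is, with
probability ``p_attract``, generated from the City 1 or City 2 template
instead (an attraction/pattern-completion error; the trial is then answered
incorrectly).  Correct City 3 trials carry a fraction ``c3_stability`` of
their signal energy from the stable City 3 template, the remainder being a
fresh idiosyncratic direction per trial — ``c3_stability=1`` reproduces a
fully stable code, small values a weakly reinstated one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    BLOCK_HALVES,
    CITIES,
    DISTINCT_CITY,
    INTERFERENCE_CITY,
    SIMILAR_CITIES,
    CityTemplateSet,
    EventRow,
    EventTable,
    PatternDataset,
    TrialSpec,
    centered_block_mask,
    compact_grid_coords,
)

__all__ = [
    "make_city_templates",
    "simulate_trial_patterns",
    "make_event_tables",
    "simulate_bold_runs",
    "simulate_cohort",
    "CohortSubject",
]

DEFAULT_N_VOXELS = 200
DEFAULT_NOISE_SD = 0.35
DEFAULT_TRIALS_PER_HALF = 20
DEFAULT_TR = 3.0


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def make_city_templates(
    n_voxels: int = DEFAULT_N_VOXELS,
    separation: float = 1.0,
    attraction_mix: float = 0.0,
    seed: int = 0,
) -> CityTemplateSet:
    """Draw one unit-norm template per city.

    Parameters
    ----------
    n_voxels
        Template length (>= 2).
    separation
        Expected correlation distance between different cities' templates in
        [0, 1]: 1 gives independent (near-orthogonal) templates, 0 identical
        ones; intermediate values mix a common component so that the expected
        between-city template correlation is ``1 - separation``.
    attraction_mix
        Fraction (lambda in [0, 1]) of City 3's template taken from the
        normalized average of Cities 1 & 2's templates; the remainder is an
        independent draw.  With orthogonal components the correlation of the
        City 3 template with that average is lambda / sqrt(lambda^2 +
        (1-lambda)^2).
    """
    if n_voxels < 2:
        raise ValueError("n_voxels must be >= 2")
    if not 0.0 <= attraction_mix <= 1.0:
        raise ValueError("attraction_mix must lie in [0, 1]")
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    common = _unit(rng.standard_normal(n_voxels))
    uniques = [_unit(rng.standard_normal(n_voxels)) for _ in range(4)]
    w_common = np.sqrt(1.0 - separation)
    w_unique = np.sqrt(separation)
    templates = np.empty((4, n_voxels))
    for c in (1, 2, 4):
        templates[c - 1] = _unit(w_common * common + w_unique * uniques[c - 1])
    base3 = _unit(w_common * common + w_unique * uniques[2])
    lam = attraction_mix
    if lam == 0.0:
        t3 = base3
    else:
        similar_mean = _unit(0.5 * (templates[0] + templates[1]))
        t3 = _unit(lam * similar_mean + (1.0 - lam) * base3)
    templates[2] = t3
    return CityTemplateSet(
        templates=templates,
        n_voxels=n_voxels,
        separation=separation,
        attraction_mix=attraction_mix,
        seed=seed,
    )


def _build_trial_specs(
    n_trials_per_half: int,
    rng: np.random.Generator,
) -> list[TrialSpec]:
    """Full design: 4 cities x 2 halves x n trials, with shared triads for
    Cities 1-3, a disjoint triad pool for City 4, and response sides swapped
    between the A and B halves of each city."""
    n = n_trials_per_half
    shared_pool = np.arange(n)
    distinct_pool = np.arange(n, 2 * n)
    # correct side per (city, triad) in half A; flipped in half B
    side_a = {
        (city, int(tid)): ("left" if rng.random() < 0.5 else "right")
        for city in CITIES
        for tid in (shared_pool if city != DISTINCT_CITY else distinct_pool)
    }
    flip = {"left": "right", "right": "left"}
    specs = []
    for city in CITIES:
        pool = distinct_pool if city == DISTINCT_CITY else shared_pool
        for half in BLOCK_HALVES:
            for tid in pool:
                side = side_a[(city, int(tid))]
                if half == "B":
                    side = flip[side]
                specs.append(
                    TrialSpec(
                        city=city,
                        block_half=half,
                        triad_id=int(tid),
                        response_side=side,
                    )
                )
    return specs


def simulate_trial_patterns(
    templates: CityTemplateSet,
    n_trials_per_half: int = DEFAULT_TRIALS_PER_HALF,
    noise_sd: float = DEFAULT_NOISE_SD,
    p_attract: float = 0.0,
    c3_stability: float = 1.0,
    lapse_rate: float = 0.0,
    seed: int = 0,
    grid_shape: tuple[int, int, int] | None = None,
    roi_block: tuple[int, int, int] | None = None,
    attraction_unit: str = "triad",
) -> PatternDataset:
    """Simulate single-trial voxel patterns for the full four-city design.

    Each trial's pattern is its city's template plus i.i.d. Gaussian noise of
    standard deviation ``noise_sd`` per voxel.  Each City 3 trial is, with
    probability ``p_attract``, generated from the City 1 or City 2 template
    (chosen uniformly) instead; its ``attracted_to`` field records the
    captured-by city and its ``correct`` flag is False.  Non-attracted City 3
    trials carry sqrt(c3_stability) of the City 3 template plus a fresh
    unit-norm idiosyncratic direction weighted sqrt(1 - c3_stability).
    Trials of other cities are correct except for an independent
    ``lapse_rate`` of behavioral lapses (pattern unchanged).

    ``attraction_unit`` controls where the attraction coin is tossed:
    ``"triad"`` (default) draws it once per stimulus triad, so an interfered
    store-pair memory errs in both retrieval blocks — interference is a
    property of the stored relation, and every non-attracted triad stays
    analyzable in cross-block pairings; ``"trial"`` tosses independently per
    trial.

    If ``grid_shape`` is given, the template voxels are embedded in a
    centered block (``roi_block``, ROI label 1) of a larger grid whose
    remaining voxels are pure noise (label 0); otherwise the dataset voxels
    are laid on a compact grid and all labeled 1.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if n_trials_per_half < 1:
        raise ValueError("n_trials_per_half must be >= 1")
    if not 0.0 <= p_attract <= 1.0:
        raise ValueError("p_attract must lie in [0, 1]")
    if not 0.0 <= c3_stability <= 1.0:
        raise ValueError("c3_stability must lie in [0, 1]")
    if attraction_unit not in ("triad", "trial"):
        raise ValueError("attraction_unit must be 'triad' or 'trial'")
    rng = np.random.default_rng(seed)
    specs = _build_trial_specs(n_trials_per_half, rng)
    n_sig = templates.n_voxels

    # per-triad attraction outcome for the interference city: None = stable
    triad_target = {
        tid: (int(rng.choice(SIMILAR_CITIES)) if rng.random() < p_attract else None)
        for tid in range(n_trials_per_half)
    }

    signals = np.empty((len(specs), n_sig))
    out_specs: list[TrialSpec] = []
    for i, spec in enumerate(specs):
        if spec.city == INTERFERENCE_CITY:
            if attraction_unit == "triad":
                attracted = triad_target[spec.triad_id] is not None
            else:
                attracted = rng.random() < p_attract
            if attracted:
                target = (
                    triad_target[spec.triad_id]
                    if attraction_unit == "triad"
                    else int(rng.choice(SIMILAR_CITIES))
                )
                signals[i] = templates.template(target)
                spec = TrialSpec(
                    city=spec.city,
                    block_half=spec.block_half,
                    triad_id=spec.triad_id,
                    correct=False,
                    attracted_to=target,
                    response_side=spec.response_side,
                )
            else:
                sig = np.sqrt(c3_stability) * templates.template(INTERFERENCE_CITY)
                if c3_stability < 1.0:
                    idio = _unit(rng.standard_normal(n_sig))
                    sig = sig + np.sqrt(1.0 - c3_stability) * idio
                signals[i] = sig
        else:
            signals[i] = templates.template(spec.city)
            if lapse_rate > 0.0 and rng.random() < lapse_rate:
                spec = TrialSpec(
                    city=spec.city,
                    block_half=spec.block_half,
                    triad_id=spec.triad_id,
                    correct=False,
                    response_side=spec.response_side,
                )
        out_specs.append(spec)

    if grid_shape is None:
        matrix = signals
        if noise_sd > 0:
            matrix = matrix + rng.normal(0.0, noise_sd, size=matrix.shape)
        coords = compact_grid_coords(n_sig)
        labels = np.ones(n_sig, dtype=int)
    else:
        if roi_block is None:
            raise ValueError("roi_block is required when grid_shape is given")
        mask = centered_block_mask(grid_shape, roi_block)
        if int(mask.sum()) != n_sig:
            raise ValueError(
                f"roi_block holds {int(mask.sum())} voxels but templates have {n_sig}"
            )
        coords = np.stack(
            np.meshgrid(*(np.arange(s) for s in grid_shape), indexing="ij"), axis=-1
        ).reshape(-1, 3)
        labels = mask.reshape(-1).astype(int)
        matrix = np.zeros((len(out_specs), coords.shape[0]))
        matrix[:, labels == 1] = signals
        if noise_sd > 0:
            matrix = matrix + rng.normal(0.0, noise_sd, size=matrix.shape)
    return PatternDataset(
        matrix=matrix, meta=out_specs, voxel_coords=coords, roi_labels=labels
    )


def make_event_tables(
    meta: list[TrialSpec],
    tr: float = DEFAULT_TR,
    soa: float = 9.0,
    duration: float = 4.0,
    start: float = 6.0,
) -> EventTable:
    """Build per-block event timing for a list of trials.

    One run per (city, block half) pair, trials at a fixed stimulus-onset
    asynchrony.  The default 4 s duration matches the average retrieval
    response window; run numbering follows block order of appearance.
    """
    run_of: dict[tuple[int, str], int] = {}
    counters: dict[int, int] = {}
    rows = []
    for spec in meta:
        key = (spec.city, spec.block_half)
        if key not in run_of:
            run_of[key] = len(run_of)
        run = run_of[key]
        k = counters.get(run, 0)
        counters[run] = k + 1
        rows.append(EventRow(onset=start + k * soa, duration=duration, trial=spec, run=run))
    return EventTable(rows)


def run_length_scans(events: EventTable, tr: float = DEFAULT_TR, pad_scans: int = 10) -> int:
    """Run length: last event offset rounded up to a scan, plus padding."""
    if len(events) == 0:
        raise ValueError("empty event table")
    last = max(r.onset + r.duration for r in events.rows)
    return int(np.ceil(last / tr)) + pad_scans


def convolved_regressor(
    onset: float,
    duration: float,
    hrf_samples: np.ndarray,
    hrf_dt: float,
    n_scans: int,
    tr: float = DEFAULT_TR,
) -> np.ndarray:
    """Boxcar(onset, duration) convolved with an HRF kernel, sampled at scans.

    The convolution runs on the kernel's (microtime) grid and is then read
    out at scan acquisition times; both the forward simulator and the GLM
    estimator build regressors through this function so that noise-free
    simulation followed by estimation is exactly self-consistent.
    """
    hrf_samples = np.asarray(hrf_samples, dtype=float)
    n_fine = int(np.ceil(n_scans * tr / hrf_dt)) + len(hrf_samples) + 1
    t_fine = np.arange(n_fine) * hrf_dt
    boxcar = ((t_fine >= onset) & (t_fine < onset + duration)).astype(float)
    sig = np.convolve(boxcar, hrf_samples)[:n_fine] * hrf_dt
    scan_idx = np.round(np.arange(n_scans) * tr / hrf_dt).astype(int)
    return sig[scan_idx]


def simulate_bold_runs(
    events: EventTable,
    templates: CityTemplateSet,
    hrf_samples: np.ndarray,
    hrf_dt: float,
    tr: float = DEFAULT_TR,
    noise_sd: float = 0.0,
    seed: int = 0,
    trial_patterns: np.ndarray | None = None,
    baseline_amplitude: float = 0.0,
) -> list[np.ndarray]:
    """Forward-model BOLD runs: per-voxel superposition of convolved trials.

    Each voxel's time series is the sum over that run's trials of the trial's
    amplitude at the voxel times the trial's convolved boxcar regressor, plus
    white Gaussian noise.  Returns one (n_voxels, n_scans) array per run.
    ``trial_patterns`` overrides the amplitude patterns (rows aligned with
    ``events``); by default they are derived from each trial's spec (the
    attracted-to city's template for attracted trials).

    ``baseline_amplitude`` adds a shared evoked response of that amplitude to
    every voxel on every trial — the task-general activation real BOLD data
    carry on top of the condition-specific pattern.  It cancels out of
    pattern correlations and decoding but is what lets an average response
    shape (for empirical-HRF extraction) dominate the trial-wise variation.
    """
    if len(events) == 0:
        raise ValueError("empty event table")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    if trial_patterns is None:
        trial_patterns = np.stack(
            [
                templates.template(
                    r.trial.attracted_to
                    if r.trial.attracted_to is not None
                    else r.trial.city
                )
                for r in events.rows
            ]
        )
    trial_patterns = np.asarray(trial_patterns, dtype=float)
    if trial_patterns.shape[0] != len(events):
        raise ValueError("trial_patterns rows must align with events")
    if baseline_amplitude:
        trial_patterns = trial_patterns + baseline_amplitude
    out = []
    row_idx = np.arange(len(events))
    for run in events.runs:
        sel = [i for i in row_idx if events.rows[i].run == run]
        run_events = EventTable([events.rows[i] for i in sel])
        n_scans = run_length_scans(run_events, tr=tr)
        for r in run_events.rows:
            if r.onset + r.duration > n_scans * tr:
                raise ValueError(f"event at {r.onset}s extends past run end")
        regs = np.stack(
            [
                convolved_regressor(r.onset, r.duration, hrf_samples, hrf_dt, n_scans, tr)
                for r in run_events.rows
            ]
        )  # (n_trials_run, n_scans)
        data = trial_patterns[sel].T @ regs  # (n_voxels, n_scans)
        if noise_sd > 0:
            data = data + rng.normal(0.0, noise_sd, size=data.shape)
        out.append(data)
    return out


@dataclass
class CohortSubject:
    """One simulated participant: neural patterns plus behavioral accuracy."""

    dataset: PatternDataset
    behavior: dict[int, float]  # city -> proportion correct
    p_attract: float


def simulate_cohort(
    n_subjects: int = 19,
    p_attract_range: tuple[float, float] = (0.15, 0.65),
    n_voxels: int = DEFAULT_N_VOXELS,
    noise_sd: float = DEFAULT_NOISE_SD,
    separation: float = 1.0,
    attraction_mix: float = 0.0,
    c3_stability: float = 0.1,
    lapse_rate: float = 0.05,
    n_trials_per_half: int = DEFAULT_TRIALS_PER_HALF,
    seed: int = 0,
    grid_shape: tuple[int, int, int] | None = None,
    roi_block: tuple[int, int, int] | None = None,
) -> list[CohortSubject]:
    """Simulate a cohort in the interference regime of the four-city design.

    Each subject gets their own templates (cities are subject-specific codes)
    and an attraction probability drawn uniformly from ``p_attract_range``
    (default mean 0.4).  Behavioral accuracy per city is the empirical
    proportion of correct trials — for City 3 this is 1 - p_attract up to
    binomial noise at 2 x n_trials_per_half trials.  Correct City 3 trials
    reinstate only a weak stable code (``c3_stability``, default 0.1),
    mirroring an unstable interference-city representation.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    lo, hi = p_attract_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("p_attract_range must be ordered within [0, 1]")
    rng = np.random.default_rng(seed)
    subjects = []
    for s in range(n_subjects):
        p = float(rng.uniform(lo, hi))
        tpl_seed = int(rng.integers(2**31 - 1))
        ds_seed = int(rng.integers(2**31 - 1))
        templates = make_city_templates(
            n_voxels=n_voxels,
            separation=separation,
            attraction_mix=attraction_mix,
            seed=tpl_seed,
        )
        ds = simulate_trial_patterns(
            templates,
            n_trials_per_half=n_trials_per_half,
            noise_sd=noise_sd,
            p_attract=p,
            c3_stability=c3_stability,
            lapse_rate=lapse_rate,
            seed=ds_seed,
            grid_shape=grid_shape,
            roi_block=roi_block,
        )
        df = ds.to_frame()
        behavior = {
            int(city): float(grp["correct"].mean())
            for city, grp in df.groupby("city")
        }
        subjects.append(CohortSubject(dataset=ds, behavior=behavior, p_attract=p))
    return subjects
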