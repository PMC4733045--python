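"""Estimation stage: FIR design, empirical HRF extraction, resampling, trial betas."""

import numpy as np
import pytest

from remapkit.core import EventRow, EventTable, TrialSpec
from remapkit.synthetic import (
    convolved_regressor,
    make_city_templates,
    make_event_tables,
    simulate_bold_runs,
    simulate_trial_patterns,
)
from remapkit.trialbeta import (
    HrfKernel,
    build_fir_design,
    canonical_hrf,
    estimate_single_trial_betas,
    extract_empirical_hrf,
    fit_fir,
    resample_hrf,
)

TR = 3.0


def _events(onsets, duration=4.0, city=1):
    rows = [
        EventRow(
            onset=o,
            duration=duration,
            trial=TrialSpec(city=city, block_half="A", triad_id=i),
            run=0,
        )
        for i, o in enumerate(onsets)
    ]
    return EventTable(rows)


class TestFirDesign:
    def test_single_event_shifts_identity_bins(self):
        design = build_fir_design(_events([15.0]), n_scans=30, tr=TR, n_bins=10)
        assert design.shape == (30, 10)
        for j in range(10):
            col = design[:, j]
            assert col.sum() == 1 and col[5 + j] == 1

    def test_nonoverlapping_events_are_block_diagonal(self):
        design = build_fir_design(_events([0.0, 36.0]), n_scans=30, tr=TR, n_bins=10)
        assert np.array_equal(design[:10, :10], np.eye(10))
        assert np.array_equal(design[12:22, 10:], np.eye(10))
        assert design[:12, 10:].sum() == 0 and design[10:, :10].sum() == 0

    def test_event_past_run_end_rejected(self):
        with pytest.raises(ValueError):
            build_fir_design(_events([100.0]), n_scans=30, tr=TR)

    def test_bins_exceeding_run_rejected(self):
        with pytest.raises(ValueError):
            build_fir_design(_events([75.0]), n_scans=30, tr=TR, n_bins=10)

    def test_fir_fit_recovers_injected_hrf(self):
        # non-overlapping events (SOA >= n_bins * TR keeps the design full rank)
        hrf = canonical_hrf(dt=TR)
        events = _events([0.0, 36.0, 72.0], duration=TR)
        amps = np.array([[1.5], [0.7], [2.0]])  # one voxel
        n_scans = 40
        reg_rows = [
            convolved_regressor(r.onset, r.duration, hrf.samples, TR, n_scans, TR)
            for r in events.rows
        ]
        data = (amps * np.stack(reg_rows)).sum(axis=0)[None, :]
        fir = fit_fir(data, events, tr=TR)
        for t, row in enumerate(events.rows):
            onset_scan = int(round(row.onset / TR))
            expected = amps[t, 0] * reg_rows[t][onset_scan : onset_scan + 10]
            assert np.max(np.abs(fir.coefficients[t, 0] - expected)) < 1e-6


class TestBlockFir:
    def test_recovers_shared_shape_under_overlap(self):
        # block-level FIR stays full rank at short SOA; with a response shape
        # whose support fits the bin window the fit is exact
        from remapkit.trialbeta import build_block_fir_design, fit_block_fir

        shape = np.array([0.0, 1.0, 2.5, 1.5, 0.6, 0.2, 0.05, 0.0, 0.0, 0.0])
        events = _events([6.0, 15.0, 24.0, 33.0], duration=4.0)
        n_scans = 30
        design = build_block_fir_design(events, n_scans, TR)
        assert np.linalg.matrix_rank(design) == 10
        amps = np.array([[1.0], [2.0]])  # two voxels, different gains
        data = (amps * (design @ shape)[None, :]).reshape(2, n_scans)
        prof = fit_block_fir(data, events, tr=TR)
        assert np.allclose(prof, amps * shape[None, :], atol=1e-9)

    def test_empty_events_rejected(self):
        from remapkit.trialbeta import build_block_fir_design

        with pytest.raises(ValueError):
            build_block_fir_design(EventTable([]), 30, TR)


class TestEmpiricalHrf:
    def test_identical_profiles_return_that_shape(self):
        shape = canonical_hrf(dt=TR).samples[:10]
        profiles = np.tile(shape, (30, 1))
        for method in ("first_pc", "infomax_ica"):
            k = extract_empirical_hrf(profiles, method=method)
            assert abs(np.corrcoef(k.samples, shape)[0, 1]) > 1 - 1e-9
            assert k.variance_explained == pytest.approx(1.0, abs=1e-9)
            assert k.samples[np.argmax(np.abs(k.samples))] > 0  # peak positive

    def test_dominant_component_selected_by_back_projected_variance(self):
        # 90% of rows carry shape A, 10% an orthogonal shape B; the returned
        # component must be A-dominated, matching the eigendecomposition oracle
        rng = np.random.default_rng(0)
        a = canonical_hrf(dt=TR).samples[:10]
        b = np.zeros(10)
        b[7] = 1.0
        b = b - (b @ a) / (a @ a) * a
        rows = [rng.uniform(0.8, 1.2) * a for _ in range(90)]
        rows += [rng.uniform(0.8, 1.2) * b for _ in range(10)]
        profiles = np.array(rows) + 0.01 * rng.standard_normal((100, 10))
        _, s, vt = np.linalg.svd(profiles, full_matrices=False)
        oracle = vt[0] * np.sign(vt[0][np.argmax(np.abs(vt[0]))])
        for method in ("first_pc", "infomax_ica"):
            k = extract_empirical_hrf(profiles, method=method, seed=1)
            assert np.corrcoef(k.samples, oracle)[0, 1] > 0.98
            assert abs(np.corrcoef(k.samples, a)[0, 1]) > abs(
                np.corrcoef(k.samples, b)[0, 1]
            )

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            extract_empirical_hrf(np.ones((1, 10)))

    def test_constant_zero_profiles_rejected(self):
        with pytest.raises(ValueError):
            extract_empirical_hrf(np.zeros((5, 10)))


class TestResampleHrf:
    def test_linear_ramp_stays_a_ramp(self):
        k = HrfKernel(samples=np.arange(6, dtype=float), dt=TR)
        fine = resample_hrf(k, bins_per_scan=4)
        t_fine = np.arange(len(fine.samples)) * fine.dt
        assert np.allclose(fine.samples, t_fine / TR, atol=1e-12)

    def test_decimation_recovers_original_exactly(self):
        k = canonical_hrf(dt=TR)
        fine = resample_hrf(k, bins_per_scan=16)
        assert np.allclose(fine.samples[::16], k.samples, atol=1e-12)
        assert fine.dt == pytest.approx(TR / 16)

    def test_upsampled_double_gamma_tracks_closed_form(self):
        # at 1 s sampling the cubic interpolant stays within 2% (max-abs,
        # relative to peak) of the directly evaluated fine-grid function
        coarse = canonical_hrf(dt=1.0)
        fine = resample_hrf(coarse, bins_per_scan=16)
        direct = canonical_hrf(dt=1.0 / 16)
        n = min(len(fine.samples), len(direct.samples))
        err = np.max(np.abs(fine.samples[:n] - direct.samples[:n]))
        assert err < 0.02 * np.max(np.abs(direct.samples))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            resample_hrf(HrfKernel(samples=np.array([0.0, 1.0, 0.5]), dt=TR))


class TestSingleTrialBetas:
    def _simulate(self, templates, n_trials_per_half, soa=9.0, noise_sd=0.0, seed=0):
        ds = simulate_trial_patterns(
            templates, n_trials_per_half=n_trials_per_half, noise_sd=0.3, seed=seed
        )
        events = make_event_tables(ds.meta, tr=TR, soa=soa)
        hrf = canonical_hrf(dt=TR / 16)
        order = _event_order(ds, events)
        runs = simulate_bold_runs(
            events, templates, hrf.samples, hrf.dt, tr=TR,
            noise_sd=noise_sd, trial_patterns=ds.matrix[order],
        )
        return ds, events, hrf, order, runs

    def test_overlapping_trials_recover_injected_patterns(self, templates_small):
        # 20 trials per run at the paper-like 9 s SOA, noise off
        ds, events, hrf, order, runs = self._simulate(templates_small, 20)
        betas = estimate_single_trial_betas(runs, events, hrf, tr=TR)
        assert np.max(np.abs(betas.matrix - ds.matrix[order])) < 1e-6

    def test_all_zero_data_gives_zero_betas(self, templates_small):
        ds, events, hrf, order, runs = self._simulate(templates_small, 5)
        zero_runs = [np.zeros_like(r) for r in runs]
        betas = estimate_single_trial_betas(zero_runs, events, hrf, tr=TR)
        assert np.allclose(betas.matrix, 0.0)

    def test_voxel_permutation_equivariance(self, templates_small):
        ds, events, hrf, order, runs = self._simulate(templates_small, 5)
        perm = np.random.default_rng(1).permutation(runs[0].shape[0])
        betas = estimate_single_trial_betas(runs, events, hrf, tr=TR)
        betas_p = estimate_single_trial_betas(
            [r[perm] for r in runs], events, hrf, tr=TR
        )
        assert np.allclose(betas_p.matrix, betas.matrix[:, perm], atol=1e-10)

    def test_uniform_scaling_scales_betas_linearly(self, templates_small):
        ds, events, hrf, order, runs = self._simulate(templates_small, 5)
        betas = estimate_single_trial_betas(runs, events, hrf, tr=TR)
        betas_s = estimate_single_trial_betas(
            [3.0 * r for r in runs], events, hrf, tr=TR
        )
        assert np.allclose(betas_s.matrix, 3.0 * betas.matrix, atol=1e-9)

    def test_impulse_model_with_response_shape_kernel(self, templates_small):
        # a kernel that already embodies the trial response, placed at onsets
        # without boxcar convolution, recovers overlapping amplitudes exactly
        shape = np.array([0.0, 1.0, 2.5, 1.5, 0.6, 0.2, 0.05, 0.0, 0.0, 0.0])
        ds = simulate_trial_patterns(templates_small, n_trials_per_half=5,
                                     noise_sd=0.3, seed=9)
        # one-sample "events": the forward boxcar covers a single kernel bin,
        # so simulation and impulse estimation share the same regressor
        events = make_event_tables(ds.meta, tr=TR, soa=9.0, duration=TR)
        order = _event_order(ds, events)
        runs = simulate_bold_runs(
            events, templates_small, shape, TR, tr=TR, noise_sd=0.0,
            trial_patterns=ds.matrix[order],
        )
        kernel = HrfKernel(samples=shape, dt=TR)
        betas = estimate_single_trial_betas(
            runs, events, kernel, tr=TR, event_model="impulse"
        )
        # impulse regressors equal the boxcar-free kernel up to the microtime
        # bin width, so betas recover amplitudes up to one global scale
        ratio = betas.matrix / ds.matrix[order]
        assert np.allclose(ratio, ratio.flat[0], atol=1e-8)

    def test_decoding_matches_ground_truth_patterns(self, templates_small):
        # pipeline consistency: estimated betas carry the same decodable
        # information as the patterns that generated the BOLD data
        from remapkit.searchlight import classify_neighborhood

        ds, events, hrf, order, runs = self._simulate(
            templates_small, 6, noise_sd=0.0, seed=3
        )
        betas = estimate_single_trial_betas(
            runs, events, hrf, tr=TR,
            voxel_coords=ds.voxel_coords, roi_labels=ds.roi_labels,
        )
        from remapkit.core import PatternDataset

        est = PatternDataset(
            betas.matrix, [r.trial for r in events.rows],
            ds.voxel_coords, ds.roi_labels,
        )
        truth = PatternDataset(
            ds.matrix[order], [r.trial for r in events.rows],
            ds.voxel_coords, ds.roi_labels,
        )
        conf_est = classify_neighborhood(est, np.arange(est.n_voxels))
        conf_truth = classify_neighborhood(truth, np.arange(truth.n_voxels))
        assert np.array_equal(conf_est.counts, conf_truth.counts)


def _event_order(dataset, events):
    key = {(t.city, t.block_half, t.triad_id): i for i, t in enumerate(dataset.meta)}
    return np.array(
        [key[(r.trial.city, r.trial.block_half, r.trial.triad_id)] for r in events.rows]
    )
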