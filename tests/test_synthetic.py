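"""Generator properties: template geometry, attenuation, attraction, BOLD forward model."""

import numpy as np
import pytest

from remapkit.core import INTERFERENCE_CITY
from remapkit.synthetic import (
    make_city_templates,
    make_event_tables,
    simulate_bold_runs,
    simulate_cohort,
    simulate_trial_patterns,
)


def _pairwise_corr(a, b):
    return float(np.corrcoef(a, b)[0, 1])


class TestCityTemplates:
    def test_independent_templates_near_orthogonal(self):
        t = make_city_templates(100, separation=1.0, attraction_mix=0.0, seed=1)
        c = np.corrcoef(t.templates)
        off = c[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.35)  # |r| ~ O(1/sqrt(100)) for independent draws

    def test_full_attraction_mix_aligns_city3_with_similar_mean(self):
        t = make_city_templates(100, separation=1.0, attraction_mix=1.0, seed=2)
        m = 0.5 * (t.template(1) + t.template(2))
        assert _pairwise_corr(t.template(3), m) > 0.99

    def test_half_attraction_mix_matches_closed_form(self):
        # unit-norm mixture of orthogonal components: corr = lam/sqrt(lam^2+(1-lam)^2)
        lam = 0.5
        expected = lam / np.sqrt(lam**2 + (1 - lam) ** 2)
        t = make_city_templates(10000, separation=1.0, attraction_mix=lam, seed=3)
        m = 0.5 * (t.template(1) + t.template(2))
        assert _pairwise_corr(t.template(3), m) == pytest.approx(expected, abs=0.03)

    def test_half_attraction_closed_form_against_resampling_oracle(self):
        # brute-force oracle: rebuild the mixture from fresh orthogonalized draws
        lam, n = 0.35, 2000
        rng = np.random.default_rng(4)
        rs = []
        for _ in range(50):
            m = rng.standard_normal(n)
            u = rng.standard_normal(n)
            u -= u @ m / (m @ m) * m  # exactly orthogonal
            mix = lam * m / np.linalg.norm(m) + (1 - lam) * u / np.linalg.norm(u)
            rs.append(_pairwise_corr(mix, m))
        expected = lam / np.sqrt(lam**2 + (1 - lam) ** 2)
        assert np.mean(rs) == pytest.approx(expected, abs=0.01)

    def test_separation_dials_between_city_correlation(self):
        for sep in (0.25, 0.5, 0.75):
            t = make_city_templates(5000, separation=sep, seed=5)
            assert _pairwise_corr(t.template(1), t.template(2)) == pytest.approx(
                1 - sep, abs=0.05
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_voxels": 1},
            {"attraction_mix": -0.1},
            {"attraction_mix": 1.5},
            {"separation": 2.0},
        ],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            make_city_templates(**{"n_voxels": 100, **kwargs})

    def test_deterministic_given_seed(self):
        a = make_city_templates(50, seed=9).templates
        b = make_city_templates(50, seed=9).templates
        c = make_city_templates(50, seed=10).templates
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestTrialPatterns:
    def test_noise_free_rows_equal_city_templates(self, templates_small, dataset_clean):
        for i, spec in enumerate(dataset_clean.meta):
            assert np.allclose(
                dataset_clean.matrix[i], templates_small.template(spec.city)
            )

    def test_full_attraction_marks_all_city3_trials(self, templates_small):
        ds = simulate_trial_patterns(templates_small, p_attract=1.0, seed=21)
        c3 = [t for t in ds.meta if t.city == INTERFERENCE_CITY]
        assert all(t.attracted_to in (1, 2) and not t.correct for t in c3)
        others = [t for t in ds.meta if t.city != INTERFERENCE_CITY]
        assert all(t.correct for t in others)

    def test_negative_noise_rejected(self, templates_small):
        with pytest.raises(ValueError):
            simulate_trial_patterns(templates_small, noise_sd=-1.0)

    def test_attenuation_matches_analytic_formula(self):
        # within-city pair correlation ~= 1/(1 + noise_sd^2 * V / |T|^2),
        # checked against >10k Monte-Carlo pairs
        n_vox, noise_sd = 500, 1.0
        tpl = make_city_templates(n_vox, seed=22)
        ds = simulate_trial_patterns(
            tpl, n_trials_per_half=40, noise_sd=noise_sd, seed=23
        )
        rs = []
        for city in (1, 2, 3, 4):
            idx = ds.trial_indices(city=city)
            x = ds.matrix[idx]
            xc = x - x.mean(axis=1, keepdims=True)
            xn = xc / np.linalg.norm(xc, axis=1, keepdims=True)
            c = xn @ xn.T
            rs.append(c[np.triu_indices_from(c, 1)])
        rs = np.concatenate(rs)
        assert len(rs) > 10000
        expected = 1.0 / (1.0 + noise_sd**2 * n_vox)
        assert rs.mean() == pytest.approx(expected, abs=3e-3)

    def test_attenuation_monotone_in_noise(self, templates_small):
        means = []
        for noise_sd in (0.1, 0.3, 0.6, 1.2):
            ds = simulate_trial_patterns(
                templates_small, n_trials_per_half=20, noise_sd=noise_sd, seed=24
            )
            idx = ds.trial_indices(city=1)
            x = ds.matrix[idx]
            xc = x - x.mean(axis=1, keepdims=True)
            xn = xc / np.linalg.norm(xc, axis=1, keepdims=True)
            c = xn @ xn.T
            means.append(c[np.triu_indices_from(c, 1)].mean())
        assert np.all(np.diff(means) < 0)

    def test_attracted_trials_resemble_similar_city_templates(self, templates_small):
        ds = simulate_trial_patterns(
            templates_small, n_trials_per_half=20, noise_sd=0.5, p_attract=0.5, seed=25
        )
        sim_mean = 0.5 * (templates_small.template(1) + templates_small.template(2))
        attracted, stable = [], []
        for i, t in enumerate(ds.meta):
            if t.city != INTERFERENCE_CITY:
                continue
            target = templates_small.template(t.attracted_to) if t.attracted_to else sim_mean
            r = _pairwise_corr(ds.matrix[i], target)
            (attracted if t.attracted_to else stable).append(r)
        assert np.mean(attracted) > np.mean(stable)

    def test_response_sides_swap_between_halves(self, dataset_clean):
        # motor-response control: the same triad has opposite correct sides in A vs B
        by_key = {}
        for t in dataset_clean.meta:
            by_key[(t.city, t.triad_id, t.block_half)] = t.response_side
        for (city, tid, half), side in by_key.items():
            if half == "A":
                assert by_key[(city, tid, "B")] != side

    def test_triad_pools_shared_and_disjoint(self, dataset_clean):
        pools = {
            c: {t.triad_id for t in dataset_clean.meta if t.city == c}
            for c in (1, 2, 3, 4)
        }
        assert pools[1] == pools[2] == pools[3]
        assert pools[4].isdisjoint(pools[1])

    def test_deterministic_given_seed(self, templates_small):
        a = simulate_trial_patterns(templates_small, noise_sd=0.4, p_attract=0.3, seed=8)
        b = simulate_trial_patterns(templates_small, noise_sd=0.4, p_attract=0.3, seed=8)
        assert np.array_equal(a.matrix, b.matrix)
        assert a.meta == b.meta

    def test_grid_embedding_labels_roi_block(self, templates_small):
        ds = simulate_trial_patterns(
            templates_small, noise_sd=0.1, seed=26,
            grid_shape=(6, 5, 4), roi_block=(5, 4, 3),
        )
        assert ds.n_voxels == 6 * 5 * 4
        assert int(np.sum(ds.roi_labels == 1)) == 60
        # signal lives only in the ROI block
        roi = ds.roi_voxels(1)
        out = np.flatnonzero(ds.roi_labels == 0)
        assert np.std(ds.matrix[:, roi].mean(axis=0)) > np.std(
            ds.matrix[:, out].mean(axis=0)
        )


class TestBoldForwardModel:
    def test_single_trial_series_is_template_times_regressor(self, templates_small):
        from remapkit.synthetic import convolved_regressor

        ds = simulate_trial_patterns(templates_small, n_trials_per_half=1, seed=30,
                                     noise_sd=0.0)
        events = make_event_tables(ds.meta[:1], tr=3.0)
        hrf = np.array([0.0, 1.0, 0.6, 0.2])
        runs = simulate_bold_runs(events, templates_small, hrf, 3.0, tr=3.0)
        n_scans = runs[0].shape[1]
        reg = convolved_regressor(6.0, 4.0, hrf, 3.0, n_scans, 3.0)
        expected = np.outer(templates_small.template(ds.meta[0].city), reg)
        assert np.allclose(runs[0], expected)

    def test_zero_templates_give_pure_noise(self, templates_small):
        from remapkit.core import CityTemplateSet

        zero = CityTemplateSet(
            templates=np.zeros((4, 60)), n_voxels=60, separation=1.0,
            attraction_mix=0.0, seed=0,
        )
        ds = simulate_trial_patterns(templates_small, n_trials_per_half=4, seed=31)
        events = make_event_tables(ds.meta, tr=3.0)
        runs = simulate_bold_runs(
            events, zero, np.array([0, 1.0, 0.5, 0.1]), 3.0, noise_sd=2.0, seed=5
        )
        sd = np.std(np.concatenate([r.ravel() for r in runs]))
        assert sd == pytest.approx(2.0, rel=0.05)

    def test_superposition_of_event_sets(self, templates_small):
        # simulated BOLD of concatenated events equals the sum of separately
        # simulated signals (linearity, noise off)
        ds = simulate_trial_patterns(templates_small, n_trials_per_half=2, seed=32,
                                     noise_sd=0.0)
        meta = [t for t in ds.meta if t.city == 1]
        events = make_event_tables(meta, tr=3.0, soa=9.0).for_run(0)
        hrf = np.array([0.0, 1.0, 0.6, 0.2])
        full = simulate_bold_runs(events, templates_small, hrf, 3.0)[0]
        parts = []
        for row in events.rows:
            from remapkit.core import EventTable

            single = EventTable([row])
            part = simulate_bold_runs(single, templates_small, hrf, 3.0)[0]
            parts.append(np.pad(part, ((0, 0), (0, full.shape[1] - part.shape[1]))))
        assert np.allclose(full, sum(parts))

    def test_empty_events_rejected(self, templates_small):
        from remapkit.core import EventTable

        with pytest.raises(ValueError):
            simulate_bold_runs(
                EventTable([]), templates_small, np.array([0, 1.0]), 3.0
            )


class TestCohort:
    def test_no_attraction_means_ceiling_behavior(self):
        cohort = simulate_cohort(
            n_subjects=3, p_attract_range=(0.0, 0.0), n_voxels=40,
            lapse_rate=0.0, seed=40,
        )
        for subj in cohort:
            assert all(acc == 1.0 for acc in subj.behavior.values())

    def test_city3_behavior_tracks_attraction_rate(self):
        cohort = simulate_cohort(
            n_subjects=12, p_attract_range=(0.0, 0.6), n_voxels=40,
            lapse_rate=0.0, seed=41,
        )
        p = np.array([s.p_attract for s in cohort])
        acc3 = np.array([s.behavior[3] for s in cohort])
        # behavioral accuracy = 1 - p_attract up to binomial noise at n=40
        assert np.all(np.abs(acc3 - (1 - p)) < 0.25)
        assert np.corrcoef(p, acc3)[0, 1] < -0.8

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(n_subjects=1)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(n_subjects=3, p_attract_range=(0.7, 0.2))
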