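import pytest

from remapkit.synthetic import make_city_templates, simulate_trial_patterns


@pytest.fixture(scope="session")
def templates_small():
    """Four near-orthogonal unit-norm templates over 60 voxels."""
    return make_city_templates(n_voxels=60, separation=1.0, attraction_mix=0.0, seed=7)


@pytest.fixture(scope="session")
def dataset_clean(templates_small):
    """Noise-free four-city dataset: every row equals its city's template."""
    return simulate_trial_patterns(
        templates_small, n_trials_per_half=10, noise_sd=0.0, p_attract=0.0, seed=11
    )


@pytest.fixture(scope="session")
def dataset_noisy(templates_small):
    """Moderate-noise dataset in the default regime (no attraction)."""
    return simulate_trial_patterns(
        templates_small, n_trials_per_half=10, noise_sd=0.35, p_attract=0.0, seed=13
    )


@pytest.fixture(scope="session")
def dataset_interference(templates_small):
    """Dataset with attraction errors and an unstable City 3 code."""
    return simulate_trial_patterns(
        templates_small,
        n_trials_per_half=20,
        noise_sd=0.35,
        p_attract=0.4,
        c3_stability=0.1,
        seed=17,
    )
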