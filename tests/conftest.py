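import pytest

from olfbilat import (
    ModelConfig,
    build_response_matrix,
    generate_glomerular_panel,
    generate_ground_truth_tuning,
    generate_session_design,
    generate_trials,
)


@pytest.fixture(scope="session")
def schedule():
    """The study design: 15 odors + blank, 2 sides, 7 repetitions."""
    return generate_session_design(seed=11)


@pytest.fixture(scope="session")
def high_snr_session(schedule):
    """Strong responses (magnitudes far above Poisson noise) with 40% BCNs."""
    tuning = generate_ground_truth_tuning(
        150, bcn_fraction=0.4, slope=0.8, magnitude_scale_hz=14.0, seed=21
    )
    recording = generate_trials(tuning, schedule, seed=22)
    return tuning, recording


@pytest.fixture(scope="session")
def high_snr_matrix(high_snr_session):
    _, recording = high_snr_session
    return build_response_matrix(recording)


@pytest.fixture(scope="session")
def panel():
    return generate_glomerular_panel(155, 15, similarity_target=0.3, seed=31)


@pytest.fixture(scope="session")
def small_model_config():
    """Reduced cortex size; alpha fits are insensitive to this (tested)."""
    return ModelConfig(n_neurons=2000, seed=41)
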