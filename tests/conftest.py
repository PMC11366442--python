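import numpy as np
import pytest

from ldcnn import (
    MITBIH5,
    PTB2,
    SyntheticConfig,
    default_templates,
    generate_record,
    generate_segment_table,
)


@pytest.fixture(scope="session")
def templates5():
    """Five-class morphology bank at 360 Hz."""
    return default_templates(MITBIH5, sampling_rate=360.0)


@pytest.fixture(scope="session")
def templates2():
    """Binary morphology bank at 125 Hz (187-sample window regime)."""
    return default_templates(PTB2, sampling_rate=125.0)


@pytest.fixture(scope="session")
def clean_config():
    """Interference-free generator settings (the zero-noise oracle regime)."""
    return SyntheticConfig(
        n_beats=100,
        noise_sd=0.0,
        baseline_wander_amplitude=0.0,
        powerline_amplitude=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_record(clean_config, templates5):
    return generate_record(clean_config, templates5)


@pytest.fixture(scope="session")
def noisy_record(templates5):
    cfg = SyntheticConfig(n_beats=120, noise_sd=0.05, seed=5)
    return generate_record(cfg, templates5)


@pytest.fixture(scope="session")
def small_table5(templates5):
    """Balanced-ish 5-class segmented table, light noise, 360-sample windows."""
    cfg = SyntheticConfig(
        n_beats=250,
        class_proportions={c: 0.2 for c in MITBIH5.classes},
        noise_sd=0.02,
        baseline_wander_amplitude=0.0,
        powerline_amplitude=0.0,
        seed=21,
    )
    return generate_segment_table(cfg, templates5, 360, MITBIH5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
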