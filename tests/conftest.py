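import numpy as np
import pytest

from eegmvpa.design import generate_design
from eegmvpa.synth import EffectSpec, SynthConfig, generate_subject

# a short epoch keeps unit tests fast: 300 raw samples -> 60 bins of 5 ms
SHORT_WINDOW = (-100.0, 199.0)
SHORT_BASELINE = (-100.0, 0.0)


@pytest.fixture(scope="session")
def design():
    return generate_design()


@pytest.fixture(scope="session")
def null_dataset(design):
    """One subject of pure AR(1) noise (no planted effects), 60 bins."""
    cfg = SynthConfig(n_subjects=1, epoch_window=SHORT_WINDOW, seed=101)
    return generate_subject(design, cfg, 1)


@pytest.fixture(scope="session")
def planted_dataset(design):
    """One subject with a strong occipital car-category transient at 105 ms."""
    eff = EffectSpec(
        dimension="category", level="car", spatial_pattern="occipital",
        onset_ms=105.0, width_ms=5.0, amplitude=25.0,
    )
    cfg = SynthConfig(n_subjects=1, epoch_window=SHORT_WINDOW, effects=(eff,), seed=202)
    return generate_subject(design, cfg, 1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
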