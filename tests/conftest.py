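import numpy as np
import pytest

from tensorcardiography import presets, synth
from tensorcardiography.fitting import BeatFiducials


@pytest.fixture(scope="session")
def separate_mean_model():
    """Population-mean RT-separate beat model (lead II, healthy adults)."""
    return presets.beat_model_from_intervals(presets.SEPARATE_ALL_AVE,
                                             "separate")


@pytest.fixture(scope="session")
def bulk_mean_model():
    """Population-mean RT-bulk beat model."""
    return presets.beat_model_from_intervals(presets.BULK_ALL_AVE, "bulk")


@pytest.fixture(scope="session")
def ers_a1_model():
    """First 10-beat block of the ERS case (complete bulk parameter set)."""
    return presets.beat_model_from_intervals(presets.ERS_BEAT_BLOCKS["A1"],
                                             "bulk")


@pytest.fixture
def beat_factory():
    """Synthesize a beat and return (t, y, fiducials, truth)."""

    def make(model, fs=1000.0, noise_sd=0.0, seed=None):
        rng = np.random.default_rng(seed) if seed is not None else None
        y, truth = synth.synthesize_beat(model, fs=fs, noise_sd=noise_sd,
                                         rng=rng)
        t = np.arange(len(y)) * 1000.0 / fs
        return t, y, BeatFiducials.from_truth(truth), truth

    return make
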