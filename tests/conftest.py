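import numpy as np
import pytest

from leafvi import phantom, validation

#: Study conditions for the surrogate validation batch: 20 scenes on a
#: 128x128 canvas, 204 bands, reflectance noise sd 0.005, shadow enabled.
BATCH_KW = dict(size=(128, 128), bands=204, noise_sd=0.005, shadow=True)
BATCH_SEED = 42


@pytest.fixture(scope="session")
def phantom_batch():
    return phantom.scene_batch(20, BATCH_SEED, **BATCH_KW)


@pytest.fixture(scope="session")
def paired_tables(phantom_batch):
    """(reference_df, candidate_df) of jitter-reference vs auto ROI VI values."""
    return validation.paired_roi_table(phantom_batch, seed=BATCH_SEED)


@pytest.fixture(scope="session")
def noiseless_scene():
    spec = phantom.sample_spec(7, size=(96, 96), bands=204, noise_sd=0.0, shadow=True)
    return phantom.build_scene(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
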