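import numpy as np
import pytest

from hypertender import SceneSpec, calibrate_reflectance, render_sample


@pytest.fixture(scope="session")
def default_scene():
    """One default-parameter rendered acquisition, shared across tests."""
    spec = SceneSpec(seed=11)
    cube, refs, truth = render_sample(1, spec, sample_id="S01")
    return spec, cube, refs, truth


@pytest.fixture(scope="session")
def calibrated_scene(default_scene):
    spec, cube, refs, truth = default_scene
    return spec, calibrate_reflectance(cube, refs), refs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
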