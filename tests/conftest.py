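import numpy as np
import pytest
from hypothesis import settings

import transloquant as tq
from transloquant.io import scene_roi_set

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_optics():
    return tq.Optics(wavelength_em=610.0, numerical_aperture=1.45, pixel_size=100.0)


@pytest.fixture(scope="session")
def pm_scene():
    """One default plasma-membrane scene with rising kinetics."""
    return tq.simulate_cell_scene(tq.SceneParams(seed=1), tq.TranslocationKinetics())


@pytest.fixture(scope="session")
def pm_rois(pm_scene):
    return scene_roi_set(pm_scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
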