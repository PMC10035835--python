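import numpy as np
import pytest

from kelpcanopy.io import PipelineConfig
from kelpcanopy.pipeline import run_pipeline
from kelpcanopy.scene import KELP, LAND, SEAWATER, SceneTruth
from kelpcanopy.simulate import generate_scene, generate_spectral_library, make_domain


@pytest.fixture(scope="session")
def library():
    return generate_spectral_library(1)


@pytest.fixture(scope="session")
def domain():
    return make_domain(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_truth(kelp_fraction, tide_height=0.5, water_region=None):
    """Truth raster helper: kelp where fraction > 0, seawater elsewhere."""
    f = np.asarray(kelp_fraction, dtype=float)
    cls = np.where(f > 0, KELP, SEAWATER).astype(np.uint8)
    return SceneTruth(
        kelp_fraction=f, class_map=cls, tide_height=tide_height,
        water_region=water_region,
    )


@pytest.fixture(scope="session")
def simple_scene(library):
    """A 10x10 noiseless scene: kelp block, seawater, one land column."""
    f = np.zeros((10, 10))
    f[2:5, 4:8] = 0.5
    cls = np.where(f > 0, KELP, SEAWATER).astype(np.uint8)
    cls[:, 0] = LAND
    truth = SceneTruth(kelp_fraction=f, class_map=cls, tide_height=0.3)
    scene = generate_scene(truth, library, noise_sd=0.0, seed=3)
    return scene, truth


@pytest.fixture(scope="session")
def pipeline_run():
    """One full archive run shared across end-to-end tests."""
    return run_pipeline(PipelineConfig(seed=1))
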