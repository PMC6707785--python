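import numpy as np
import pytest

from imclesion.pipeline import preprocess_roi, quantify_roi
from imclesion.synthetic import SceneConfig, gates_from_intensity_model, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """One active-lesion-center scene under the default noise model."""
    cfg = SceneConfig(seed=1)
    image, truth = generate_scene(cfg)
    return cfg, image, truth


@pytest.fixture(scope="session")
def noiseless_scene():
    """Same composition, shot noise and speckles disabled."""
    cfg = SceneConfig(seed=2, poisson_noise=False, speckle_rate=0.0)
    image, truth = generate_scene(cfg)
    return cfg, image, truth


def _run(cfg, image, truth):
    _, _, _, _, stats = preprocess_roi(image, truth.roi)
    gates = gates_from_intensity_model(cfg, stats)
    return quantify_roi(image, truth.roi, gates), gates


@pytest.fixture(scope="session")
def default_result(default_scene):
    cfg, image, truth = default_scene
    result, gates = _run(cfg, image, truth)
    return cfg, truth, result, gates


@pytest.fixture(scope="session")
def noiseless_result(noiseless_scene):
    cfg, image, truth = noiseless_scene
    result, gates = _run(cfg, image, truth)
    return cfg, truth, result, gates


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
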