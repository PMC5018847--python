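import numpy as np
import pytest

from nestcam.pipeline import RunConfig, analyze_scene
from nestcam.synthetic import SceneTruth, make_scene


@pytest.fixture(scope="session")
def default_scene():
    """One full-scale rendered nest scene shared across tests."""
    scene, mask, truth = make_scene(SceneTruth(seed=42))
    return scene, mask, truth


@pytest.fixture(scope="session")
def default_record(default_scene):
    scene, mask, _ = default_scene
    record, artifacts = analyze_scene(scene, mask, RunConfig(), nest_id="n42", species="plover", crop=False)
    return record, artifacts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
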