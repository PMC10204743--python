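import numpy as np
import pytest

from alaem import random_scene, render_scene


@pytest.fixture(scope="session")
def rendered_scene():
    """One deterministic 20-leaf non-overlapping scene plus ground truth."""
    scene = random_scene(n_leaves=20, seed=7)
    image, gt = render_scene(scene)
    return scene, image, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
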