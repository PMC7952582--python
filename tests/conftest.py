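import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from organoquant import SceneParams, render_scene


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic scene with ground truth (rendered once)."""
    return render_scene(SceneParams(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_masks(rng):
    """A batch of small random binary masks with mixed densities."""
    masks = []
    for density in (0.2, 0.4, 0.6):
        for _ in range(10):
            masks.append(rng.random((32, 32)) < density)
    return masks
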