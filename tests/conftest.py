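import numpy as np
import pytest

from fluorocell.synth import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20240106)


@pytest.fixture
def small_spec():
    return SceneSpec(height=96, width=96, n_cells_lambda=4.0,
                     semi_axis_range=(6.0, 10.0))


@pytest.fixture
def small_scene(small_spec):
    return generate_scene(small_spec, np.random.default_rng(7))


def gt_masks_of(scene):
    return [scene.instance_mask == lab
            for lab in range(1, scene.instance_mask.max() + 1)]
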