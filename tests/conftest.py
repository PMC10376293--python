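import numpy as np
import pytest

from cstdnet.data import SceneParams, synth_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_scene_params():
    """Desk-scale scene conditions: 64-px frames with 1-2 small faces."""
    return SceneParams(
        image_size=(64, 64), n_faces=(1, 2), face_side_range=(10.0, 24.0),
        cluster_prob=0.3, illumination_range=(0.8, 1.0), noise_sd=2.0, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_scenes(tiny_scene_params):
    """Eight annotated synthetic scenes, fixed seeds."""
    from dataclasses import replace

    return [synth_scene(replace(tiny_scene_params, seed=tiny_scene_params.seed + i))
            for i in range(8)]


def random_box(rng, lo=0.0, hi=64.0, min_side=1.0, max_side=30.0):
    w = rng.uniform(min_side, max_side)
    h = rng.uniform(min_side, max_side)
    cx = rng.uniform(lo + w / 2, hi - w / 2)
    cy = rng.uniform(lo + h / 2, hi - h / 2)
    return np.array([cx, cy, w, h])
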