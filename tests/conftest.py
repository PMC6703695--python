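"""Shared fixtures: small synthetic scenes and a trained classifier.

Everything is generated programmatically at test time; the scenes are tiny
relative to the defaults so the whole suite stays fast.
"""

import numpy as np
import pytest

from envseg import (SceneSpec, SegmentationParams, generate_scene,
                    train_classifier, training_table_from_labels)


def scene_params(**overrides):
    """Segmentation variables matched to the synthetic scene conditions."""
    base = dict(seed_threshold=60.0, min_volume=100.0, max_volume=2000.0,
                max_jump=3)
    base.update(overrides)
    return SegmentationParams(**base)


@pytest.fixture(scope="session")
def small_scene():
    """A 12-nucleus densely touching scene with exact ground truth."""
    spec = SceneSpec(n_nuclei=12, field_um=(60.0, 60.0, 28.0),
                     crowding="touching", seed=3)
    vol, gt = generate_scene(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def small_params():
    return scene_params()


@pytest.fixture(scope="session")
def small_classifier(small_scene, small_params):
    _, vol, gt = small_scene
    rng = np.random.default_rng(0)
    table = training_table_from_labels(vol, gt, rng, n_valid=10, n_invalid=10,
                                       params=small_params)
    return train_classifier(table)


@pytest.fixture(scope="session")
def shell_plane():
    """A drawn circular shell: radius 12 px, ~2 px thick, on background 10."""
    from skimage.draw import circle_perimeter
    import scipy.ndimage as ndi

    plane = np.full((64, 64), 10.0)
    rr, cc = circle_perimeter(32, 32, 12)
    plane[rr, cc] = 200.0
    plane = ndi.grey_dilation(plane, size=2)
    return plane
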