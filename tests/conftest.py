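import numpy as np
import pytest

from skyfilter import BlobSvmDetector, SceneSpec, generate_scene
from skyfilter.occupancy_filter import SmallConvNetFilter, make_patch_dataset


def easy_spec(seed, n_birds, size=720, gsd=0.3, **kw):
    """The easy study regime: fine GSD, strong contrast, calm sea, no glare."""
    return SceneSpec(width_px=size, height_px=size, gsd_cm=gsd,
                     n_birds=n_birds, bird_contrast=0.5, sea_state=0.15,
                     glare_fraction=0.0, seed=seed, **kw)


@pytest.fixture(scope="session")
def easy_train_scenes():
    """Eight 720x720 training scenes at GSD 0.3 cm, alternating empty and
    4-bird occupancy."""
    return [generate_scene(easy_spec(seed=s, n_birds=0 if s % 2 else 4))
            for s in range(8)]


@pytest.fixture(scope="session")
def trained_detector(easy_train_scenes):
    occupied = [s for s in easy_train_scenes if s.gt_boxes]
    det = BlobSvmDetector(random_state=0)
    det.fit([s.image for s in occupied], [s.gt_boxes for s in occupied])
    return det


@pytest.fixture(scope="session")
def trained_filter(easy_train_scenes):
    patches, labels = make_patch_dataset(
        [s.image for s in easy_train_scenes],
        [s.gt_boxes for s in easy_train_scenes],
        n_augments=2, seed=0)
    return SmallConvNetFilter(random_state=0).fit(patches, labels)
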