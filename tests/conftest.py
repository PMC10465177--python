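import numpy as np
import pytest
from skimage.transform import resize

from organoidaug import make_dataset
from organoidaug.synthetic import SYNTHETIC_GROUPS, ExpertProfile


def downscale(img, size):
    out = resize(np.asarray(img, dtype=float), (size, size), preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def downscale_mask(mask, size):
    out = resize(np.asarray(mask, dtype=float), (size, size), preserve_range=True, order=0)
    return (out > 0.5).astype(np.uint8)


@pytest.fixture(scope="session")
def organoid_stack_64():
    """Eight generated organoid images at 64x64, as a (8, 64, 64) uint8 stack."""
    data = make_dataset(8, seed=1)
    return np.stack([downscale(img, 64) for img, _ in data])


@pytest.fixture(scope="session")
def textured_fixture():
    """A fixed textured image for blur-index calibration sweeps."""
    rng = np.random.default_rng(7)
    base = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
    return base


@pytest.fixture(scope="session")
def uniform_profiles():
    """Eight identical expert profiles with fp probability 0.3 on every group."""
    return [
        ExpertProfile(
            expert_id=f"expert_{i}",
            fp_prob_by_group={g: 0.3 for g in SYNTHETIC_GROUPS},
            fn_prob=0.05,
        )
        for i in range(8)
    ]


@pytest.fixture(scope="session")
def full_session_images():
    """40 originals + 40 images per loss group: (image_id, group) labels."""
    images = [(f"orig_{i:03d}", "original") for i in range(40)]
    for group in SYNTHETIC_GROUPS:
        images.extend((f"{group}_{i:03d}", group) for i in range(40))
    return images
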