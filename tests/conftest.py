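import numpy as np
import pytest

import vineprep as vp


@pytest.fixture(scope="session")
def leaf_classes():
    return vp.default_classes()


@pytest.fixture(scope="session")
def small_samples(leaf_classes):
    """Two 96x96 samples per class, shared across tests."""
    return vp.generate_dataset(leaf_classes, 2, 96, 96, seed=5)


@pytest.fixture(scope="session")
def small_collection(small_samples):
    """The shared samples wrapped as a labeled raw collection."""
    return [
        vp.RawImage(image=s.image, label=s.label, name=f"s{i}", mask=s.mask)
        for i, s in enumerate(small_samples)
    ]


def random_segmented(rng, h, w, density=0.4):
    """Random exact-black-background image for warp/patch property tests."""
    img = rng.integers(1, 256, size=(h, w, 3), dtype=np.int64).astype(np.uint8)
    mask = rng.random((h, w)) < density
    img[~mask] = 0
    return img
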