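import numpy as np
import pytest

from leukonet import (GeneratorConfig, ImageSample, default_class_specs,
                      generate_samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return ImageSample(rng.random((32, 32, 3), dtype=np.float32))


@pytest.fixture(scope="session")
def small_dataset():
    """15 classes x 6 images at 32x32 (fast; enough to exercise plumbing)."""
    cfg = GeneratorConfig(specs=default_class_specs(), images_per_class=6,
                          image_size=32, seed=99)
    return generate_samples(cfg)


@pytest.fixture(scope="session")
def myeloblast_images_56():
    """A single-class batch at the 56x56 scaled-down working size."""
    spec = tuple(s for s in default_class_specs() if s.label == "myeloblast")
    cfg = GeneratorConfig(specs=spec, images_per_class=40, image_size=56, seed=7)
    from leukonet import as_array
    return as_array(generate_samples(cfg))
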