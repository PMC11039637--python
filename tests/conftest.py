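import numpy as np
import pytest

from lesionforge import LesionSpec, generate_dataset, generate_lesion
from lesionforge.preprocess import PreprocessConfig


@pytest.fixture(scope="session")
def base_spec():
    return LesionSpec(height=64, width=64, foreground_fraction=0.20, seed=7)


@pytest.fixture(scope="session")
def clean_image(base_spec):
    return generate_lesion(base_spec)


@pytest.fixture(scope="session")
def pre_cfg():
    return PreprocessConfig(target_height=64, target_width=64)


@pytest.fixture(scope="session")
def small_dataset():
    """20 segmentation images, 64x64, 20% lesions."""
    return generate_dataset(20, [LesionSpec(height=64, width=64)], seed=5)


def class_images(n, fraction, class_id, seed, size=32):
    """Images of one synthetic class; class identity is lesion size."""
    spec = LesionSpec(height=size, width=size, foreground_fraction=fraction,
                      class_id=class_id)
    return generate_dataset(n, [spec], seed=seed)
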