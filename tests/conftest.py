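"""Shared fixtures: small phantom sets and canonical geometric masks."""

import numpy as np
import pytest

from regionbow import phantoms


@pytest.fixture(scope="session")
def small_dataset():
    """12 phantoms (3 classes x 4), enough for stage-level tests."""
    return phantoms.generate_dataset(phantoms.default_spec(seed=3), 4)


@pytest.fixture(scope="session")
def disk():
    """Radius-20 disk mask centered in a 101x101 image, plus its center."""
    yy, xx = np.mgrid[0:101, 0:101]
    mask = (yy - 50) ** 2 + (xx - 50) ** 2 <= 20**2
    return mask, (50.0, 50.0)


@pytest.fixture(scope="session")
def tiny_config():
    """Reduced vocabulary sizes so unit tests stay fast."""
    from regionbow.pipeline import PipelineConfig

    return PipelineConfig(k_tumor=20, k_margin=10, max_fit_patches=5000, seed=11)
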