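import numpy as np
import pytest

from radbiopsy.io import ImageVolume, SegmentationMask
from radbiopsy.synthetic import SyntheticCohortConfig, generate_cohort, generate_subject


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort configuration used where grid size is immaterial."""
    return SyntheticCohortConfig(
        n_positive=5,
        n_negative=6,
        grid_shape=(48, 48, 48),
        lesion_radius_range=(7.0, 9.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_case():
    """One default-geometry subject, negative class."""
    return generate_subject(SyntheticCohortConfig(), "negative", seed=5)


def random_lesion(rng, shape=(10, 10, 10), density=0.6, n_levels=4):
    """A random quantized lesion grid: levels 1..n_levels inside, 0 outside."""
    mask = rng.random(shape) < density
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    q = np.zeros(shape, dtype=np.int32)
    q[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return q


def volume_from(values, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(values=np.asarray(values, dtype=float), spacing=spacing)


def mask_from(values, spacing=(1.0, 1.0, 1.0)):
    return SegmentationMask(values=np.asarray(values, dtype=bool), spacing=spacing)
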