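import numpy as np
import pytest

from temporalign import synthdata as sd
from temporalign.volume import binary_mask


@pytest.fixture(scope="session")
def ball_mask():
    """Voxelized ball, radius 10 voxels (genus 0)."""
    x = np.arange(-14, 15)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    return binary_mask(X ** 2 + Y ** 2 + Z ** 2 <= 10 ** 2)


@pytest.fixture(scope="session")
def torus_mask():
    """Voxelized solid torus (genus 1), major radius 9, minor radius 4."""
    x = np.arange(-16, 17)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    ring = np.sqrt(X ** 2 + Y ** 2) - 9.0
    return binary_mask(ring ** 2 + Z ** 2 <= 4.0 ** 2)


@pytest.fixture(scope="session")
def small_cohort():
    """Four deformed subjects on a level-3 sphere (fast alignment fixture)."""
    return sd.make_cohort(sd.CohortSpec(n_subjects=4, level=3, seed=11))


@pytest.fixture(scope="session")
def phantom():
    """Default folded two-tissue phantom with truth masks."""
    return sd.make_volume_phantom(sd.PhantomSpec(seed=3))
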