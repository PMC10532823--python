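import numpy as np
import pytest

from parcale.ale import GridSpec, make_mni_grid


@pytest.fixture(scope="session")
def tiny_grid() -> GridSpec:
    """5x5x5 fully-masked 2 mm lattice centered at the origin."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = [-4.0, -4.0, -4.0]
    return GridSpec(
        shape=(5, 5, 5), affine=affine, voxel_size=2.0, mask=np.ones((5, 5, 5), bool)
    )


@pytest.fixture(scope="session")
def coarse_grid() -> GridSpec:
    """8 mm brain-envelope grid: cheap enough for permutation tests."""
    return make_mni_grid(8.0)


@pytest.fixture(scope="session")
def sim_grid() -> GridSpec:
    """4 mm brain-envelope grid used by the simulation studies."""
    return make_mni_grid(4.0)
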