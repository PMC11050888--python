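import numpy as np
import pytest
from hypothesis import settings

import pulptherm as pt

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def library():
    return pt.default_library()


@pytest.fixture(scope="session")
def coarse_params():
    """Fast 0.5 mm phantom for solver behaviour tests."""
    return pt.PhantomParams(voxel_size=0.5)


@pytest.fixture(scope="session")
def coarse_intact(coarse_params):
    return pt.build_phantom(coarse_params)


@pytest.fixture(scope="session")
def coarse_restored(coarse_intact):
    return pt.carve_and_fill(
        coarse_intact, pt.CavityDesign.default("direct_access")
    )


@pytest.fixture(scope="session")
def default_intact():
    """Default-resolution (0.25 mm) intact phantom."""
    return pt.build_phantom(pt.PhantomParams())


@pytest.fixture(scope="session")
def fine_intact():
    """Fine-resolution (0.125 mm) intact phantom for volume calibration."""
    return pt.build_phantom(pt.PhantomParams(voxel_size=0.125))


@pytest.fixture(scope="session")
def comparative_run():
    """The four-design comparative study at default resolution.

    Computed once per session; feeds both the qualitative-ordering checks
    and the maximum-principle checks on realistic phantoms.
    """
    runs, summary = pt.compare_designs()
    return runs, summary


def random_small_grid(rng: np.random.Generator, shape=(4, 4, 4)):
    """A random labelled grid (may contain any tissue, with composite
    guaranteed to touch the exterior) for assembly oracle checks."""
    labels = rng.integers(0, 5, size=shape).astype(np.int8)
    labels[0, 0, 0] = pt.COMPOSITE  # ensure an exterior source face
    return pt.TissueLabelGrid(
        labels=labels, voxel_size=0.5, origin=(0.0, 0.0, 0.0),
        cervical_z=-1e9,  # every enamel exterior face is convective
    )
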