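import numpy as np
import pytest

from lc_relaxo.params import AcquisitionProtocol, TissueParameters
from lc_relaxo.phantom import PhantomSpec


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def wm_voxel() -> TissueParameters:
    """A white-matter-like voxel for single-component model checks."""
    return TissueParameters(m0=100.0, t1_single=1000.0, t2_single=80.0)


@pytest.fixture(scope="session")
def two_pool_voxel() -> TissueParameters:
    """A two-pool voxel with parameters inside the default MWF priors."""
    return TissueParameters(
        m0=100.0, mwf=0.15, t1_short=350.0, t1_long=1100.0,
        t2_short=18.0, t2_long=85.0,
    )


@pytest.fixture(scope="session")
def default_phantom_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def tiny_phantom_spec() -> PhantomSpec:
    """Coarse, short phantom for fast volume round trips."""
    return PhantomSpec(
        grid_shape=(16, 16, 14), voxel_size=1.0, lc_length=10.0,
        lc_thickness=2.5, lc_center_offsets=(-3.0, 3.0),
    )
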