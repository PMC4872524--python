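import numpy as np
import pytest

from microtrap import geometry, transport


@pytest.fixture(scope="session")
def design1():
    return geometry.preset_design(1, 15)


@pytest.fixture(scope="session")
def design2():
    return geometry.preset_design(2, 15)


@pytest.fixture(scope="session")
def design1_domain_coarse(design1):
    """Design-1 raster at dx=1 μm with a 10 μm particle exclusion."""
    return geometry.rasterize(design1, dx=1.0, particle_radius=5.0)


@pytest.fixture(scope="session")
def design1_field_coarse(design1_domain_coarse):
    return transport.solve_field(design1_domain_coarse, inlet_velocity=100e-6)


@pytest.fixture(scope="session")
def mini_unit():
    """A trap unit with a short bypass loop, for fast flow-solver tests."""
    return geometry.TrapUnitGeometry.from_dims(
        L11=10, L12=5, W12=5, W13=25, L13=50, W2=25, L2=305, H=15,
    )
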