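import math

import numpy as np
import pytest

from afm3d import (
    ConstantModulus,
    ElasticParams,
    IndenterGeometry,
    simulate_curve,
)
from afm3d.units import KPA, NM


@pytest.fixture
def cone25():
    return IndenterGeometry.cone(math.radians(25.0))


@pytest.fixture
def paraboloid_1um():
    return IndenterGeometry.paraboloid(1e-6)


@pytest.fixture
def sphere_1um():
    return IndenterGeometry.sphere(1e-6)


@pytest.fixture
def cylinder_1um():
    return IndenterGeometry.cylinder(1e-6)


@pytest.fixture
def params_20kpa():
    return ElasticParams(modulus=20 * KPA, poisson_ratio=0.5)


@pytest.fixture
def depth_grid_nm():
    """64 sampling depths from 10 nm to 900 nm, in metres."""
    return np.linspace(10, 900, 64) * NM


@pytest.fixture
def homogeneous_curve(cone25, depth_grid_nm):
    """Noiseless conical curve from a 20 kPa homogeneous sample."""
    curve, _ = simulate_curve(ConstantModulus(20 * KPA), cone25, 0.5, depth_grid_nm)
    return curve
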