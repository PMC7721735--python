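import numpy as np
import pytest

from neureit import (
    ConductivityField,
    ElectrodeLayout,
    build_mesh,
    build_protocol,
)
from neureit.forward import CEMSystem, compute_jacobian, solve_forward
from neureit.pipeline import NerveSystem


@pytest.fixture(scope="session")
def system() -> NerveSystem:
    """Default cuff system: graded mesh, 14-pad layout, 4-off protocol,
    baseline conductivity, element + 40 µm voxel Jacobians."""
    return NerveSystem.build()


@pytest.fixture(scope="session")
def mesh(system):
    return system.mesh


@pytest.fixture(scope="session")
def layout(system):
    return system.layout


@pytest.fixture(scope="session")
def protocol(system):
    return system.protocol


@pytest.fixture(scope="session")
def baseline_sigma(system):
    return system.sigma


@pytest.fixture(scope="session")
def forward_solution(system):
    return solve_forward(system.mesh, system.sigma, system.layout, system.protocol)


@pytest.fixture(scope="session")
def bath_mesh():
    """Wide external bath (2 mm) variant used by geometry tests."""
    return build_mesh(nerve_radius=0.7e-3, external_radius=2.0e-3, target_element_size=60e-6)
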