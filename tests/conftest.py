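"""Shared fixtures.

The coupled four-condition run is session-scoped because it is the
expensive part of the suite (the same four simulations back both the
synergy and the clot-height checks).
"""

from __future__ import annotations

import numpy as np
import pytest

from clotflow.flow import FluidProperties, FlowState
from clotflow.geometry import ChannelGeometry, build_mesh


@pytest.fixture(scope="session")
def default_mesh():
    return build_mesh(ChannelGeometry(), 2.0, 2.0)


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def make_flow():
    """Factory for uniform synthetic flow states (transport oracles)."""
    def _make(mesh, u_value=0.0, v_value=0.0):
        nx, ny = mesh.shape
        return FlowState(mesh=mesh,
                         u=np.full((nx + 1, ny), float(u_value)),
                         v=np.full((nx, ny + 1), float(v_value)),
                         p=np.zeros((nx, ny)))
    return _make


@pytest.fixture(scope="session")
def coupled_runs():
    """The four canonical coupled simulations to 450 s on the 2-µm grid."""
    from clotflow.simulation import SimulationConfig, run_all_conditions
    return run_all_conditions(SimulationConfig())
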