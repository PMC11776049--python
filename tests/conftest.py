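import numpy as np
import pytest

from splitmem.analysis import fit_diffusion, lateral_msd
from splitmem.core import MembraneComposition
from splitmem.fixtures import FixtureConfig, brownian_trajectory, build_bilayer
from splitmem.split import default_split_spec, split_system


@pytest.fixture(scope="session")
def popc_system():
    """Small pure-POPC toy bilayer (16 lipids/leaflet) plus topologies."""
    comp = MembraneComposition({"POPC": 16}, 16)
    config = FixtureConfig(composition=comp, seed=7)
    return build_bilayer(config)


@pytest.fixture(scope="session")
def popc_specs(popc_system):
    _, topologies = popc_system
    return {"POPC": default_split_spec(topologies["POPC"])}


@pytest.fixture(scope="session")
def popc_split(popc_system, popc_specs):
    frame, topologies = popc_system
    return split_system(frame, topologies, popc_specs)


@pytest.fixture(scope="session")
def mixed_system():
    """POPC/POPS/POPA bilayer with cholesterol, 16 lipids/leaflet."""
    comp = MembraneComposition(
        {"POPC": 6, "POPS": 5, "POPA": 3, "CHL": 2}, 16
    )
    config = FixtureConfig(composition=comp, seed=11)
    return build_bilayer(config)


@pytest.fixture(scope="session")
def brownian_fit():
    """Fitted lateral D of the reference Brownian fixture (target 0.05)."""
    traj = brownian_trajectory(
        n_particles=500, d_target=0.05, dt=0.1, n_frames=2000,
        box=(30.0, 30.0, 10.0), seed=42,
    )
    series = lateral_msd(traj, max_lag=60.0)
    return fit_diffusion(series, (5.0, 50.0))
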