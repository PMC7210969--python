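import numpy as np
import pytest

import colmech as cm
from colmech.fibril_topology import linear_chain_coords


@pytest.fixture(scope="session")
def full_fibril():
    """Default 37-helix, one-D-period segment with crosslinks placed."""
    return cm.build_fibril()


@pytest.fixture(scope="session")
def mini_fibril():
    """Reduced-geometry crosslinked fibril for simulation-backed tests."""
    return cm.build_fibril(cm.mini_config())


@pytest.fixture(scope="session")
def mini_trajectory(mini_fibril):
    """Equal-loading pulling run of the reduced fibril (fixed seed).

    Long enough past the slowest chain relaxation time (~26 tau) that the
    retained frames are at steady state.
    """
    params = cm.SimulationParams(
        seed=7, n_steps=40_000, record_every=100, equilibration_fraction=0.4
    )
    return cm.simulate_pulling(mini_fibril, params)


@pytest.fixture(scope="session")
def mini_force_table(mini_trajectory):
    return cm.compute_pairwise_forces(mini_trajectory)


@pytest.fixture(scope="session")
def chain20_trajectory():
    """20-bead straight chain pulled at the 1 nN per-chain force."""
    chain = cm.linear_chain_topology(20)
    traj = cm.simulate_pulling(
        chain, cm.SimulationParams(seed=11), coords=linear_chain_coords(chain)
    )
    return traj


@pytest.fixture(scope="session")
def chain20_unloaded():
    chain = cm.linear_chain_topology(20)
    return cm.simulate_pulling(
        chain,
        cm.SimulationParams(seed=12, per_chain_force=0.0),
        coords=linear_chain_coords(chain),
    )
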