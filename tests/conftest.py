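import numpy as np
import pytest

from dynml import (
    PendulumProtocol,
    RosslerProtocol,
    assemble_transitions,
    simulate_ensemble,
)


@pytest.fixture(scope="session")
def rossler_small():
    """100-trajectory Rössler ensemble (protocol defaults otherwise)."""
    return simulate_ensemble(RosslerProtocol(n_traj=100, seed=11))


@pytest.fixture(scope="session")
def pendulum_small():
    """100-trajectory double-pendulum ensemble."""
    return simulate_ensemble(PendulumProtocol(n_traj=100, seed=11))


@pytest.fixture(scope="session")
def pendulum_500():
    """500-trajectory double-pendulum ensemble (scaled-down protocol)."""
    return simulate_ensemble(PendulumProtocol(n_traj=500, seed=0))


@pytest.fixture(scope="session")
def rossler_2000():
    """Full 2000-trajectory Rössler ensemble per the reference protocol."""
    return simulate_ensemble(RosslerProtocol(n_traj=2000, seed=0))


@pytest.fixture(scope="session")
def pendulum_500_ds(pendulum_500):
    return assemble_transitions(pendulum_500)


@pytest.fixture(scope="session")
def scaled_inputs(pendulum_small):
    """Standardized pendulum states to feed entropy scans."""
    ds = assemble_transitions(pendulum_small)
    u = ds.inputs
    return (u - u.mean(0)) / u.std(0)
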