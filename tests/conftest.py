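"""Shared fixtures: the expensive reference simulations are session-scoped
so the burst traces and the desk-scale sweep are integrated once."""

import numpy as np
import pytest

from burstnet.biophysical_neuron import simulate_biophysical
from burstnet.core_numerics import SimSettings
from burstnet.phase_model import PhaseParams, simulate_phase_single
from burstnet.phase_network import PhaseNetConfig, simulate_phase_network
from burstnet.state_classification import sweep_phase_diagram
from burstnet.synapse_coupling import SynapseParams


@pytest.fixture(scope="session")
def burst_traj_68():
    """Single burster in the bursting regime (drive 68)."""
    return simulate_biophysical(
        68.0, settings=SimSettings(t_end=20000.0, t_transient=5000.0,
                                   record_every=2))


@pytest.fixture(scope="session")
def tonic_traj_70():
    """Single burster in the tonic-spiking regime (drive 70)."""
    return simulate_biophysical(
        70.0, settings=SimSettings(t_end=12000.0, t_transient=4000.0,
                                   record_every=2))


@pytest.fixture(scope="session")
def phase_burst_traj():
    """Generative burster just above threshold (I=2.01, n=5)."""
    return simulate_phase_single(
        PhaseParams(I=2.01, n=5), SimSettings(t_end=600.0, t_transient=100.0))


@pytest.fixture(scope="session")
def sr_phase_net_traj():
    """Synchronized phase-network reference run (K=0.8, dI=0.001, n=5)."""
    cfg = PhaseNetConfig(
        N=200, K=0.8, dI=0.001, n=5,
        synapse=SynapseParams(beta=1.5, K=0.8),
        settings=SimSettings(t_end=2500.0, t_transient=500.0,
                             record_every=10, seed=1))
    return simulate_phase_network(cfg)


@pytest.fixture(scope="session")
def desk_sweep_table():
    """Desk-scale 11x11 phase-network sweep (N=200, n=5, 2000 time units
    post-transient per cell)."""
    return sweep_phase_diagram("phase", master_seed=42)
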