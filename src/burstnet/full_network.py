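"""All-to-all network of biophysical bursters coupled through the mean
synaptic action.

Each neuron follows the four-variable burster with its own rescaled drive
``b * I_i`` (drives uniform on ``[2.1 - dI, 2.1 + dI]``; the rescaling
``b = 32.4`` maps the drive centre onto the bursting current ~68) plus the
coupling current ``sigma K S (V_i - v_th)`` inside the capacitance bracket,
where ``S`` is the population-mean synaptic gate. ``sigma`` follows the
coupling form: ``as_printed`` adds the term with a plus sign;
``conductance`` uses the standard excitatory conductance sign
``-K S (V_i - v_th)``, which depolarises toward ``v_th`` — the form under
which the network reproduces the synchronized/incoherent reference regimes.
Synapses are integrated either as full gate ODEs or via the quasi-static
map (``synapse_mode``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .biophysical_neuron import BiophysParams, biophysical_rhs, gating_curves
from .core_numerics import (DriveSpec, IntegrationError, SimSettings,
                            sample_drives, transient_index_of)
from .synapse_coupling import SynapseParams, quasi_static_s, synapse_rhs

__all__ = [
    "FullNetConfig",
    "FullNetTrajectory",
    "initial_network_state",
    "full_network_rhs",
    "simulate_full_network",
]

SYNAPSE_MODES = ("quasi_static", "ode")


@dataclass
class FullNetConfig:
    """Population size, coupling, dispersion and integration settings of
    the biophysical network."""

    N: int = 100
    K: float = 0.0
    dI: float = 0.0
    b: float = 32.4
    drive_center: float = 2.1
    params: BiophysParams = field(default_factory=BiophysParams)
    synapse: SynapseParams = field(default_factory=lambda: SynapseParams(
        beta=0.1, coupling_form="conductance"))
    settings: SimSettings = field(default_factory=lambda: SimSettings(
        t_end=20000.0, t_transient=5000.0, record_every=10))
    synapse_mode: str = "quasi_static"

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.K < 0 or self.dI < 0:
            raise ValueError("K and dI must be >= 0")
        if self.b <= 0:
            raise ValueError("b must be positive")
        if self.synapse_mode not in SYNAPSE_MODES:
            raise ValueError(f"synapse_mode must be one of {SYNAPSE_MODES}")

    def drive_spec(self) -> DriveSpec:
        return DriveSpec(center=self.drive_center, half_width=self.dI,
                         count=self.N, seed=self.settings.seed)


@dataclass
class FullNetTrajectory:
    """Thinned recording of the network: V matrix (time x neuron), mean
    synaptic action S, and the full parameter record."""

    t: np.ndarray
    V: np.ndarray
    S: np.ndarray
    transient_index: int
    drives: np.ndarray
    config: FullNetConfig
    s: Optional[np.ndarray] = None  # gate matrix in ode mode (record_all)

    @property
    def V_mean(self) -> np.ndarray:
        return self.V.mean(axis=1)

    def metadata(self) -> dict:
        return {
            "model": "full",
            "N": self.config.N,
            "K": self.config.K,
            "dI": self.config.dI,
            "b": self.config.b,
            "beta": self.config.synapse.beta,
            "v_th": self.config.synapse.v_th,
            "coupling_form": self.config.synapse.coupling_form,
            "synapse_mode": self.config.synapse_mode,
            "variant": self.config.params.variant,
            "seed": self.config.settings.seed,
            "dt": self.config.settings.dt,
            "t_end": self.config.settings.t_end,
            "t_transient": self.config.settings.t_transient,
        }


def initial_network_state(config: FullNetConfig, rng: np.random.Generator):
    """Seeded initial conditions: V uniform in [-60, -20] mV, gates at
    their steady state for that potential, Ca = 0.5."""
    V0 = rng.uniform(-60.0, -20.0, size=config.N)
    _, w_inf, n_inf, _ = gating_curves(V0, config.params)
    Ca0 = np.full(config.N, 0.5)
    s0 = quasi_static_s(V0, config.synapse.beta)
    return V0, np.asarray(w_inf), Ca0, np.asarray(n_inf), s0


def full_network_rhs(V, w, Ca, n, drives, config: FullNetConfig, s=None):
    """Reference (non-jitted) derivative of the coupled population.

    With ``K = 0`` each row equals the uncoupled single-neuron derivative
    at its own drive. In ode mode ``s`` must hold the gate states and the
    gate derivatives are returned as a fifth array.
    """
    V = np.asarray(V, float)
    arrs = [np.asarray(a, float) for a in (w, Ca, n, drives)]
    if any(a.shape != V.shape for a in arrs):
        raise ValueError("state arrays and drives must share one shape")
    w, Ca, n, drives = arrs
    beta = config.synapse.beta
    if config.synapse_mode == "ode":
        if s is None:
            raise ValueError("ode synapse mode needs gate states s")
        S = float(np.mean(s))
    else:
        S = float(np.mean(quasi_static_s(V, beta)))
    sigma = config.synapse.coupling_sign
    out = np.empty((4, V.size))
    for i in range(V.size):
        out[:, i] = biophysical_rhs((V[i], w[i], Ca[i], n[i]),
                                    drives[i], config.params)
    out[0] += sigma * config.K * S * (V - config.synapse.v_th) / config.params.c
    if config.synapse_mode == "ode":
        return out[0], out[1], out[2], out[3], synapse_rhs(s, V, beta)
    return out[0], out[1], out[2], out[3]


def simulate_full_network(config: FullNetConfig,
                          drives: Optional[np.ndarray] = None,
                          initial_state=None,
                          record_all: bool = False) -> FullNetTrajectory:
    """Integrate the network and record V, S and the transient marker.

    Drives are ``b`` times the heterogeneous values sampled from the
    seeded uniform distribution unless supplied explicitly (already
    rescaled) by the caller.
    """
    settings = config.settings
    rng = np.random.default_rng(settings.seed)
    if drives is None:
        drives = config.b * sample_drives(config.drive_spec())
    drives = np.asarray(drives, float)
    if initial_state is None:
        initial_state = initial_network_state(config, rng)
    V0, w0, Ca0, n0, s0 = [np.asarray(a, float) for a in initial_state]
    ode = config.synapse_mode == "ode"
    out = _kernels.biophys_net_integrate(
        V0, w0, Ca0, n0, s0, drives, config.params.pvec(),
        config.K, config.synapse.beta, config.synapse.v_th,
        config.synapse.coupling_sign, ode, settings.dt, settings.n_steps,
        settings.record_every, settings.method == "heun", record_all,
    )
    V_rec, S_rec, _, _, _, s_rec, blowup = out
    if blowup >= 0:
        raise IntegrationError(
            f"non-finite membrane potential at t = {blowup * settings.dt:g}")
    t = np.arange(V_rec.shape[0]) * (settings.dt * settings.record_every)
    return FullNetTrajectory(
        t=t, V=V_rec, S=S_rec,
        transient_index=transient_index_of(t, settings.t_transient),
        drives=drives, config=config,
        s=s_rec if (ode and record_all) else None,
    )
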