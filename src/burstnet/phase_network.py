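"""Mean-field coupled network of generative phase bursters.

N bursters with heterogeneous drives (uniform on ``[2.1 - dI, 2.1 + dI]``)
follow ``dtheta_i/dt = F(theta_i; I_i, n) - Gamma sin(theta_i)
(cos(theta_i) - v_th)`` with the mean synaptic field ``Gamma`` computed
from the population's phases (see :mod:`burstnet.synapse_coupling`). The
coupling response was derived for a spiking circle, and because sin/cos
are 2-pi-periodic it automatically acts on the fast angle of the extended
circle — one response lobe per spike.

Initial phases are uniform random on the extended circle, seeded through
the run settings; with zero dispersion and identical initial phases the
synchronous manifold is exactly invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .core_numerics import DriveSpec, SimSettings, sample_drives, transient_index_of
from .phase_model import phase_rhs_single
from .synapse_coupling import GAMMA_SIGNS, SynapseParams, mean_field_gamma

__all__ = [
    "PhaseNetConfig",
    "PhaseNetTrajectory",
    "phase_network_rhs",
    "simulate_phase_network",
]


@dataclass
class PhaseNetConfig:
    """Population size, coupling, dispersion, spikes-per-burst and
    integration settings of the phase network."""

    N: int = 200
    K: float = 0.0
    dI: float = 0.0
    n: int = 5
    drive_center: float = 2.1
    synapse: SynapseParams = field(default_factory=lambda: SynapseParams(beta=1.5))
    settings: SimSettings = field(default_factory=lambda: SimSettings(
        t_end=2500.0, t_transient=500.0, record_every=10))
    exclude_self: bool = True
    gamma_sign: str = "as_printed"

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.K < 0 or self.dI < 0:
            raise ValueError("K and dI must be >= 0")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError("n must be a positive integer")
        if self.gamma_sign not in GAMMA_SIGNS:
            raise ValueError(f"gamma_sign must be one of {GAMMA_SIGNS}")

    def drive_spec(self) -> DriveSpec:
        return DriveSpec(center=self.drive_center, half_width=self.dI,
                         count=self.N, seed=self.settings.seed)


@dataclass
class PhaseNetTrajectory:
    """Thinned recording: unwrapped phase matrix (time x neuron), mean
    field Gamma, derived V/V_mean/R_theta series, and the full record."""

    t: np.ndarray
    theta: np.ndarray  # unwrapped
    gamma: np.ndarray
    transient_index: int
    drives: np.ndarray
    config: PhaseNetConfig

    @property
    def V(self) -> np.ndarray:
        return -np.cos(self.theta)

    @property
    def V_mean(self) -> np.ndarray:
        return self.V.mean(axis=1)

    @property
    def R_theta(self) -> np.ndarray:
        return np.cos(self.theta).mean(axis=1)

    def metadata(self) -> dict:
        return {
            "model": "phase",
            "N": self.config.N,
            "K": self.config.K,
            "dI": self.config.dI,
            "n": self.config.n,
            "beta": self.config.synapse.beta,
            "v_th": self.config.synapse.v_th,
            "gamma_sign": self.config.gamma_sign,
            "exclude_self": self.config.exclude_self,
            "seed": self.config.settings.seed,
            "dt": self.config.settings.dt,
            "t_end": self.config.settings.t_end,
            "t_transient": self.config.settings.t_transient,
        }


def phase_network_rhs(theta, drives, config: PhaseNetConfig) -> np.ndarray:
    """Reference (non-jitted) derivative vector of the coupled population.

    With ``K = 0`` this reduces to the uncoupled generative flows; the
    coupling response vanishes at ``theta = 0`` when ``v_th = 0``.
    """
    theta = np.asarray(theta, float)
    drives = np.asarray(drives, float)
    if theta.shape != drives.shape:
        raise ValueError("theta and drives must share one shape")
    syn = config.synapse
    out = np.empty_like(theta)
    for i in range(theta.size):
        gam = mean_field_gamma(theta, config.K, syn.beta,
                               exclude_self=i if (config.exclude_self and
                                                  theta.size > 1) else None,
                               gamma_sign=config.gamma_sign)
        out[i] = (phase_rhs_single(theta[i], drives[i], config.n)
                  - gam * np.sin(theta[i]) * (np.cos(theta[i]) - syn.v_th))
    return out


def simulate_phase_network(config: PhaseNetConfig,
                           drives: Optional[np.ndarray] = None,
                           theta0: Optional[np.ndarray] = None) -> PhaseNetTrajectory:
    """Integrate the phase network; phases evolve unwrapped, and Gamma,
    V_mean and R_theta are available on the recorded grid."""
    settings = config.settings
    rng = np.random.default_rng(settings.seed)
    if drives is None:
        drives = sample_drives(config.drive_spec())
    drives = np.asarray(drives, float)
    if theta0 is None:
        theta0 = rng.uniform(-config.n * np.pi, config.n * np.pi,
                             size=config.N)
    theta0 = np.asarray(theta0, float)
    gamma_sign = 1.0 if config.gamma_sign == "as_printed" else -1.0
    th_rec, gam_rec = _kernels.phase_net_integrate(
        theta0, drives, float(config.n), config.K, config.synapse.beta,
        config.synapse.v_th, config.exclude_self, gamma_sign,
        settings.dt, settings.n_steps, settings.record_every,
        settings.method == "heun",
    )
    t = np.arange(th_rec.shape[0]) * (settings.dt * settings.record_every)
    return PhaseNetTrajectory(
        t=t, theta=th_rec, gamma=gam_rec,
        transient_index=transient_index_of(t, settings.t_transient),
        drives=drives, config=config,
    )
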