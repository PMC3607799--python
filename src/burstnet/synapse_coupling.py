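"""Fast excitatory synapse and its mean fields.

The synaptic gate obeys ``ds/dt = a(V)(1 - s) - s/beta`` with the logistic
activation ``a(V) = 1/(1 + exp(-V/2))``. For AMPA-like kinetics the gate is
much faster than the membrane, and the quasi-static (adiabatic) reduction
``s*(V) = beta/(1 + beta + exp(-V/2))`` — the exact equilibrium of the gate
ODE — replaces the extra state variable. The reduction is accurate for
``beta`` in roughly [0.01, 0.5] and breaks down for slow synapses
(``beta ~ 5``), which the test suite checks on a spiking trajectory.

Two population fields are provided: ``S``, the arithmetic mean of the
gates (voltage networks), and ``Gamma``, the phase-model analogue obtained
by evaluating the transfer at ``cos(theta_l)`` and scaling by the coupling
strength K. The phase transfer uses ``exp(-cos(theta)/2)`` as the mean
field is defined for the phase model; the substitution ``V = -cos(theta)``
would give the opposite sign inside the exponential, and that monotone
reparameterisation is reachable via ``gamma_sign="voltage"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "COUPLING_FORMS",
    "GAMMA_SIGNS",
    "SynapseParams",
    "synaptic_activation",
    "synapse_rhs",
    "quasi_static_s",
    "mean_synaptic_action",
    "mean_field_gamma",
]

# as_printed adds +K S (V - v_th) to the membrane equation; conductance
# flips the sign to the standard excitatory conductance form -K S (V - v_th).
COUPLING_FORMS = ("as_printed", "conductance")
GAMMA_SIGNS = ("as_printed", "voltage")


@dataclass
class SynapseParams:
    """Synaptic time constant, coupling strength and reversal threshold."""

    beta: float = 0.1
    K: float = 0.0
    v_th: float = 0.0
    coupling_form: str = "as_printed"

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.coupling_form not in COUPLING_FORMS:
            raise ValueError(f"coupling_form must be one of {COUPLING_FORMS}")

    @property
    def coupling_sign(self) -> float:
        return 1.0 if self.coupling_form == "as_printed" else -1.0


def synaptic_activation(V):
    """Logistic presynaptic activation ``a(V) = 1/(1 + exp(-V/2))``."""
    with np.errstate(over="ignore"):  # deep hyperpolarisation -> a = 0
        return 1.0 / (1.0 + np.exp(-np.asarray(V, dtype=float) / 2.0))


def synapse_rhs(s, V, beta: float):
    """Gate kinetics ``ds/dt = a(V)(1 - s) - s/beta``."""
    s = np.asarray(s, dtype=float)
    return synaptic_activation(V) * (1.0 - s) - s / beta


def quasi_static_s(V, beta: float):
    """Adiabatic gate equilibrium ``s* = beta/(1 + beta + exp(-V/2))``,
    the exact root of :func:`synapse_rhs` in ``s``."""
    with np.errstate(over="ignore"):  # deep hyperpolarisation -> s* = 0
        return beta / (1.0 + beta + np.exp(-np.asarray(V, dtype=float) / 2.0))


def mean_synaptic_action(values, beta: float = 0.1,
                         mode: str = "quasi_static") -> float:
    """Population mean synaptic action S.

    ``mode="ode"`` treats ``values`` as stored gate states s_i;
    ``mode="quasi_static"`` treats them as membrane potentials and applies
    the adiabatic map first.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("population must be nonempty")
    if mode == "ode":
        return float(np.mean(v))
    if mode == "quasi_static":
        return float(np.mean(quasi_static_s(v, beta)))
    raise ValueError("mode must be 'ode' or 'quasi_static'")


def mean_field_gamma(theta, K: float, beta: float = 0.1,
                     exclude_self=None, gamma_sign: str = "as_printed"):
    """Phase-model mean synaptic field.

    ``Gamma = (K/N) sum_{l != i} beta/(1 + beta + exp(-cos(theta_l)/2))``.
    With ``exclude_self=None`` the full sum is returned (the difference is
    O(1/N)); an integer index drops that neuron's own term while keeping
    the 1/N normalisation. ``gamma_sign="voltage"`` uses
    ``exp(+cos(theta_l)/2)`` (the transfer of ``V = -cos(theta)``).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValueError("phase vector must be nonempty")
    sign = 1.0 if gamma_sign == "as_printed" else -1.0
    if gamma_sign not in GAMMA_SIGNS:
        raise ValueError(f"gamma_sign must be one of {GAMMA_SIGNS}")
    transfer = beta / (1.0 + beta + np.exp(-sign * np.cos(theta) / 2.0))
    total = transfer.sum()
    if exclude_self is not None:
        total = total - transfer[exclude_self]
    return K * total / theta.size
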