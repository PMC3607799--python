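"""The Rinzel–Ermentrout parabolic burster.

A Morris–Lecar fast subsystem (membrane potential ``V`` and K⁺-gate ``w``)
augmented with two slow variables: intracellular calcium ``Ca`` (driving a
Ca-gated K⁺ current through ``z = Ca/(Ca + Ca0)``) and a slow inward-gate
``n`` contributing to the Ca²⁺ current. The slow subsystem periodically
carries the fast subsystem back and forth across a saddle-node-on-invariant-
circle (SNIC) threshold, producing parabolic bursting: spike rate lowest at
burst onset and offset, no fast-subsystem bistability required.

Under the default (``ml_canonical``) parameter set the single neuron is
quiescent at low drive, bursts near ``I = 68`` and fires tonically for
``I >= 70``; its steady state destabilizes into repetitive multi-spike
firing at ``I = 60``.

Two parameter variants are provided. ``ml_canonical`` (default) uses the
canonical type-I Morris–Lecar values ``v1 = -1.2``, ``V_l = -60`` and
``tau_w(V) = 1/cosh((V - v3)/(2 v4))``; ``paper_literal`` keeps the
alternative printed signs (``v1 = +1.2``, ``V_l = +60``) and the sigmoidal
``tau_w`` for audit. With a +60 mV leak reversal the resting state sits far
above the sub-(-40 mV) regime the model is meant to describe, so the
canonical variant is the scientific default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .core_numerics import IntegrationError, SimSettings, transient_index_of

__all__ = [
    "VARIANTS",
    "BiophysParams",
    "BiophysState",
    "BiophysTrajectory",
    "gating_curves",
    "biophysical_rhs",
    "default_initial_state",
    "simulate_biophysical",
    "detect_spikes",
    "group_bursts",
    "scan_firing_onset",
]

VARIANTS = ("ml_canonical", "paper_literal")


@dataclass
class BiophysParams:
    """All fixed constants of the four-variable burster (mV, conductance and
    time units as in the canonical Morris–Lecar formulation)."""

    V_K: float = -84.0
    V_l: float = -60.0
    V_Ca: float = 120.0
    g_K: float = 8.0
    g_l: float = 2.0
    g_Ca: float = 4.0
    g_kCa: float = 1.0
    g_sCa: float = 1.0
    c: float = 20.0
    v1: float = -1.2
    v2: float = 18.0
    v3: float = 12.0
    v4: float = 17.4
    v5: float = 12.0
    v6: float = 24.0
    phi: float = 0.06666666
    tau_n: float = 0.05
    eps: float = 0.0005
    mu: float = 0.025
    Ca0: float = 1.0
    variant: str = "ml_canonical"

    def __post_init__(self) -> None:
        for name in ("g_K", "g_l", "g_Ca", "g_kCa", "g_sCa"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.c <= 0 or self.eps <= 0 or self.Ca0 <= 0:
            raise ValueError("c, eps and Ca0 must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    @classmethod
    def from_variant(cls, variant: str = "ml_canonical") -> "BiophysParams":
        if variant == "paper_literal":
            return cls(v1=1.2, V_l=60.0, variant="paper_literal")
        return cls()

    def pvec(self) -> np.ndarray:
        """Parameter vector in the kernel layout (see ``_kernels.PVEC_FIELDS``)."""
        tau_w_form = (
            _kernels.TAU_W_PAPER_LITERAL
            if self.variant == "paper_literal"
            else _kernels.TAU_W_ML_CANONICAL
        )
        return np.array(
            [self.V_K, self.V_l, self.V_Ca, self.g_K, self.g_l, self.g_Ca,
             self.g_kCa, self.g_sCa, self.c, self.v1, self.v2, self.v3,
             self.v4, self.v5, self.v6, self.phi, self.tau_n, self.eps,
             self.mu, self.Ca0, tau_w_form],
            dtype=float,
        )


@dataclass
class BiophysState:
    """Single-neuron state: membrane potential, K-gate, calcium, slow gate."""

    V: float
    w: float
    Ca: float
    n: float

    def __post_init__(self) -> None:
        self.w = float(np.clip(self.w, 0.0, 1.0))
        self.n = float(np.clip(self.n, 0.0, 1.0))
        self.Ca = max(float(self.Ca), 0.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.w, self.Ca, self.n])


@dataclass
class BiophysTrajectory:
    """Recorded single-neuron trajectory with the transient marked."""

    t: np.ndarray
    V: np.ndarray
    w: np.ndarray
    Ca: np.ndarray
    n: np.ndarray
    transient_index: int
    drive: float
    s: Optional[np.ndarray] = None  # synaptic gate, when tracked as an ODE

    def to_frame(self):
        import pandas as pd

        cols = {"time": self.t, "V": self.V, "w": self.w, "Ca": self.Ca,
                "n": self.n}
        if self.s is not None:
            cols["s"] = self.s
        return pd.DataFrame(cols)


def gating_curves(V, params: BiophysParams):
    """Steady-state activations (m_inf, w_inf, n_inf) and the w time scale
    tau_w at potential ``V`` (scalar or array)."""
    V = np.asarray(V, dtype=float)
    m_inf = 0.5 * (1.0 + np.tanh((V - params.v1) / params.v2))
    w_inf = 0.5 * (1.0 + np.tanh((V - params.v3) / params.v4))
    n_inf = 0.5 * (1.0 + np.tanh((V - params.v5) / params.v6))
    if params.variant == "paper_literal":
        tau_w = 0.5 * (1.0 + np.tanh((V - params.v3) / (2.0 * params.v2)))
    else:
        tau_w = 1.0 / np.cosh((V - params.v3) / (2.0 * params.v4))
    return m_inf, w_inf, n_inf, tau_w


def biophysical_rhs(state, drive: float, params: BiophysParams) -> np.ndarray:
    """Time derivative of ``(V, w, Ca, n)`` for a single uncoupled neuron.

    The Ca²⁺ current is ``I_Ca = (g_Ca m_inf(V) + g_sCa n)(V - V_Ca)``; the
    Ca-gated K⁺ activation is ``z = Ca/(Ca + Ca0)``; calcium integrates the
    (inward, hence negative) Ca²⁺ current with influx scale ``mu`` on the
    slow time scale ``eps``.
    """
    if isinstance(state, BiophysState):
        V, w, Ca, n = state.V, state.w, state.Ca, state.n
    else:
        V, w, Ca, n = np.asarray(state, dtype=float)
    m_inf, w_inf, n_inf, tau_w = gating_curves(V, params)
    I_Ca = (params.g_Ca * m_inf + params.g_sCa * n) * (V - params.V_Ca)
    z = Ca / (Ca + params.Ca0)
    dV = (drive - I_Ca - (params.g_K * w + params.g_kCa * z) * (V - params.V_K)
          - params.g_l * (V - params.V_l)) / params.c
    dw = params.phi * (w_inf - w) / tau_w
    dCa = params.eps * (-params.mu * I_Ca - Ca)
    dn = params.eps * (n_inf - n) / params.tau_n
    return np.array([dV, dw, dCa, dn])


def default_initial_state(params: BiophysParams, V0: float = -50.0) -> BiophysState:
    """Deterministic initial condition: gates at their steady state for
    ``V0``, calcium at 0.5."""
    _, w_inf, n_inf, _ = gating_curves(V0, params)
    return BiophysState(V=V0, w=float(w_inf), Ca=0.5, n=float(n_inf))


def _integrate_population(V0, w0, Ca0, n0, s0, drives, params, settings,
                          K=0.0, beta=0.1, v_th=0.0, coupling_sign=1.0,
                          synapse_ode=False, record_all=True):
    """Shared wrapper around the jitted population kernel."""
    out = _kernels.biophys_net_integrate(
        np.asarray(V0, float), np.asarray(w0, float), np.asarray(Ca0, float),
        np.asarray(n0, float), np.asarray(s0, float), np.asarray(drives, float),
        params.pvec(), float(K), float(beta), float(v_th),
        float(coupling_sign), bool(synapse_ode), settings.dt,
        settings.n_steps, settings.record_every,
        settings.method == "heun", bool(record_all),
    )
    V_rec, S_rec, w_rec, Ca_rec, n_rec, s_rec, blowup = out
    if blowup >= 0:
        raise IntegrationError(
            f"non-finite membrane potential at t = {blowup * settings.dt:g}"
        )
    t = np.arange(V_rec.shape[0]) * (settings.dt * settings.record_every)
    return t, V_rec, S_rec, w_rec, Ca_rec, n_rec, s_rec


def simulate_biophysical(drive: float, params: Optional[BiophysParams] = None,
                         settings: Optional[SimSettings] = None,
                         y0: Optional[BiophysState] = None,
                         track_synapse: bool = False,
                         beta: float = 0.1) -> BiophysTrajectory:
    """Integrate a single uncoupled burster at the given applied current.

    ``track_synapse`` co-integrates the (passive, non-fed-back) synaptic
    gate ``ds/dt = a(V)(1 - s) - s/beta`` so the quasi-static reduction can
    be checked against the full kinetics.
    """
    params = params or BiophysParams()
    settings = settings or SimSettings(t_end=20000.0, t_transient=5000.0)
    y0 = y0 or default_initial_state(params)
    t, V, S, w, Ca, n, s = _integrate_population(
        [y0.V], [y0.w], [y0.Ca], [y0.n], [0.0], [drive], params, settings,
        synapse_ode=track_synapse, beta=beta, record_all=True,
    )
    return BiophysTrajectory(
        t=t, V=V[:, 0], w=w[:, 0], Ca=Ca[:, 0], n=n[:, 0],
        transient_index=transient_index_of(t, settings.t_transient),
        drive=float(drive),
        s=s[:, 0] if track_synapse else None,
    )


def detect_spikes(t: np.ndarray, V: np.ndarray, threshold: float = 0.0,
                  refractory: float = 2.0) -> np.ndarray:
    """Spike times: upward threshold crossings on a uniformly sampled trace,
    with subsequent crossings inside the refractory window suppressed."""
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    if V.size < 2:
        return np.empty(0)
    up = np.flatnonzero((V[:-1] < threshold) & (V[1:] >= threshold))
    if up.size == 0:
        return np.empty(0)
    times = t[up + 1]
    kept = [times[0]]
    for ti in times[1:]:
        if ti - kept[-1] > refractory:
            kept.append(ti)
    return np.asarray(kept)


def group_bursts(spike_times: Sequence[float], gap_factor: float = 3.0):
    """Group a sorted spike train into bursts.

    A new burst starts whenever an inter-spike interval exceeds
    ``gap_factor`` times the median ISI of the whole train. Returns a list
    of bursts, each ``(spike_count, within-burst ISI array)``.
    """
    st = np.asarray(spike_times, float)
    if st.size == 0:
        return []
    if st.size == 1:
        return [(1, np.empty(0))]
    isi = np.diff(st)
    gap = gap_factor * np.median(isi)
    breaks = np.flatnonzero(isi > gap)
    bursts = []
    start = 0
    for b in list(breaks) + [st.size - 1]:
        seg = st[start: b + 1]
        bursts.append((seg.size, np.diff(seg)))
        start = b + 1
    return bursts


def scan_firing_onset(I_min: float, I_max: float, step: float,
                      params: Optional[BiophysParams] = None,
                      settings: Optional[SimSettings] = None,
                      min_spikes: int = 3,
                      spike_threshold: float = 0.0,
                      refractory: float = 2.0) -> Optional[float]:
    """Smallest scanned drive with sustained post-transient firing.

    Scans ``I = I_min, I_min + step, ...`` up to ``I_max`` (inclusive);
    "firing" means at least ``min_spikes`` detected spikes in the analysis
    window, which guards against the few transient spikes a neuron may emit
    before settling to rest. Returns ``None`` when no scanned drive fires.
    All drives are integrated as one uncoupled population (vectorised over
    the scan), so the cost is one network integration.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    params = params or BiophysParams()
    settings = settings or SimSettings(t_end=20000.0, t_transient=5000.0,
                                       record_every=4)
    drives = np.arange(I_min, I_max + 0.5 * step, step)
    n = drives.size
    y0 = default_initial_state(params)
    t, V, _, _, _, _, _ = _integrate_population(
        np.full(n, y0.V), np.full(n, y0.w), np.full(n, y0.Ca),
        np.full(n, y0.n), np.zeros(n), drives, params, settings,
        record_all=False,
    )
    i0 = transient_index_of(t, settings.t_transient)
    for j, I in enumerate(drives):
        spikes = detect_spikes(t[i0:], V[i0:, j], spike_threshold, refractory)
        if spikes.size >= min_spikes:
            return float(I)
    return None
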