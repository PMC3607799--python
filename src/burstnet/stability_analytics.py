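"""Semi-analytic layer: drift fixed points, linear stability, the continuum
stationary phase density, and the critical lines of the (K, dI) diagram.

All formulas share one definition of the drift,

    v0(theta; I, Gamma) = F(theta; I, n) - Gamma sin(theta)(cos(theta) - v_th),

exactly the per-neuron vector field of the mean-field phase network (for
v_th = 0 the response is sin(theta)cos(theta) = sin(2 theta)/2, so Gamma
here absorbs the conventional factor of two of a sin(2 theta) notation).

Two stationary regimes exist per neuron: when the drift has roots the
neuron is pinned (stable fixed point; the continuum density is a point
mass), and when it has none the neuron rotates and the stationary density
is inversely proportional to the drift, ``f0 = L / v0`` with ``L`` fixed by
normalisation over the extended circle — so ``2 pi n L`` is the neuron's
rotation number.

Critical lines of the phase diagram:

* PO/IN (saddle-node): ``|K| = eps_pert * m * (dI - dI_c)`` — a straight
  line through (dI_c, 0). eps_pert, m, dI_c have no universal values; the
  defaults (eps_pert * m = 1, dI_c = 0.1, p = 1) are calibration hooks and
  can be refitted to a numerical sweep.
* IN/SR (Hopf): ``|K| = a0 dI + a1 dI^2 + a2 dI^3`` with default
  coefficients a0 = 8/pi, a1 = 0, a2 = 128/pi^3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .phase_model import phase_rhs_single

__all__ = [
    "AnalyticsParams",
    "velocity_field",
    "drift_derivative",
    "fixed_points",
    "stability_eigenvalue",
    "StationaryDensity",
    "stationary_density",
    "critical_line_po_in",
    "critical_line_in_sr",
    "fit_boundaries",
    "detect_in_sr_transition",
]


@dataclass
class AnalyticsParams:
    """Coefficients of the two critical lines."""

    eps_pert: float = 1.0
    m: float = 1.0
    dI_c: float = 0.1
    p: float = 1.0
    a0: float = 8.0 / np.pi
    a1: float = 0.0
    a2: float = 128.0 / np.pi**3

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("m must be positive")
        if self.a0 < 0:
            raise ValueError("a0 must be >= 0")


def velocity_field(theta, I: float, Gamma: float, n: int = 5,
                   v_th: float = 0.0):
    """Stationary drift ``v0 = F(theta) - Gamma sin(theta)(cos(theta) - v_th)``."""
    theta = np.asarray(theta, float)
    return (phase_rhs_single(theta, I, n)
            - Gamma * np.sin(theta) * (np.cos(theta) - v_th))


def drift_derivative(theta, I: float, Gamma: float, n: int = 5,
                     v_th: float = 0.0):
    """Exact d(v0)/d(theta): ``sin(theta) + sin(theta/n)/n
    - Gamma (cos(2 theta) - v_th cos(theta))``."""
    theta = np.asarray(theta, float)
    return (np.sin(theta) + np.sin(theta / n) / n
            - Gamma * (np.cos(2.0 * theta) - v_th * np.cos(theta)))


def fixed_points(I: float, Gamma: float, n: int = 5, v_th: float = 0.0,
                 resolution: int = 4096) -> List[Tuple[float, str]]:
    """All roots of the drift on the extended circle with their stability.

    Roots are located by dense sampling plus bisection; stability follows
    the sign of the drift derivative (negative slope = stable). An empty
    list means the neuron rotates (no rest state).
    """
    L = 2.0 * np.pi * n
    grid = np.linspace(-L / 2, L / 2, resolution + 1)
    vals = velocity_field(grid, I, Gamma, n, v_th)
    roots: List[Tuple[float, str]] = []
    for k in range(resolution):
        a, b = grid[k], grid[k + 1]
        fa, fb = vals[k], vals[k + 1]
        if fa == 0.0:
            roots.append((float(a), ""))
        elif fa * fb < 0:
            th = brentq(lambda x: float(velocity_field(x, I, Gamma, n, v_th)),
                        a, b, xtol=1e-12)
            roots.append((float(th), ""))
    out = []
    for th, _ in roots:
        lam = float(drift_derivative(th, I, Gamma, n, v_th))
        out.append((th, "stable" if lam < 0 else "unstable"))
    return out


def stability_eigenvalue(theta_star: float, I: float, Gamma: float,
                         n: int = 5, v_th: float = 0.0) -> float:
    """Linearisation of the drift at a fixed point: the exact derivative
    ``F'(theta*) - Gamma (cos(2 theta*) - v_th cos(theta*))``; a negative
    value means local stability."""
    return float(drift_derivative(theta_star, I, Gamma, n, v_th))


@dataclass
class StationaryDensity:
    """Continuum stationary state: either a normalized rotating density
    on the extended circle or the pinned fixed point."""

    kind: str  # "density" or "point_mass"
    theta: Optional[np.ndarray] = None
    density: Optional[np.ndarray] = None
    L_const: Optional[float] = None  # normalisation constant = 1/period
    fixed_point: Optional[float] = None

    @property
    def rotation_number(self) -> float:
        """``2 pi n L`` for a rotating density, 0 for a pinned neuron."""
        if self.kind == "point_mass":
            return 0.0
        n_sub = (self.theta[-1] - self.theta[0]) / (2.0 * np.pi)
        return float(n_sub * 2.0 * np.pi * self.L_const)


def stationary_density(I: float, Gamma: float, n: int = 5, v_th: float = 0.0,
                       resolution: int = 2048) -> StationaryDensity:
    """Stationary solution of the continuum continuity equation.

    Rotating case (drift root-free): ``f0 = L / v0`` with
    ``L = 1 / (closed-circle integral of 1/v0)`` so that the density
    integrates to 1 over the extended circle. Pinned case: the stable
    fixed point is returned as a point-mass indicator.
    """
    if resolution < 256:
        raise ValueError("resolution must be >= 256")
    fps = fixed_points(I, Gamma, n, v_th)
    if fps:
        stable = [th for th, s in fps if s == "stable"]
        return StationaryDensity(kind="point_mass",
                                 fixed_point=stable[0] if stable else fps[0][0])
    L = 2.0 * np.pi * n
    period, _ = quad(lambda th: 1.0 / float(velocity_field(th, I, Gamma, n, v_th)),
                     -L / 2, L / 2, points=[0.0], limit=400)
    Lc = 1.0 / period
    grid = np.linspace(-L / 2, L / 2, resolution + 1)
    dens = Lc / velocity_field(grid, I, Gamma, n, v_th)
    return StationaryDensity(kind="density", theta=grid, density=dens,
                             L_const=float(Lc))


def critical_line_po_in(dI, params: AnalyticsParams = AnalyticsParams()):
    """Saddle-node boundary ``|K| = eps_pert m (dI - dI_c)`` (straight line
    through ``(dI_c, 0)``); raises below the critical dispersion."""
    dI = np.asarray(dI, float)
    if np.any(dI < params.dI_c):
        raise ValueError(f"below critical dispersion dI_c = {params.dI_c}")
    return params.eps_pert * params.m * (dI - params.dI_c)


def critical_line_in_sr(dI, params: AnalyticsParams = AnalyticsParams()):
    """Hopf boundary ``|K| = a0 dI + a1 dI^2 + a2 dI^3``."""
    dI = np.asarray(dI, float)
    if np.any(dI < 0):
        raise ValueError("dI must be >= 0")
    return params.a0 * dI + params.a1 * dI**2 + params.a2 * dI**3


def fit_boundaries(sweep_table, params: AnalyticsParams = AnalyticsParams()
                   ) -> AnalyticsParams:
    """Refit the critical-line coefficients to a sweep table by least
    squares.

    PO/IN: for each dI column with both labels present, the boundary point
    is the midpoint between the largest IN-labeled K below the smallest
    PO-labeled K; a straight line K = em (dI - dI_c) is fitted. IN/SR: for
    each dI column the midpoint between the largest IN K and the smallest
    SR K above it; the odd cubic a0 dI + a2 dI^3 is fitted. Columns without
    a transition are skipped; missing transitions leave the corresponding
    defaults untouched.
    """
    import pandas as pd

    df = sweep_table[sweep_table["label"] != ""]
    po_pts, sr_pts = [], []
    for dI, grp in df.groupby("dI"):
        grp = grp.sort_values("K")
        labels = grp["label"].to_numpy()
        Ks = grp["K"].to_numpy()
        in_ks = Ks[labels == "IN"]
        po_ks = Ks[labels == "PO"]
        sr_ks = Ks[labels == "SR"]
        if in_ks.size and po_ks.size and po_ks.min() > in_ks.max():
            po_pts.append((dI, 0.5 * (in_ks.max() + po_ks.min())))
        if in_ks.size and sr_ks.size and sr_ks.min() > in_ks.max():
            sr_pts.append((dI, 0.5 * (in_ks.max() + sr_ks.min())))
    em, dI_c = params.eps_pert * params.m, params.dI_c
    a0, a2 = params.a0, params.a2
    if len(po_pts) >= 2:
        x = np.array([p[0] for p in po_pts])
        y = np.array([p[1] for p in po_pts])
        slope, intercept = np.polyfit(x, y, 1)
        if slope > 0:
            em, dI_c = slope, -intercept / slope
    if len(sr_pts) >= 2:
        x = np.array([p[0] for p in sr_pts])
        y = np.array([p[1] for p in sr_pts])
        A = np.column_stack([x, x**3])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        if coef[0] > 0:
            a0, a2 = float(coef[0]), float(coef[1])
    return AnalyticsParams(eps_pert=1.0, m=em, dI_c=float(dI_c), p=params.p,
                           a0=a0, a1=params.a1, a2=a2)


def detect_in_sr_transition(dI: float, K_lo: float = 0.0, K_hi: float = 1.0,
                            N: int = 500, n: int = 1, master_seed: int = 0,
                            n_iter: int = 7, chi_thr: float = 0.5) -> float:
    """Numerical IN -> SR transition coupling at fixed dispersion, by
    bisection on the coherence criterion ``chi >= chi_thr``."""
    from dataclasses import replace

    from .core_numerics import SimSettings, cell_seed
    from .observables import phase_network_report
    from .phase_network import PhaseNetConfig, simulate_phase_network

    base = PhaseNetConfig(N=N, n=n, settings=SimSettings(
        t_end=1500.0, t_transient=500.0, record_every=10,
        seed=cell_seed(master_seed, int(round(1000 * dI)))))

    def coherent(K: float) -> bool:
        traj = simulate_phase_network(replace(base, K=float(K), dI=float(dI)))
        return phase_network_report(traj).chi >= chi_thr

    lo, hi = K_lo, K_hi
    if not coherent(hi):
        return float("nan")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if coherent(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
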