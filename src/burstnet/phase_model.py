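"""The generative parabolic burster: one phase variable, n spikes per burst.

The model is ``dtheta/dt = I - cos(theta) - cos(theta/n)`` on an extended
circle of circumference ``2 pi n``. The fast cosine generates spikes (the
membrane-like observable is ``V = -cos(theta)``); the slow cosine stands in
for the entire slow subsystem of a conductance-based burster, gating the
fast rotation on and off so that each full cycle of the extended circle
contains exactly ``n`` spike passages — parabolic bursting with a SNIC
onset. Both cosines attain 1 simultaneously at ``theta = 0``, so the firing
threshold is ``I_c = 2`` for every ``n``: below it a rest state exists, at
it the period diverges, above it the flow rotates monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .core_numerics import SimSettings, Trajectory, integrate_fixed_step

__all__ = [
    "PhaseParams",
    "PhaseTrajectory",
    "phase_rhs_single",
    "firing_threshold",
    "period_single",
    "simulate_phase_single",
    "phase_spike_times",
    "spikes_per_cycle",
    "isi_profile",
]


@dataclass
class PhaseParams:
    """Drive, spikes-per-burst integer and initial phase of one burster."""

    I: float = 2.01
    n: int = 5
    theta0: float = 0.0

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError("n must be a positive integer")

    @property
    def circumference(self) -> float:
        return 2.0 * np.pi * self.n


@dataclass
class PhaseTrajectory:
    """Single-burster trajectory; phases are stored unwrapped and the
    wrapped copy (on [-n pi, n pi)) is derived."""

    t: np.ndarray
    theta: np.ndarray  # unwrapped
    n: int
    transient_index: int
    drive: float

    @property
    def theta_wrapped(self) -> np.ndarray:
        L = 2.0 * np.pi * self.n
        return (self.theta + self.n * np.pi) % L - self.n * np.pi

    @property
    def V(self) -> np.ndarray:
        return -np.cos(self.theta)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time": self.t,
            "theta_wrapped": self.theta_wrapped,
            "theta_unwrapped": self.theta,
            "V": self.V,
        })


def phase_rhs_single(theta, I: float, n: int):
    """``F(theta; I, n) = I - cos(theta) - cos(theta/n)``."""
    theta = np.asarray(theta, dtype=float)
    return I - np.cos(theta) - np.cos(theta / n)


def firing_threshold(n: int, grid_points: int = 100_001) -> float:
    """Critical drive ``I_c = max_theta [cos(theta) + cos(theta/n)]``.

    Below ``I_c`` the flow has a rest state; above it ``dtheta/dt > 0``
    everywhere (SNIC). The maximum is located by a dense grid over the
    extended circle plus local refinement; both cosines peak together at
    ``theta = 0``, so the result is 2 for every ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = np.linspace(-n * np.pi, n * np.pi, grid_points)
    vals = np.cos(grid) + np.cos(grid / n)
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid_points - 1)]
    res = minimize_scalar(lambda th: -(np.cos(th) + np.cos(th / n)),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return float(max(vals[k], -res.fun))


def period_single(I: float, n: int = 5) -> float:
    """Full burst-cycle period ``T = integral over one extended circle of
    dtheta / F(theta; I, n)`` by adaptive quadrature.

    Diverges as ``I`` approaches the threshold from above; for ``n = 1``
    the closed form ``2 pi / sqrt(I^2 - 4)`` is recovered.
    """
    Ic = 2.0
    if I <= Ic:
        raise ValueError(f"no rotation: I = {I} is at or below threshold {Ic}")
    L = 2.0 * np.pi * n
    # the flow is slowest near theta = 0; split the domain there
    val, _ = quad(lambda th: 1.0 / (I - np.cos(th) - np.cos(th / n)),
                  -L / 2, L / 2, points=[0.0], limit=400)
    return float(val)


def simulate_phase_single(params: Optional[PhaseParams] = None,
                          settings: Optional[SimSettings] = None) -> PhaseTrajectory:
    """Integrate one generative burster; the unwrapped phase is retained so
    rotation numbers are a plain difference quotient."""
    params = params or PhaseParams()
    settings = settings or SimSettings(t_end=1000.0, t_transient=100.0)
    traj: Trajectory = integrate_fixed_step(
        lambda t, y: phase_rhs_single(y, params.I, params.n),
        [params.theta0], settings,
    )
    return PhaseTrajectory(t=traj.t, theta=traj.y[:, 0], n=params.n,
                           transient_index=traj.transient_index,
                           drive=params.I)


def phase_spike_times(t: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Spike times of an unwrapped phase trajectory.

    Spikes are the passages of the maxima of ``V = -cos(theta)``, i.e. the
    upward crossings of odd multiples of pi. Counting uses the running
    maximum of the crossed-threshold index so that small non-monotone
    wiggles of the flow never double-count a passage; crossing times are
    linearly interpolated inside the step.
    """
    t = np.asarray(t, float)
    theta = np.asarray(theta, float)
    # index of the last odd-pi threshold at or below theta
    m = np.floor((theta - np.pi) / (2.0 * np.pi)).astype(np.int64)
    run = np.maximum.accumulate(m)
    times = []
    for k in np.flatnonzero(np.diff(run) > 0):
        # thresholds passed between sample k and k+1 (normally one)
        for j in range(run[k] + 1, run[k + 1] + 1):
            thr = (2 * j + 1) * np.pi
            th0, th1 = theta[k], theta[k + 1]
            if th1 == th0:
                times.append(t[k + 1])
            else:
                frac = np.clip((thr - th0) / (th1 - th0), 0.0, 1.0)
                times.append(t[k] + frac * (t[k + 1] - t[k]))
    return np.asarray(times)


def _cycle_slices(theta: np.ndarray, n: int):
    """Index ranges of complete extended-circle cycles (length 2 pi n)."""
    L = 2.0 * np.pi * n
    c = np.floor((theta - theta[0]) / L).astype(np.int64)
    run = np.maximum.accumulate(c)
    starts = [0]
    for k in np.flatnonzero(np.diff(run) > 0):
        starts.append(k + 1)
    return [(starts[i], starts[i + 1]) for i in range(len(starts) - 1)]


def spikes_per_cycle(traj: PhaseTrajectory, n: Optional[int] = None) -> int:
    """Spike count per full cycle of the extended circle.

    For the monotone suprathreshold flow this equals ``n`` exactly. Raises
    when the trajectory does not cover a complete cycle.
    """
    n = n or traj.n
    i0 = traj.transient_index
    theta = traj.theta[i0:]
    cycles = _cycle_slices(theta, n)
    if not cycles:
        raise ValueError("no complete cycle in the (post-transient) trajectory")
    t = traj.t[i0:]
    counts = []
    for a, b in cycles:
        counts.append(phase_spike_times(t[a:b + 1], theta[a:b + 1]).size)
    # all complete cycles agree for a monotone flow; report the modal count
    vals, freq = np.unique(counts, return_counts=True)
    return int(vals[np.argmax(freq)])


def isi_profile(traj: PhaseTrajectory) -> np.ndarray:
    """Within-burst inter-spike intervals of one complete cycle.

    Returns the ``n - 1`` intervals between the ``n`` spikes of the first
    complete post-transient cycle. The flow is slowest mid-bottleneck, so
    the first and last interval exceed the interior minimum (the parabolic
    signature).
    """
    i0 = traj.transient_index
    theta = traj.theta[i0:]
    t = traj.t[i0:]
    cycles = _cycle_slices(theta, traj.n)
    if not cycles:
        raise ValueError("no complete cycle in the (post-transient) trajectory")
    a, b = cycles[0]
    st = phase_spike_times(t[a:b + 1], theta[a:b + 1])
    return np.diff(st)
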