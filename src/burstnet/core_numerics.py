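"""Shared numerical plumbing for all simulation modules.

Fixed-step integrators (Heun = two-stage trapezoidal predictor-corrector,
and forward Euler), seeded sampling of heterogeneous applied drives, and
phase unwrapping on circles of arbitrary circumference.

All simulations in this package run on a fixed time grid with default
``dt = 0.05`` model time units; transients are specified in model time
units and marked on every returned trajectory rather than silently
discarded, so observables can choose their own analysis window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "METHODS",
    "DRIVE_SCHEMES",
    "IntegrationError",
    "SimSettings",
    "DriveSpec",
    "Trajectory",
    "integrate_fixed_step",
    "sample_drives",
    "unwrap_phase",
    "cell_seed",
]

METHODS = ("heun", "euler")
DRIVE_SCHEMES = ("random_uniform", "evenly_spaced")


class IntegrationError(RuntimeError):
    """Raised when a trajectory leaves the finite domain (numerical blow-up)."""


@dataclass
class SimSettings:
    """Integration settings shared by every simulation in the package.

    Parameters
    ----------
    dt:
        Fixed time step in model time units.
    t_end:
        Integration horizon; states are returned on ``t = 0, dt, ..., t_end``.
    t_transient:
        Initial window, in model time units, to exclude from analysis.
        Trajectories keep these samples but mark the first post-transient
        index.
    method:
        ``"heun"`` (second-order predictor-corrector) or ``"euler"``.
    seed:
        Non-negative integer seeding any randomness (initial conditions,
        drive sampling) tied to this run.
    record_every:
        Keep every ``record_every``-th step in network simulations to bound
        memory; single-unit simulations normally record every step.
    """

    dt: float = 0.05
    t_end: float = 1000.0
    t_transient: float = 200.0
    method: str = "heun"
    seed: int = 0
    record_every: int = 1

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not 0 <= self.t_transient < self.t_end:
            raise ValueError(
                f"need 0 <= t_transient < t_end, got {self.t_transient}, {self.t_end}"
            )
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt

    def replace(self, **kwargs) -> "SimSettings":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class DriveSpec:
    """Heterogeneous applied-drive population.

    Drives are symmetric about ``center`` with half-width ``half_width``
    (the dispersion parameter of both network models). ``random_uniform``
    draws i.i.d. values on ``[center - half_width, center + half_width]``;
    ``evenly_spaced`` places the ``count`` midpoints of equal subintervals.
    """

    center: float = 2.1
    half_width: float = 0.0
    count: int = 1
    scheme: str = "random_uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.scheme not in DRIVE_SCHEMES:
            raise ValueError(f"scheme must be one of {DRIVE_SCHEMES}")


@dataclass
class Trajectory:
    """Time grid, state matrix (n_times x n_dims) and the transient marker."""

    t: np.ndarray
    y: np.ndarray
    transient_index: int

    @property
    def t_post(self) -> np.ndarray:
        return self.t[self.transient_index :]

    @property
    def y_post(self) -> np.ndarray:
        return self.y[self.transient_index :]


def transient_index_of(t: np.ndarray, t_transient: float) -> int:
    """First index of ``t`` with ``t >= t_transient``."""
    return int(np.searchsorted(t, t_transient - 1e-12))


def integrate_fixed_step(rhs, y0, settings: SimSettings) -> Trajectory:
    """Integrate ``dy/dt = rhs(t, y)`` on a fixed grid.

    ``heun`` applies the two-stage trapezoidal predictor-corrector
    (second-order Runge-Kutta); ``euler`` the one-stage rule. The right-hand
    side must be deterministic and finite along the trajectory; a non-finite
    state aborts with :class:`IntegrationError` naming the blow-up time.
    """
    y = np.atleast_1d(np.asarray(y0, dtype=float)).copy()
    if not np.all(np.isfinite(y)):
        raise IntegrationError("initial state is not finite")
    dt = settings.dt
    n_steps = settings.n_steps
    out = np.empty((n_steps + 1, y.size))
    out[0] = y
    heun = settings.method == "heun"
    t = 0.0
    for k in range(1, n_steps + 1):
        k1 = np.asarray(rhs(t, y), dtype=float)
        if heun:
            k2 = np.asarray(rhs(t + dt, y + dt * k1), dtype=float)
            y = y + 0.5 * dt * (k1 + k2)
        else:
            y = y + dt * k1
        t = k * dt
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state at t = {t:g}")
        out[k] = y
    tgrid = settings.time_grid()
    return Trajectory(tgrid, out, transient_index_of(tgrid, settings.t_transient))


def sample_drives(spec: DriveSpec) -> np.ndarray:
    """Ordered sequence of ``count`` drive values per the spec's scheme.

    ``random_uniform`` is bit-reproducible for a fixed seed (PCG64 stream).
    """
    lo = spec.center - spec.half_width
    hi = spec.center + spec.half_width
    if spec.scheme == "evenly_spaced":
        i = np.arange(spec.count)
        return lo + (hi - lo) * (i + 0.5) / spec.count
    rng = np.random.default_rng(spec.seed)
    return rng.uniform(lo, hi, size=spec.count)


def unwrap_phase(wrapped: np.ndarray, period: float = 2 * np.pi) -> np.ndarray:
    """Remove wrap discontinuities from a phase series on a circle of the
    given circumference; ``unwrap(x) mod period`` equals the input.

    Successive samples should differ by less than half the period; larger
    jumps are ambiguous and flagged with a warning.
    """
    x = np.asarray(wrapped, dtype=float)
    if x.size >= 2:
        d = np.diff(x)
        wrapped_jumps = np.abs(d - period * np.round(d / period))
        if np.any(wrapped_jumps > period / 2 - 1e-12):
            warnings.warn(
                "phase jump at or beyond half the period; unwrap is ambiguous",
                RuntimeWarning,
                stacklevel=2,
            )
    return np.unwrap(x, period=period)


def cell_seed(master_seed: int, *indices: int) -> int:
    """Deterministic per-cell seed derived from a master seed and grid indices.

    Cells of a parameter sweep are seeded independently of execution order;
    the result is kept below 2**31 for portability.
    """
    ss = np.random.SeedSequence([int(master_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
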