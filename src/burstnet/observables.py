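"""Population summaries for both network models.

* ``V_mean`` — population-averaged (membrane-like) potential.
* ``R`` — time-averaged squared fluctuation of ``V_mean`` over the analysis
  window; the coherence/incoherence order parameter (non-zero for a
  collectively oscillating population, O(1/N) for an incoherent one).
* ``R_theta`` — population mean of ``cos(theta)``, a Kuramoto-like order
  parameter bounded by 1 in absolute value.
* ``rho_i`` — rotation numbers: long-time average phase velocity per neuron
  (phase networks) or ``2 pi x spike count / window`` (voltage networks);
  zero identifies silent neurons.
* ``chi`` — normalized coherence: std over time of ``V_mean`` divided by
  the population-mean per-neuron std, a scale-free variant of ``R`` that
  equals 1 for identical oscillators and decays like 1/sqrt(N) for
  independent ones.
* global-cycle phase — a piecewise-linear instantaneous phase of ``V_mean``
  rising 0 to pi from each cycle minimum to the interior maximum and pi to
  2 pi back to the next minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .biophysical_neuron import detect_spikes

__all__ = [
    "OrderParameterReport",
    "mean_signal",
    "variance_order_parameter",
    "kuramoto_like_order",
    "rotation_numbers",
    "rotation_numbers_from_spikes",
    "chi_coherence",
    "global_cycle_phase",
    "array_diagram",
    "phase_network_report",
    "full_network_report",
]

EPS_SILENT = 0.01  # rad / time unit: rotation numbers below this are "silent"


@dataclass
class OrderParameterReport:
    """Per-run bundle of order parameters feeding the state classifier."""

    R: float
    chi: float
    rho: np.ndarray
    f_silent: float
    R_theta_series: Optional[np.ndarray] = None

    @property
    def R_theta_amplitude(self) -> float:
        if self.R_theta_series is None or self.R_theta_series.size == 0:
            return float("nan")
        return float(self.R_theta_series.max() - self.R_theta_series.min())

    def diagnostics(self) -> dict:
        return {"R": self.R, "chi": self.chi, "f_silent": self.f_silent,
                "R_theta_amplitude": self.R_theta_amplitude}


def mean_signal(V: np.ndarray) -> np.ndarray:
    """Arithmetic mean across neurons at each time (V is time x neuron)."""
    V = np.asarray(V, float)
    if V.size == 0:
        raise ValueError("empty matrix")
    return V.mean(axis=1)


def variance_order_parameter(V_mean: np.ndarray) -> float:
    """Time-averaged squared fluctuation of ``V_mean`` over the window:
    ``mean((V_mean - <V_mean>)^2)``. Pass the post-transient slice."""
    v = np.asarray(V_mean, float)
    if v.size == 0:
        raise ValueError("empty analysis window")
    return float(np.mean((v - v.mean()) ** 2))


def kuramoto_like_order(theta: np.ndarray) -> np.ndarray:
    """``R_theta(t) = mean_i cos(theta_i(t))`` (theta is time x neuron)."""
    return np.cos(np.asarray(theta, float)).mean(axis=1)


def rotation_numbers(t: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Average phase velocity per neuron over the window (unwrapped phases,
    time x neuron): ``(theta(t1) - theta(t0)) / (t1 - t0)``."""
    t = np.asarray(t, float)
    theta = np.asarray(theta, float)
    if t.size < 2:
        raise ValueError("window must contain at least two samples")
    return (theta[-1] - theta[0]) / (t[-1] - t[0])


def rotation_numbers_from_spikes(t: np.ndarray, V: np.ndarray,
                                 threshold: float = 0.0,
                                 refractory: float = 2.0) -> np.ndarray:
    """Voltage-network rotation numbers: ``2 pi x spike count / window``
    per neuron (V is time x neuron)."""
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    window = t[-1] - t[0]
    if window <= 0:
        raise ValueError("window must have positive length")
    return np.array([
        2.0 * np.pi * detect_spikes(t, V[:, i], threshold, refractory).size / window
        for i in range(V.shape[1])
    ])


def chi_coherence(V: np.ndarray) -> float:
    """Normalized coherence: std over time of ``V_mean`` divided by the
    population mean of per-neuron std over time; 0 by convention when the
    whole population is flat (all-silent)."""
    V = np.asarray(V, float)
    if V.ndim != 2 or V.shape[1] < 2:
        raise ValueError("need a time x neuron matrix with >= 2 neurons")
    denom = V.std(axis=0).mean()
    if denom < 1e-12:
        return 0.0
    return float(V.mean(axis=1).std() / denom)


def global_cycle_phase(t: np.ndarray, V_mean: np.ndarray,
                       prominence_frac: float = 0.01):
    """Instantaneous global phase of ``V_mean`` by linear interpolation.

    Global cycles are delimited by successive strict local minima of
    ``V_mean`` (with a prominence floor of ``prominence_frac`` times the
    series range, to suppress integration ripple). Within each cycle the
    phase rises linearly 0 -> pi from the minimum to the interior maximum
    and pi -> 2 pi from the maximum to the next minimum. Returns
    ``(times, phases)`` restricted to complete cycles.
    """
    t = np.asarray(t, float)
    v = np.asarray(V_mean, float)
    rng = v.max() - v.min()
    if rng < 1e-12:
        raise ValueError("no complete global cycle: series is constant")
    prom = prominence_frac * rng
    minima, _ = find_peaks(-v, prominence=prom)
    if minima.size < 2:
        raise ValueError("no complete global cycle: fewer than 2 minima")
    times, phases = [], []
    for a, b in zip(minima[:-1], minima[1:]):
        seg = v[a:b + 1]
        m = a + int(np.argmax(seg))
        if m == a or m == b:  # no interior maximum; skip degenerate cycle
            continue
        for k in range(a, b):
            if k <= m:
                ph = np.pi * (t[k] - t[a]) / (t[m] - t[a])
            else:
                ph = np.pi + np.pi * (t[k] - t[m]) / (t[b] - t[m])
            times.append(t[k])
            phases.append(ph)
    if not times:
        raise ValueError("no complete global cycle with an interior maximum")
    return np.asarray(times), np.asarray(phases)


def array_diagram(matrix: np.ndarray, sort_by: Optional[np.ndarray] = None) -> np.ndarray:
    """Neuron x time matrix for raster-style display.

    The input is time x neuron (as recorded); the output is transposed,
    with rows optionally sorted by a per-neuron key (e.g. initial phase).
    """
    M = np.asarray(matrix, float).T
    if sort_by is not None:
        M = M[np.argsort(np.asarray(sort_by))]
    return M


def phase_network_report(traj, eps_silent: float = EPS_SILENT) -> OrderParameterReport:
    """Order parameters of a phase-network trajectory on its post-transient
    window (V = -cos(theta))."""
    i0 = traj.transient_index
    t = traj.t[i0:]
    theta = traj.theta[i0:]
    V = -np.cos(theta)
    rho = rotation_numbers(t, theta)
    return OrderParameterReport(
        R=variance_order_parameter(V.mean(axis=1)),
        chi=chi_coherence(V),
        rho=rho,
        f_silent=float(np.mean(np.abs(rho) < eps_silent)),
        R_theta_series=np.cos(theta).mean(axis=1),
    )


def full_network_report(traj, spike_threshold: float = 0.0,
                        refractory: float = 2.0) -> OrderParameterReport:
    """Order parameters of a biophysical-network trajectory; silence is
    zero detected spikes in the post-transient window."""
    i0 = traj.transient_index
    t = traj.t[i0:]
    V = traj.V[i0:]
    rho = rotation_numbers_from_spikes(t, V, spike_threshold, refractory)
    return OrderParameterReport(
        R=variance_order_parameter(V.mean(axis=1)),
        chi=chi_coherence(V),
        rho=rho,
        f_silent=float(np.mean(rho == 0.0)),
        R_theta_series=None,
    )
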