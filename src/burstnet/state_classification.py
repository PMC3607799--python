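"""SR/PO/IN labeling and the (K, dI) phase-diagram sweep.

A simulated network is classified from its order-parameter report:

* PO (partial oscillation) — a non-negligible fraction of neurons is
  silent (rotation number below the silence tolerance) while others fire;
  the all-silent quiescent state (oscillator death) is the QD sublabel,
  folded into PO.
* SR (synchronized regime) — essentially all neurons fire and the
  normalized coherence ``chi`` is high; in-phase and anti-phase clustered
  synchrony are lumped together.
* IN (incoherent) — essentially all neurons fire but the mean potential is
  nearly stationary (low ``chi``).

Thresholds are frozen in :class:`ClassifierThresholds` (``chi >= 0.5`` for
SR, silent fraction ``>= 0.05`` for PO, silence tolerance 0.01 rad/time)
and are never tuned per run.

The sweep integrates one network per (K, dI) grid cell with a per-cell
seed derived deterministically from the master seed and the grid indices,
so rows are reproducible under any execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_numerics import cell_seed
from .full_network import FullNetConfig, simulate_full_network
from .observables import (OrderParameterReport, full_network_report,
                          phase_network_report)
from .phase_network import PhaseNetConfig, simulate_phase_network

__all__ = [
    "ClassifierThresholds",
    "StateLabel",
    "classify_state",
    "run_cell",
    "sweep_phase_diagram",
    "count_states",
]

LABELS = ("SR", "PO", "IN")


@dataclass(frozen=True)
class ClassifierThresholds:
    chi_thr: float = 0.5
    f_thr: float = 0.05
    eps_silent: float = 0.01


@dataclass
class StateLabel:
    """Categorical network state with diagnostics."""

    label: str
    sublabel: str = "none"  # "QD" marks the all-silent case (within PO)
    diagnostics: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.sublabel == "QD" and self.label != "PO":
            raise ValueError("QD sublabel is only defined within PO")


def classify_state(report: OrderParameterReport,
                   thresholds: ClassifierThresholds = ClassifierThresholds()
                   ) -> StateLabel:
    """Decision rules: all silent -> PO/QD; silent fraction >= f_thr -> PO;
    chi >= chi_thr -> SR; otherwise IN."""
    diag = report.diagnostics()
    if report.f_silent >= 1.0:
        return StateLabel("PO", "QD", diag)
    if report.f_silent >= thresholds.f_thr:
        return StateLabel("PO", "none", diag)
    if report.chi >= thresholds.chi_thr:
        return StateLabel("SR", "none", diag)
    return StateLabel("IN", "none", diag)


def run_cell(model: str, K: float, dI: float, seed: int,
             base_config=None,
             thresholds: ClassifierThresholds = ClassifierThresholds()):
    """Simulate and classify one (K, dI) cell; returns (report, label)."""
    if model == "phase":
        base = base_config or PhaseNetConfig()
        cfg = replace(base, K=float(K), dI=float(dI),
                      settings=base.settings.replace(seed=int(seed)))
        traj = simulate_phase_network(cfg)
        report = phase_network_report(traj, eps_silent=thresholds.eps_silent)
    elif model == "full":
        base = base_config or FullNetConfig()
        cfg = replace(base, K=float(K), dI=float(dI),
                      settings=base.settings.replace(seed=int(seed)))
        traj = simulate_full_network(cfg)
        report = full_network_report(traj)
    else:
        raise ValueError("model must be 'phase' or 'full'")
    return report, classify_state(report, thresholds)


def default_K_grid() -> np.ndarray:
    """Desk-scale 11-point coupling axis on (0, 1]: 0.01 then 0.1 ... 1.0.

    The degenerate zero column is omitted (K = 0 is the exactly uncoupled
    special case, not a sweep cell); the smallest column sits at the
    weak-coupling incoherent reference point K = 0.01. The full-resolution
    preset is the 100-point axis 0.01 ... 1.00.
    """
    return np.concatenate([[0.01], np.round(np.arange(0.1, 1.001, 0.1), 10)])


def default_dI_grid() -> np.ndarray:
    """Desk-scale 11-point dispersion axis on (0, 1]: 0.001 then 0.1 ... 1.0.

    The synchronized regime lives at near-zero dispersion (the reference
    synchronized runs use dI = 0.001-0.002), so the smallest column is
    placed at dI = 0.001 rather than at the degenerate dI = 0.
    """
    return np.concatenate([[0.001], np.round(np.arange(0.1, 1.001, 0.1), 10)])


def full_resolution_grid() -> np.ndarray:
    return np.round(np.arange(0.01, 1.001, 0.01), 10)


def sweep_phase_diagram(model: str = "phase",
                        K_values: Optional[Sequence[float]] = None,
                        dI_values: Optional[Sequence[float]] = None,
                        base_config=None,
                        master_seed: int = 0,
                        thresholds: ClassifierThresholds = ClassifierThresholds(),
                        n_jobs: int = 1,
                        progress: bool = False) -> pd.DataFrame:
    """One simulation + classification per (K, dI) cell.

    Returns a long-format table with one row per cell, in deterministic
    (K-major) order; per-cell failures are recorded in the row's ``error``
    column and the sweep continues.
    """
    K_values = np.asarray(default_K_grid() if K_values is None else K_values, float)
    dI_values = np.asarray(default_dI_grid() if dI_values is None else dI_values, float)
    if K_values.size == 0 or dI_values.size == 0:
        raise ValueError("grids must be nonempty")

    cells = [(i, j, K, dI) for i, K in enumerate(K_values)
             for j, dI in enumerate(dI_values)]

    def one(i, j, K, dI):
        seed = cell_seed(master_seed, i, j)
        row = {"K": K, "dI": dI, "seed": seed, "R": np.nan,
               "R_theta_amplitude": np.nan, "chi": np.nan,
               "f_silent": np.nan, "label": "", "sublabel": "", "error": ""}
        try:
            report, label = run_cell(model, K, dI, seed, base_config, thresholds)
            row.update(R=report.R, chi=report.chi, f_silent=report.f_silent,
                       R_theta_amplitude=report.R_theta_amplitude,
                       label=label.label, sublabel=label.sublabel)
        except Exception as exc:  # pragma: no cover - defensive
            row["error"] = f"{type(exc).__name__}: {exc}"
        return row

    if n_jobs != 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(delayed(one)(*c) for c in cells)
    else:
        rows = []
        for idx, c in enumerate(cells):
            rows.append(one(*c))
            if progress and (idx + 1) % 10 == 0:
                print(f"  sweep cell {idx + 1}/{len(cells)}", flush=True)
    return pd.DataFrame(rows)


def count_states(table: pd.DataFrame) -> int:
    """Number of distinct labels present (QD is already folded into PO);
    empty-label rows (failed cells) are excluded."""
    if len(table) == 0:
        raise ValueError("empty sweep table")
    labels = set(table["label"]) - {""}
    return len(labels)
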