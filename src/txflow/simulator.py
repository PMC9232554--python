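"""Numerical integration of chemostat TX-TL systems and forward parameter sensitivities.

Controls are piecewise constant per refresh cycle, so integration is restarted
at every cycle boundary (the only points of discontinuity); within a cycle the
right-hand side is smooth and LSODA handles the mild stiffness of the
maturation/dilution timescale separation.

Sensitivities are central finite differences on log-parameters: rates span
several orders of magnitude, so relative steps are the natural perturbation.
Entries are reported relatively, (dy/dtheta) * theta / y, with the denominator
floored to keep near-zero observables from blowing up the scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .chemostat_io import InflowProtocol, protocol_to_controls
from .circuit_model import ODESystem, ParameterSet, build_ode_system

#: floor for relative-scaling denominators (nM)
Y_FLOOR = 1e-9


class IntegrationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Simulated time course: full state matrix plus reporter observables."""

    times: np.ndarray  # min
    states: np.ndarray  # [time, species]
    species: tuple[str, ...]
    observables: np.ndarray  # [time, reporters] (mature pools)
    observable_species: tuple[str, ...]

    def state(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def observable(self, name: str) -> np.ndarray:
        return self.observables[:, self.observable_species.index(name)]

    def to_frame(self):
        """Tidy (time_min, species, value_nM) DataFrame."""
        import pandas as pd

        recs = []
        for j, s in enumerate(self.species):
            for i, t in enumerate(self.times):
                recs.append((float(t), s, float(self.states[i, j])))
        return pd.DataFrame(recs, columns=["time_min", "species", "value_nM"])


@dataclass
class SensitivityMatrix:
    """Relative output sensitivities S[t, obs, theta] with a fixed label order."""

    entries: np.ndarray  # [time, obs, theta]
    times: np.ndarray
    observable_species: tuple[str, ...]
    labels: tuple[str, ...]

    def flattened(self) -> np.ndarray:
        """(time*obs, theta) design matrix used for FIM and collinearity."""
        t, o, p = self.entries.shape
        return self.entries.reshape(t * o, p)

    def column(self, label: str) -> np.ndarray:
        return self.flattened()[:, self.labels.index(label)]


def cycle_boundary_times(protocol: InflowProtocol) -> np.ndarray:
    """Default observation grid: one image per refresh cycle."""
    return np.arange(protocol.n_cycles + 1) * protocol.config.cycle_time


def simulate(
    system: ODESystem,
    protocol: InflowProtocol,
    t_grid: Sequence[float] | None = None,
    y0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate ``system`` under ``protocol``, restarting at cycle boundaries.

    ``t_grid`` defaults to cycle boundaries; requested times must lie within
    the protocol horizon.
    """
    if t_grid is None:
        t_grid = cycle_boundary_times(protocol)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty time grid")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if t_grid[0] < -1e-9 or t_grid[-1] > protocol.horizon + 1e-9:
        raise ValueError("time grid extends beyond the protocol horizon")

    kin_fn, lam_fn = protocol_to_controls(protocol)
    T = protocol.config.cycle_time
    y = np.zeros(system.n_states) if y0 is None else np.asarray(y0, dtype=float).copy()
    if y.shape != (system.n_states,):
        raise ValueError("initial state has wrong dimension")

    out = np.empty((t_grid.size, system.n_states))
    filled = 0
    if t_grid[0] <= 1e-12:
        out[0] = y
        filled = 1

    t_now = 0.0
    n_cycles = protocol.n_cycles
    for j in range(n_cycles):
        t_end = min((j + 1) * T, float(t_grid[-1]))
        if t_end <= t_now + 1e-12:
            break
        t_mid = 0.5 * (t_now + t_end)
        kin = kin_fn(t_mid)
        lam = lam_fn(t_mid)
        wanted = t_grid[(t_grid > t_now + 1e-12) & (t_grid <= t_end + 1e-12)]
        sol = solve_ivp(
            system.rhs,
            (t_now, t_end),
            y,
            t_eval=wanted if wanted.size else None,
            args=(kin, lam),
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"integrator failed in cycle {j} ({sol.message}); state head "
                f"{np.array2string(y[:4], precision=3)}"
            )
        if wanted.size:
            out[filled : filled + wanted.size] = sol.y.T
            filled += wanted.size
            y = sol.y[:, -1].copy()
            if abs(sol.t[-1] - t_end) > 1e-9:
                # continue to the boundary so the next cycle starts cleanly
                sol2 = solve_ivp(
                    system.rhs, (sol.t[-1], t_end), y, args=(kin, lam),
                    method="LSODA", rtol=rtol, atol=atol,
                )
                if not sol2.success:
                    raise IntegrationError(f"integrator failed in cycle {j}")
                y = sol2.y[:, -1].copy()
        else:
            y = sol.y[:, -1].copy()
        t_now = t_end
        if t_now >= t_grid[-1] - 1e-9:
            break

    if filled != t_grid.size:
        raise IntegrationError("failed to fill all requested time points")
    states = np.clip(out, 0.0, None)  # integrator undershoot at 0 is numerical
    obs = states[:, system.observable_indices] if system.observable_species else np.zeros((t_grid.size, 0))
    return Trajectory(
        times=t_grid,
        states=states,
        species=system.species,
        observables=obs,
        observable_species=system.observable_species,
    )


def simulate_batch(
    system: ODESystem,
    y0: np.ndarray,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Batch-mode integration: no inflow, no dilution, fixed initial templates."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("batch time grid must be strictly increasing with >= 2 points")
    kin = np.zeros(len(system.network.constructs))
    sol = solve_ivp(
        system.rhs,
        (t_grid[0], t_grid[-1]),
        np.asarray(y0, dtype=float),
        t_eval=t_grid,
        args=(kin, 0.0),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"batch integration failed: {sol.message}")
    states = np.clip(sol.y.T, 0.0, None)
    obs = states[:, system.observable_indices] if system.observable_species else np.zeros((t_grid.size, 0))
    return Trajectory(
        times=t_grid,
        states=states,
        species=system.species,
        observables=obs,
        observable_species=system.observable_species,
    )


def batch_sensitivities(
    network,
    params: ParameterSet,
    y0: np.ndarray,
    t_grid: Sequence[float],
    labels: Sequence[str] | None = None,
    rel_step: float = 1e-4,
    rtol: float = 1e-8,
    activity=None,
    scaling: str = "relative",
) -> SensitivityMatrix:
    """Relative sensitivities of a batch experiment (same scheme as flow mode).

    ``activity`` is forwarded to the system builder so batch extract aging can
    be included in the sensitivity model.
    """
    labels = list(labels) if labels is not None else params.labels()
    t_grid = np.asarray(t_grid, dtype=float)
    base_sys = build_ode_system(network, params, activity=activity)
    base = simulate_batch(base_sys, y0, t_grid, rtol=rtol)
    y_ref = np.maximum(np.abs(base.observables), Y_FLOOR)
    n_obs = len(base.observable_species)
    S = np.empty((t_grid.size, n_obs, len(labels)))
    for k, lbl in enumerate(labels):
        theta = params[lbl]
        hi = params.copy()
        lo = params.copy()
        hi[lbl] = theta * math.exp(rel_step)
        lo[lbl] = theta * math.exp(-rel_step)
        y_hi = simulate_batch(build_ode_system(network, hi, activity=activity), y0, t_grid, rtol=rtol).observables
        y_lo = simulate_batch(build_ode_system(network, lo, activity=activity), y0, t_grid, rtol=rtol).observables
        col = (y_hi - y_lo) / (2.0 * rel_step)
        if scaling == "relative":
            col = col / y_ref
        if not np.all(np.isfinite(col)):
            raise IntegrationError(f"non-finite sensitivity for parameter {lbl}")
        S[:, :, k] = col
    return SensitivityMatrix(
        entries=S,
        times=t_grid,
        observable_species=base.observable_species,
        labels=tuple(labels),
    )


def forward_sensitivities(
    network,
    params: ParameterSet,
    protocol: InflowProtocol,
    labels: Sequence[str] | None = None,
    t_grid: Sequence[float] | None = None,
    rel_step: float = 1e-4,
    rtol: float = 1e-8,
    y0: np.ndarray | None = None,
    scaling: str = "relative",
) -> SensitivityMatrix:
    """Observable sensitivities by central differences on log-parameters.

    ``scaling="relative"`` (default): S[t, obs, k] = (dy/dlog theta_k) /
    max(|y|, floor) = the usual relative sensitivity theta/y * dy/dtheta, the
    natural input for collinearity analysis.  ``scaling="absolute"``: theta *
    dy/dtheta in nM, the natural input for information (FIM) scoring against a
    fixed measurement-noise scale, where signal magnitude must count.
    """
    labels = list(labels) if labels is not None else params.labels()
    if t_grid is None:
        t_grid = cycle_boundary_times(protocol)
    t_grid = np.asarray(t_grid, dtype=float)

    base_sys = build_ode_system(network, params)
    base = simulate(base_sys, protocol, t_grid, rtol=rtol, y0=y0)
    y_ref = np.maximum(np.abs(base.observables), Y_FLOOR)

    n_obs = len(base.observable_species)
    S = np.empty((t_grid.size, n_obs, len(labels)))
    h = rel_step
    for k, lbl in enumerate(labels):
        theta = params[lbl]
        lo = params.copy()
        hi = params.copy()
        hi[lbl] = theta * math.exp(h)
        lo[lbl] = theta * math.exp(-h)
        y_hi = simulate(build_ode_system(network, hi), protocol, t_grid, rtol=rtol, y0=y0).observables
        y_lo = simulate(build_ode_system(network, lo), protocol, t_grid, rtol=rtol, y0=y0).observables
        col = (y_hi - y_lo) / (2.0 * h)
        if scaling == "relative":
            col = col / y_ref
        elif scaling != "absolute":
            raise ValueError(f"unknown scaling {scaling!r}")
        if not np.all(np.isfinite(col)):
            raise IntegrationError(f"non-finite sensitivity for parameter {lbl}")
        S[:, :, k] = col
    return SensitivityMatrix(
        entries=S,
        times=t_grid,
        observable_species=base.observable_species,
        labels=tuple(labels),
    )


def write_trajectory_csv(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)
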