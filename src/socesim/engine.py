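"""Simulation engine: full ODE assembly, event-driven integration, steady states.

Continuity equations (well-mixed compartments; all fluxes as defined in
:mod:`socesim.fluxes`):

    d[Ca]_Cyt/dt = J_IP3R + J_RyR + J_Leak − J_SERCA,Cyt − J_PMCA
                   + (n_Ju/V_Cyt)·J_Diff − d[Ca]_B,Cyt/dt
    d[Ca]_ER/dt  = (V_Cyt/V_ER)·(J_SERCA,Cyt − J_IP3R − J_RyR − J_Leak)
                   + (n_Ju·V_Ju/V_ER)·J_SERCA,Ju − β_CSQ
    d[Ca]_Ju/dt  = J_CRAC − J_SERCA,Ju − J_Diff/V_Ju

where β_CSQ is the net rate of Ca²⁺ binding to calsequestrin.  The release
and leak fluxes carry the V_Cyt/V_ER prefactor in the ER equation so that the
amount of calcium leaving one compartment equals the amount entering the
other; with PMCA and CRAC disabled the total cell calcium
V_Cyt·([Ca]_Cyt + [Ca]_B,Cyt) + V_ER·([Ca]_ER + [CSQ]_bound) + n_Ju·V_Ju·[Ca]_Ju
is a conserved quantity.

Protocols are ordered lists of timed parameter mutations (drug applications,
bath changes).  Integration restarts at every event time so discontinuities
are sharp, and recorded parameter-dependent quantities (fluxes) switch exactly
at the event timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import fluxes as fx
from . import gating as gt
from .parameters import ModelParameters
from .state import STATE_NAMES, CalciumState, GatingState, initial_state, pack_state, unpack_state

__all__ = [
    "ProtocolEvent",
    "Protocol",
    "SolverSettings",
    "SimulationTrace",
    "WholeCellCurrentHook",
    "assemble_rhs",
    "compute_fluxes",
    "integrate",
    "find_steady_state",
    "integrate_with_vm",
]

_NEGATIVE_ABORT_TOL = 1e-6  # µM; recorded states below −tol abort with diagnostics


@dataclass(frozen=True)
class ProtocolEvent:
    """A timed parameter mutation, e.g. ``ProtocolEvent(66.0, "serca.R_serca", 0.0)``."""

    time: float
    parameter_path: str
    new_value: float


@dataclass
class Protocol:
    """Ordered timed events plus the simulation horizon and recording grid."""

    events: Sequence[ProtocolEvent] = ()
    t_end: float = 600.0
    record_interval: float = 0.1

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(t < 0 or t > self.t_end for t in times):
            raise ValueError("event times must lie within [0, t_end]")
        if self.record_interval <= 0 or self.t_end <= 0:
            raise ValueError("t_end and record_interval must be positive")


@dataclass
class SolverSettings:
    """Integrator configuration.

    ``method="adaptive"`` uses a stiff adaptive solver (LSODA) with the given
    tolerances; ``method="euler"`` is the fixed-step forward Euler validation
    mode (the step must resolve the fastest buffer kinetics, ≲1e-5 s).
    """

    method: str = "adaptive"
    step_size: float = 5e-7
    rel_tol: float = 1e-8
    abs_tol: float = 1e-12
    max_step: float = np.inf

    def __post_init__(self) -> None:
        if self.method not in ("adaptive", "euler"):
            raise ValueError("method must be 'adaptive' or 'euler'")
        if self.step_size <= 0 or self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("step size and tolerances must be positive")


@dataclass
class WholeCellCurrentHook:
    """Pluggable whole-cell current for membrane-potential co-integration.

    ``current(v_m_mV, calcium, gating, t) -> I (A)``; positive (outward)
    current hyperpolarizes: C·dV_m/dt = −I_whole_cell.
    """

    current: Callable[[float, CalciumState, GatingState, float], float]
    capacitance: float  # F

    def __post_init__(self) -> None:
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")


@dataclass
class SimulationTrace:
    """Time-indexed record of all state variables and fluxes."""

    time: np.ndarray
    states: np.ndarray          # (n, 18), columns per STATE_NAMES
    fluxes: np.ndarray          # (n, 9), columns per fluxes.FLUX_NAMES
    rho_crac: np.ndarray
    v_m: np.ndarray | None = None
    summary: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        if self.states.shape[0] != n or self.fluxes.shape[0] != n or len(self.rho_crac) != n:
            raise ValueError("trace arrays must share the time axis length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("trace time must be strictly increasing")

    def column(self, name: str) -> np.ndarray:
        if name == "time":
            return self.time
        if name == "rho_crac":
            return self.rho_crac
        if name in STATE_NAMES:
            return self.states[:, STATE_NAMES.index(name)]
        if name in fx.FLUX_NAMES:
            return self.fluxes[:, fx.FLUX_NAMES.index(name)]
        raise KeyError(name)

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask selecting records with t0 <= t < t1."""
        return (self.time >= t0) & (self.time < t1)

    def final_state(self) -> tuple[CalciumState, GatingState]:
        return unpack_state(self.states[-1])

    def to_dataframe(self) -> pd.DataFrame:
        data = {"time": self.time}
        data.update({n: self.states[:, i] for i, n in enumerate(STATE_NAMES)})
        data["rho_crac"] = self.rho_crac
        data.update({n: self.fluxes[:, i] for i, n in enumerate(fx.FLUX_NAMES)})
        if self.v_m is not None:
            data["v_m"] = self.v_m
        return pd.DataFrame(data)


# --------------------------------------------------------------------------
# Right-hand side
# --------------------------------------------------------------------------

def compute_fluxes(y: np.ndarray, params: ModelParameters, v_m: float | None = None) -> fx.FluxRecord:
    """Evaluate every flux law at a packed state vector."""
    ca_cyt, ca_er, ca_jun = max(y[0], 0.0), max(y[1], 0.0), max(y[2], 0.0)
    rho = min(max(y[7], 0.0), 1.0)
    vm = params.membrane_potential if v_m is None else v_m
    p_ip3r = gt.ip3r_open_probability(np.clip(y[8:14], 0.0, 1.0))
    p_ryr = min(gt.ryr_open_fraction(np.clip(y[14:18], 0.0, 1.0)), 1.0)
    j_crac, i_crac = fx.crac_flux(vm, params.ca_ext, ca_jun, rho, params)
    return fx.FluxRecord(
        j_ip3r=fx.ip3r_flux(p_ip3r, ca_er, ca_cyt, params),
        j_ryr=fx.ryr_flux(p_ryr, ca_er, ca_cyt, params),
        j_leak=fx.leak_flux(ca_er, ca_cyt, params),
        j_serca_cyt=fx.serca_flux(ca_cyt, ca_er, params),
        j_serca_jun=fx.serca_flux(ca_jun, ca_er, params),
        j_pmca=fx.pmca_flux(ca_cyt, params),
        j_crac=j_crac,
        j_diff=fx.diffusion_flux(ca_jun, ca_cyt, params),
        i_crac=i_crac,
    )


def assemble_rhs(t: float, y: np.ndarray, params: ModelParameters, v_m: float | None = None) -> np.ndarray:
    """Full 18-component derivative vector at time t (t enters only via events)."""
    del t
    g = params.geometry
    f = compute_fluxes(y, params, v_m)
    d_buf = gt.cytosolic_buffer_rhs(y[3], max(y[0], 0.0), params)
    d_csq = gt.csq_buffer_rhs(y[4], max(y[1], 0.0), params)
    beta_csq = -d_csq  # net Ca binding rate to CSQ, µM/s
    release = f.j_ip3r + f.j_ryr + f.j_leak

    dy = np.empty(18)
    dy[0] = (
        release - f.j_serca_cyt - f.j_pmca + g.n_junctions / g.cytosol_volume * f.j_diff - d_buf
    )
    dy[1] = (
        g.cytosol_volume / g.er_volume * (f.j_serca_cyt - release)
        + g.n_junctions * g.junction_volume / g.er_volume * f.j_serca_jun
        - beta_csq
    )
    dy[2] = f.j_crac - f.j_serca_jun - f.j_diff / g.junction_volume
    dy[3] = d_buf
    dy[4] = d_csq
    dy[5] = gt.ip3_rhs(max(y[5], 0.0), max(y[0], 0.0), params)
    dy[6] = gt.stim1_rhs(max(y[6], 0.0), max(y[1], 0.0), params)
    dy[7] = gt.crac_formation_rhs(max(y[7], 0.0), max(y[6], 0.0), params)
    dy[8:14] = gt.ip3r_states_rhs(y[8:14], max(y[0], 0.0), max(y[5], 0.0), params)
    dy[14:18] = gt.ryr_states_rhs(y[14:18], max(y[0], 0.0), max(y[4], 0.0), params)

    if not np.all(np.isfinite(dy)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(dy))]
        raise FloatingPointError(f"non-finite derivative for: {', '.join(bad)}")
    return dy


# --------------------------------------------------------------------------
# Integration
# --------------------------------------------------------------------------

def _check_recorded(times: np.ndarray, states: np.ndarray) -> None:
    bad = np.argwhere(states < -_NEGATIVE_ABORT_TOL)
    if bad.size:
        i, j = bad[0]
        raise RuntimeError(
            f"negative concentration beyond tolerance: {STATE_NAMES[j]} = "
            f"{states[i, j]:.3e} at t = {times[i]:.3f} s"
        )


def _segment_adaptive(rhs, y0, t0, t1, t_eval, solver: SolverSettings):
    appended_end = t_eval[-1] < t1
    t_req = np.append(t_eval, t1) if appended_end else t_eval
    sol = solve_ivp(
        rhs,
        (t0, t1),
        y0,
        method="LSODA",
        rtol=solver.rel_tol,
        atol=solver.abs_tol,
        max_step=solver.max_step,
        t_eval=t_req,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"solver failed on [{t0}, {t1}]: {sol.message}")
    y_end = sol.y[:, -1].copy()
    if appended_end:  # the segment endpoint advances the state but is not a record
        return sol.t[:-1], sol.y.T[:-1], y_end
    return sol.t, sol.y.T, y_end


def _segment_euler(rhs, y0, t0, t1, t_eval, solver: SolverSettings):
    dt = solver.step_size
    n_steps = int(round((t1 - t0) / dt))
    n_steps = max(n_steps, 1)
    y = np.array(y0, dtype=float)
    rec_t, rec_y = [], []
    next_rec = 0
    t = t0
    for i in range(n_steps):
        while next_rec < len(t_eval) and t_eval[next_rec] <= t + dt * 0.5:
            rec_t.append(t_eval[next_rec])
            rec_y.append(y.copy())
            next_rec += 1
        y = y + dt * rhs(t, y)
        t = t0 + (i + 1) * dt
    while next_rec < len(t_eval):
        rec_t.append(t_eval[next_rec])
        rec_y.append(y.copy())
        next_rec += 1
    return np.array(rec_t), np.array(rec_y), y


def integrate(
    calcium: CalciumState,
    gating: GatingState,
    params: ModelParameters,
    protocol: Protocol,
    solver: SolverSettings | None = None,
) -> SimulationTrace:
    """Integrate the full system under a timed protocol.

    Integration proceeds piecewise between events; each event mutates its
    parameter exactly at its timestamp.  The trace records state and fluxes on
    the regular ``record_interval`` grid (fluxes evaluated with the parameter
    set in force at each record time) and is bit-for-bit reproducible for
    fixed settings.
    """
    solver = solver or SolverSettings()
    local = params.copy_with()
    y = pack_state(calcium, gating)
    grid = np.arange(0.0, protocol.t_end + protocol.record_interval * 0.5, protocol.record_interval)
    boundaries = [e.time for e in protocol.events] + [protocol.t_end]

    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    all_f: list[np.ndarray] = []
    t0 = 0.0
    for k, t1 in enumerate(boundaries):
        if t1 > t0:
            mask = (grid >= t0) & (grid < t1) if k < len(boundaries) - 1 else (grid >= t0)
            t_eval = grid[mask]
            if len(t_eval) == 0 or t_eval[0] > t0:
                t_eval = np.concatenate([[t0], t_eval])
            rhs = lambda t, yy: assemble_rhs(t, yy, local)  # noqa: E731
            if solver.method == "adaptive":
                seg_t, seg_y, y = _segment_adaptive(rhs, y, t0, t1, t_eval, solver)
            else:
                seg_t, seg_y, y = _segment_euler(rhs, y, t0, t1, t_eval, solver)
            _check_recorded(seg_t, seg_y)
            seg_f = np.array(
                [_flux_row(seg_y[i], local) for i in range(seg_y.shape[0])]
            )
            all_t.append(seg_t)
            all_y.append(seg_y)
            all_f.append(seg_f)
        if k < len(protocol.events):
            ev = protocol.events[k]
            local.set_value(ev.parameter_path, ev.new_value)
        t0 = t1

    time = np.concatenate(all_t)
    states = np.vstack(all_y)
    flux_arr = np.vstack(all_f)
    return SimulationTrace(
        time=time,
        states=states,
        fluxes=flux_arr,
        rho_crac=np.clip(states[:, 7], 0.0, 1.0),
    )


def _flux_row(y: np.ndarray, params: ModelParameters, v_m: float | None = None) -> np.ndarray:
    f = compute_fluxes(y, params, v_m)
    return np.array([getattr(f, n) for n in fx.FLUX_NAMES])


def find_steady_state(
    params: ModelParameters,
    t_max: float = 300.0,
    tolerance: float = 1e-6,
    solver: SolverSettings | None = None,
    start: tuple[CalciumState, GatingState] | None = None,
    chunk: float = 5.0,
) -> tuple[CalciumState, GatingState, bool]:
    """Relax the system to steady state under constant parameters.

    Integrates in chunks until the maximum relative state change per second
    falls below ``tolerance`` (concentrations are compared on a 1e-6 µM floor
    so that empty compartments do not stall convergence), or ``t_max`` is
    reached.  Returns the relaxed state and a convergence flag (non-convergence
    is reported, not raised).
    """
    solver = solver or SolverSettings()
    calcium, gating = start if start is not None else initial_state(params)
    y = pack_state(calcium, gating)
    t = 0.0
    converged = False
    while t < t_max:
        dt = min(chunk, t_max - t)
        proto = Protocol(events=(), t_end=dt, record_interval=max(dt / 2, 1e-3))
        cal, gat = unpack_state(y)
        trace = integrate(cal, gat, params, proto, solver)
        y_new = trace.states[-1]
        scale = np.maximum(np.abs(y), 1e-6)
        rate = np.max(np.abs(y_new - y) / scale) / dt
        y = y_new
        t += dt
        if rate < tolerance:
            converged = True
            break
    cal, gat = unpack_state(y)
    return cal, gat, converged


def integrate_with_vm(
    calcium: CalciumState,
    gating: GatingState,
    v_m0: float,
    hook: WholeCellCurrentHook,
    params: ModelParameters,
    protocol: Protocol,
    solver: SolverSettings | None = None,
) -> SimulationTrace:
    """Co-integrate the membrane potential with the calcium system.

    V_m obeys C·dV_m/dt = −I_whole_cell(V_m, state, t) and replaces the fixed
    membrane potential in the CRAC driving force.  A zero-current hook leaves
    V_m constant and reproduces the SOCE-only run exactly.
    """
    solver = solver or SolverSettings()
    local = params.copy_with()

    def rhs(t: float, z: np.ndarray) -> np.ndarray:
        y, vm = z[:18], z[18]
        cal, gat = unpack_state(y)
        current = hook.current(vm, cal, gat, t)
        if not np.isfinite(current):
            raise FloatingPointError("whole-cell current hook returned a non-finite value")
        dy = assemble_rhs(t, y, local, v_m=vm)
        dvm = -current / hook.capacitance * 1e3  # V/s -> mV/s
        return np.append(dy, dvm)

    z = np.append(pack_state(calcium, gating), v_m0)
    grid = np.arange(0.0, protocol.t_end + protocol.record_interval * 0.5, protocol.record_interval)
    boundaries = [e.time for e in protocol.events] + [protocol.t_end]
    all_t, all_z = [], []
    t0 = 0.0
    for k, t1 in enumerate(boundaries):
        if t1 > t0:
            mask = (grid >= t0) & (grid < t1) if k < len(boundaries) - 1 else (grid >= t0)
            t_eval = grid[mask]
            if len(t_eval) == 0 or t_eval[0] > t0:
                t_eval = np.concatenate([[t0], t_eval])
            if solver.method == "adaptive":
                seg_t, seg_z, z = _segment_adaptive(rhs, z, t0, t1, t_eval, solver)
            else:
                seg_t, seg_z, z = _segment_euler(rhs, z, t0, t1, t_eval, solver)
            all_t.append(seg_t)
            all_z.append(seg_z)
        if k < len(protocol.events):
            ev = protocol.events[k]
            local.set_value(ev.parameter_path, ev.new_value)
        t0 = t1

    time = np.concatenate(all_t)
    zs = np.vstack(all_z)
    states, vms = zs[:, :18], zs[:, 18]
    _check_recorded(time, states)
    flux_arr = np.array([_flux_row(states[i], local, vms[i]) for i in range(states.shape[0])])
    return SimulationTrace(
        time=time,
        states=states,
        fluxes=flux_arr,
        rho_crac=np.clip(states[:, 7], 0.0, 1.0),
        v_m=vms,
    )
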