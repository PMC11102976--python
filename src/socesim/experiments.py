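"""Canned reproductions of the three simulation experiments.

* ``run_tg_soce_experiment`` — the thapsigargin/Ca-readdition/2-APB protocol:
  a Ca-free bath, SERCA block at 66 s, perfusion with 2 mM Ca²⁺ at 231 s and
  CRAC blockage at 429 s (n_CRAC per junction set to 0.001, not zero).
* ``run_steady_state_experiment`` — relaxation to the resting state at
  1.8 mM external Ca²⁺.
* ``run_ryr_activation_experiment`` — forced ER Ca²⁺ release: from the
  resting state the RyR flow rate is increased tenfold at 130 s.

Metric extraction conventions (the window of every metric is recorded in
``ExperimentSummary.windows``): *baseline* is the mean over the 10 s
preceding the first event (after a 10 s burn-in that hides the initial
re-equilibration transient of the buffer); *peak* is the maximum after a 1 s
post-event blanking window (bath steps produce sharp numerical spikes that
are not physiology); *plateau* is the mean over the final 30 s before the
next event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .engine import Protocol, ProtocolEvent, SimulationTrace, SolverSettings, integrate
from .parameters import ModelParameters, load_parameters
from .state import initial_state

__all__ = [
    "ExperimentSummary",
    "run_tg_soce_experiment",
    "run_steady_state_experiment",
    "run_ryr_activation_experiment",
    "run_parameter_sweep",
    "EXPERIMENTS",
]

BURN_IN = 10.0        # s, excluded before baseline extraction
BLANKING = 1.0        # s, excluded after each bath/drug step
PLATEAU_WINDOW = 30.0  # s, averaging window before the next event


@dataclass
class ExperimentSummary:
    """Named scalar metrics extracted from one simulation run."""

    name: str
    metrics: dict[str, float]
    windows: dict[str, tuple[float, float]]
    trace: SimulationTrace

    def __str__(self) -> str:  # pragma: no cover - convenience formatting
        lines = [f"experiment: {self.name}"]
        for k, v in self.metrics.items():
            w = self.windows.get(k)
            wtxt = f"  [{w[0]:.0f}-{w[1]:.0f} s]" if w else ""
            lines.append(f"  {k:>24s} = {v:.6g}{wtxt}")
        return "\n".join(lines)


def _mean(trace: SimulationTrace, col: str, t0: float, t1: float) -> float:
    m = trace.window(t0, t1)
    return float(trace.column(col)[m].mean())


def _max(trace: SimulationTrace, col: str, t0: float, t1: float) -> float:
    m = trace.window(t0, t1)
    return float(trace.column(col)[m].max())


def run_tg_soce_experiment(
    params: ModelParameters | None = None,
    solver: SolverSettings | None = None,
    t_end: float = 600.0,
    record_interval: float = 0.05,
) -> ExperimentSummary:
    """Thapsigargin-induced store depletion followed by store-operated entry.

    Starts in a Ca-free bath; 2 µM TG (SERCA rate -> 0) at 66 s, perfusion with
    2 mM Ca²⁺ at 231 s, 100 µM 2-APB (CRAC count -> 0.001) at 429 s.
    """
    params = (params or load_parameters()).copy_with({"ca_ext": 0.0})
    t_tg, t_ca, t_blk = 66.0, 231.0, 429.0
    protocol = Protocol(
        events=(
            ProtocolEvent(t_tg, "serca.R_serca", 0.0),
            ProtocolEvent(t_ca, "ca_ext", 2000.0),
            ProtocolEvent(t_blk, "crac.n_crac_per_junction", 0.001),
        ),
        t_end=t_end,
        record_interval=record_interval,
    )
    cal, gat = initial_state(params)
    trace = integrate(cal, gat, params, protocol, solver)

    windows = {
        "baseline_ca_cyt": (t_tg - 10.0, t_tg),
        "peak_ca_cyt": (t_tg + BLANKING, t_ca),
        "plateau_ca_cyt": (t_blk - PLATEAU_WINDOW, t_blk),
        "plateau_ca_jun": (t_blk - PLATEAU_WINDOW, t_blk),
        "max_rho_crac": (BURN_IN, t_blk),
        "plateau_i_crac": (t_blk - PLATEAU_WINDOW, t_blk),
        "max_csq_unbound": (BURN_IN, t_end),
        "final_ca_er": (t_end, t_end),
        "final_ca_cyt": (t_end, t_end),
    }
    f_cal, _ = trace.final_state()
    metrics = {
        "baseline_ca_cyt": _mean(trace, "ca_cyt", *windows["baseline_ca_cyt"]),
        "peak_ca_cyt": _max(trace, "ca_cyt", *windows["peak_ca_cyt"]),
        "plateau_ca_cyt": _mean(trace, "ca_cyt", *windows["plateau_ca_cyt"]),
        "plateau_ca_jun": _mean(trace, "ca_jun", *windows["plateau_ca_jun"]),
        "max_rho_crac": _max(trace, "rho_crac", *windows["max_rho_crac"]),
        "plateau_i_crac": _mean(trace, "i_crac", *windows["plateau_i_crac"]),
        "max_csq_unbound": _max(trace, "csq_unbound", *windows["max_csq_unbound"]),
        "final_ca_er": f_cal.ca_er,
        "final_ca_cyt": f_cal.ca_cyt,
    }
    trace.summary = dict(metrics)
    return ExperimentSummary("tg-soce", metrics, windows, trace)


def run_steady_state_experiment(
    params: ModelParameters | None = None,
    solver: SolverSettings | None = None,
    t_end: float = 130.0,
    record_interval: float = 0.05,
) -> ExperimentSummary:
    """Relaxation to the resting state under physiological (1.8 mM) external Ca²⁺."""
    params = params or load_parameters()
    protocol = Protocol(events=(), t_end=t_end, record_interval=record_interval)
    cal, gat = initial_state(params)
    trace = integrate(cal, gat, params, protocol, solver)
    f_cal, f_gat = trace.final_state()
    windows = {k: (t_end, t_end) for k in
               ("steady_ca_cyt", "steady_ca_er", "steady_ca_jun", "steady_rho_crac")}
    metrics = {
        "steady_ca_cyt": f_cal.ca_cyt,
        "steady_ca_er": f_cal.ca_er,
        "steady_ca_jun": f_cal.ca_jun,
        "steady_rho_crac": f_gat.crac_formed,
    }
    trace.summary = dict(metrics)
    return ExperimentSummary("steady-state", metrics, windows, trace)


def run_ryr_activation_experiment(
    params: ModelParameters | None = None,
    solver: SolverSettings | None = None,
    t_event: float = 130.0,
    t_end: float = 300.0,
    record_interval: float = 0.05,
) -> ExperimentSummary:
    """Forced ER Ca²⁺ release through RyR channels.

    The system relaxes at 1.8 mM external Ca²⁺ for ~130 s, then the RyR flow
    rate is multiplied by 10 and the run continues to a new plateau.
    """
    params = params or load_parameters()
    protocol = Protocol(
        events=(ProtocolEvent(t_event, "ryr.R_ryr", 10.0 * params.ryr.R_ryr),),
        t_end=t_end,
        record_interval=record_interval,
    )
    cal, gat = initial_state(params)
    trace = integrate(cal, gat, params, protocol, solver)
    f_cal, f_gat = trace.final_state()
    pre = (t_event - 10.0, t_event)
    post_peak = (t_event + BLANKING, t_end)
    windows = {
        "pre_ca_cyt": pre, "pre_ca_er": pre, "pre_ca_jun": pre, "pre_rho_crac": pre,
        "plateau_ca_cyt": (t_end, t_end),
        "plateau_ca_er": (t_end, t_end),
        "plateau_ca_jun": (t_end, t_end),
        "plateau_rho_crac": (t_end, t_end),
        "max_ca_cyt_post": post_peak,
        "overshoot_ca_cyt": post_peak,
    }
    max_post = _max(trace, "ca_cyt", *post_peak)
    metrics = {
        "pre_ca_cyt": _mean(trace, "ca_cyt", *pre),
        "pre_ca_er": _mean(trace, "ca_er", *pre),
        "pre_ca_jun": _mean(trace, "ca_jun", *pre),
        "pre_rho_crac": _mean(trace, "rho_crac", *pre),
        "plateau_ca_cyt": f_cal.ca_cyt,
        "plateau_ca_er": f_cal.ca_er,
        "plateau_ca_jun": f_cal.ca_jun,
        "plateau_rho_crac": f_gat.crac_formed,
        "max_ca_cyt_post": max_post,
        "overshoot_ca_cyt": max_post - f_cal.ca_cyt,
    }
    trace.summary = dict(metrics)
    return ExperimentSummary("ryr-activation", metrics, windows, trace)


EXPERIMENTS = {
    "tg-soce": run_tg_soce_experiment,
    "steady-state": run_steady_state_experiment,
    "ryr-activation": run_ryr_activation_experiment,
}


def run_parameter_sweep(
    params: ModelParameters,
    parameter_path: str,
    values: Sequence[float],
    protocol_name: str = "tg-soce",
    solver: SolverSettings | None = None,
    **kwargs: Any,
) -> list[ExperimentSummary]:
    """Re-run a named experiment for each value of one parameter."""
    if protocol_name not in EXPERIMENTS:
        raise KeyError(f"unknown experiment: {protocol_name!r}")
    runner = EXPERIMENTS[protocol_name]
    out = []
    for v in values:
        p = params.copy_with({parameter_path: v})
        summary = runner(p, solver=solver, **kwargs)
        summary.metrics[parameter_path] = float(v)
        out.append(summary)
    return out
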