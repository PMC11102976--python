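"""Trace, summary and manifest writers (delimited/structured text only)."""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .engine import Protocol, SimulationTrace, SolverSettings
from .experiments import ExperimentSummary
from .fluxes import FLUX_NAMES
from .parameters import ModelParameters
from .state import STATE_NAMES

__all__ = ["write_trace", "read_trace", "write_summary", "write_manifest"]

METRIC_UNITS = {
    "ca_cyt": "µM", "ca_er": "µM", "ca_jun": "µM", "csq": "µM",
    "rho_crac": "fraction", "i_crac": "A",
}


def _metric_unit(name: str) -> str:
    for key, unit in METRIC_UNITS.items():
        if key in name:
            return unit
    return "µM"


def write_trace(trace: SimulationTrace, destination: str | Path) -> Path:
    """Write a trace as tab-delimited text with a header row, full precision."""
    destination = Path(destination)
    df = trace.to_dataframe()
    df.to_csv(destination, sep="\t", index=False, float_format="%.17g")
    return destination


def read_trace(source: str | Path) -> SimulationTrace:
    """Read a trace written by :func:`write_trace` (lossless round trip)."""
    df = pd.read_csv(source, sep="\t", float_precision="round_trip")
    if len(df) == 0:
        return SimulationTrace(
            time=np.empty(0),
            states=np.empty((0, len(STATE_NAMES))),
            fluxes=np.empty((0, len(FLUX_NAMES))),
            rho_crac=np.empty(0),
        )
    return SimulationTrace(
        time=df["time"].to_numpy(),
        states=df[list(STATE_NAMES)].to_numpy(),
        fluxes=df[list(FLUX_NAMES)].to_numpy(),
        rho_crac=df["rho_crac"].to_numpy(),
        v_m=df["v_m"].to_numpy() if "v_m" in df.columns else None,
    )


def write_summary(summary: ExperimentSummary, destination: str | Path) -> Path:
    destination = Path(destination)
    doc = {
        "experiment": summary.name,
        "metrics": {
            name: {
                "value": value,
                "unit": _metric_unit(name),
                "window_s": list(summary.windows.get(name, ())),
            }
            for name, value in summary.metrics.items()
        },
    }
    destination.write_text(json.dumps(doc, indent=2))
    return destination


def write_manifest(
    destination: str | Path,
    params: ModelParameters,
    solver: SolverSettings,
    protocol: Protocol | None,
    experiment: str | None,
    outputs: dict[str, str],
    seed: int | None = None,
) -> Path:
    """Write a run manifest sufficient to reproduce the run exactly."""
    destination = Path(destination)
    doc = {
        "software": {"name": "socesim", "version": __version__},
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "experiment": experiment,
        "seed": seed,
        "config": params.model_dump(mode="json"),
        "solver": asdict(solver),
        "protocol": None
        if protocol is None
        else {
            "t_end": protocol.t_end,
            "record_interval": protocol.record_interval,
            "events": [asdict(e) for e in protocol.events],
        },
        "outputs": outputs,
    }
    destination.write_text(json.dumps(doc, indent=2))
    return destination
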