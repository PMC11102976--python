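"""State containers and the flat state-vector layout used by the integrator.

The dynamical state has 18 components: six concentrations (free Ca²⁺ in
cytosol/ER/junction, buffered cytosolic Ca²⁺, unbound calsequestrin, IP3),
two CRAC formation variables (free activated STIM1 and formed CRAC complexes,
both normalized to total protein = 1), six IP3R state occupancies and four
RyR state occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "CalciumState",
    "GatingState",
    "IP3R_STATES",
    "RYR_STATES",
    "STATE_NAMES",
    "initial_state",
    "pack_state",
    "unpack_state",
]

IP3R_STATES = ("R", "O", "A", "I1", "I2", "S")
RYR_STATES = ("X00", "X10", "X11", "X01")

STATE_NAMES = (
    "ca_cyt",
    "ca_er",
    "ca_jun",
    "ca_buffered_cyt",
    "csq_unbound",
    "ip3",
    "stim1_free",
    "crac_formed",
    *(f"ip3r_{s}" for s in IP3R_STATES),
    *(f"ryr_{s}" for s in RYR_STATES),
)


@dataclass
class CalciumState:
    """Free and buffered calcium concentrations plus IP3, all in µM."""

    ca_cyt: float
    ca_er: float
    ca_jun: float
    ca_buffered_cyt: float
    csq_unbound: float
    ip3: float

    def validate(self, params: ModelParameters) -> None:
        for name in ("ca_cyt", "ca_er", "ca_jun", "ca_buffered_cyt", "csq_unbound", "ip3"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative concentration: {name}")
        if self.csq_unbound > params.buffer_csq.csq_total * (1 + 1e-9):
            raise ValueError("csq_unbound exceeds csq_total")
        if self.ca_buffered_cyt > params.buffer_cyt.b_total * (1 + 1e-9):
            raise ValueError("ca_buffered_cyt exceeds b_total")


@dataclass
class GatingState:
    """STIM1/CRAC occupancy and the receptor state distributions.

    ``stim1_free`` is activated (Ca-free) STIM1; ``crac_formed`` is the
    fraction of assembled STIM1-ORAI1 complexes, which equals the CRAC open
    probability (formed channels are treated as immediately open).
    """

    stim1_free: float
    crac_formed: float
    ip3r_states: np.ndarray = field(default_factory=lambda: np.zeros(6))
    ryr_states: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def validate(self, params: ModelParameters, tol: float = 1e-6) -> None:
        if not 0 <= self.stim1_free <= params.crac.total_stim1 * (1 + tol):
            raise ValueError("stim1_free outside [0, total_stim1]")
        if not 0 <= self.crac_formed <= params.crac.total_orai1 * (1 + tol):
            raise ValueError("crac_formed outside [0, total_orai1]")
        for name, occ in (("ip3r", self.ip3r_states), ("ryr", self.ryr_states)):
            if abs(float(np.sum(occ)) - 1.0) > tol:
                raise ValueError(f"{name} occupancies do not sum to 1")


def initial_state(params: ModelParameters) -> tuple[CalciumState, GatingState]:
    """Initial condition for calcium simulations.

    Cytosol and junction start at the resting 64 nM, the ER at 250 µM with
    7 µM of the 14 µM calsequestrin pool still Ca-free, 16 µM calcium on the
    cytosolic buffer and IP3 at its 0.25 µM resting level.  No STIM1 is
    activated and no CRAC channels are formed; the IP3 receptor starts fully
    in its rest state and the RyR almost fully in X00.
    """
    del params  # the initial condition is parameter-independent
    calcium = CalciumState(
        ca_cyt=0.064,
        ca_er=250.0,
        ca_jun=0.064,
        ca_buffered_cyt=16.0,
        csq_unbound=7.0,
        ip3=0.25,
    )
    ip3r = np.zeros(6)
    ip3r[IP3R_STATES.index("R")] = 1.0
    ryr = np.zeros(4)
    ryr[RYR_STATES.index("X00")] = 0.998
    ryr[RYR_STATES.index("X01")] = 0.002
    gating = GatingState(stim1_free=0.0, crac_formed=0.0, ip3r_states=ip3r, ryr_states=ryr)
    return calcium, gating


def pack_state(calcium: CalciumState, gating: GatingState) -> np.ndarray:
    """Flatten the two state containers into the 18-component solver vector."""
    return np.concatenate(
        [
            [
                calcium.ca_cyt,
                calcium.ca_er,
                calcium.ca_jun,
                calcium.ca_buffered_cyt,
                calcium.csq_unbound,
                calcium.ip3,
                gating.stim1_free,
                gating.crac_formed,
            ],
            np.asarray(gating.ip3r_states, dtype=float),
            np.asarray(gating.ryr_states, dtype=float),
        ]
    )


def unpack_state(y: np.ndarray) -> tuple[CalciumState, GatingState]:
    calcium = CalciumState(
        ca_cyt=float(y[0]),
        ca_er=float(y[1]),
        ca_jun=float(y[2]),
        ca_buffered_cyt=float(y[3]),
        csq_unbound=float(y[4]),
        ip3=float(y[5]),
    )
    gating = GatingState(
        stim1_free=float(y[6]),
        crac_formed=float(y[7]),
        ip3r_states=np.array(y[8:14], dtype=float),
        ryr_states=np.array(y[14:18], dtype=float),
    )
    return calcium, gating
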