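"""Gating kinetics: STIM1/CRAC formation, IP3R and RyR state models, IP3 and buffers.

All functions are pure time-derivative laws on scalar concentrations (µM) and
dimensionless occupancies; they are composed into the full system by
:mod:`socesim.engine`.

CRAC formation is a two-step chain.  Ca²⁺ dissociation from luminal STIM1
activates it,

    d[STIM1]/dt = -f_s·[STIM1]·[Ca_ER]^n_s + b_s·(Total_STIM1 - [STIM1]),

and activated STIM1 binds ORAI1 to assemble CRAC complexes,

    d[CRAC]/dt = f_o·(Total_ORAI1 - [CRAC])·[STIM1] - b_o·[CRAC].

Formed complexes are treated as immediately open, so [CRAC] is the open
probability.  STIM1 acts catalytically in the second step (it is not consumed
by complex formation), which is what makes the fully-depleted-store open
probability f_o/(f_o + b_o) ≈ 0.95 with the default rates.

The IP3 receptor is the six-state (R, O, A, I1, I2, S) kinetic scheme with
saturating binding functions φᵢ(c); conducting weight (0.1·O + 0.9·A)⁴ for a
tetrameric channel.  The RyR is a four-state two-gate cycle documented in
:func:`ryr_transition_matrix`.
"""

from __future__ import annotations

import numpy as np

from .parameters import ModelParameters
from .state import GatingState

__all__ = [
    "stim1_rhs",
    "crac_formation_rhs",
    "crac_open_probability",
    "stim1_equilibrium",
    "crac_equilibrium",
    "crac_equilibrium_chain",
    "ip3r_transition_matrix",
    "ip3r_states_rhs",
    "ip3r_open_probability",
    "ryr_transition_matrix",
    "ryr_states_rhs",
    "ryr_open_fraction",
    "ip3_rhs",
    "cytosolic_buffer_rhs",
    "csq_buffer_rhs",
]

_NEG_TOL = -1e-9


def _check_nonneg(**values: float) -> None:
    bad = [k for k, v in values.items() if v < _NEG_TOL]
    if bad:
        raise ValueError(f"negative input(s): {', '.join(bad)}")


# --------------------------------------------------------------------------
# STIM1 / CRAC
# --------------------------------------------------------------------------

def stim1_rhs(stim1_free: float, ca_er: float, params: ModelParameters) -> float:
    """Rate of change of free (activated) STIM1, 1/s."""
    _check_nonneg(stim1_free=stim1_free, ca_er=ca_er)
    p = params.crac
    ca_er = max(ca_er, 0.0)
    return -p.f_s * stim1_free * ca_er**p.n_s + p.b_s * (p.total_stim1 - stim1_free)


def crac_formation_rhs(crac_formed: float, stim1_free: float, params: ModelParameters) -> float:
    """Rate of change of formed CRAC complexes, 1/s."""
    _check_nonneg(crac_formed=crac_formed, stim1_free=stim1_free)
    p = params.crac
    return p.f_o * (p.total_orai1 - crac_formed) * max(stim1_free, 0.0) - p.b_o * crac_formed


def crac_open_probability(gating: GatingState) -> float:
    """Open probability of the CRAC channel: the formed fraction itself."""
    return gating.crac_formed


def stim1_equilibrium(ca_er: float, params: ModelParameters) -> float:
    """Closed-form stationary free STIM1 at a fixed ER Ca²⁺ level."""
    p = params.crac
    return p.b_s * p.total_stim1 / (p.f_s * ca_er**p.n_s + p.b_s)


def crac_equilibrium(stim1_free: float, params: ModelParameters) -> float:
    """Closed-form stationary CRAC fraction at a fixed free-STIM1 level."""
    p = params.crac
    s = p.f_o * stim1_free
    return p.total_orai1 * s / (s + p.b_o)


def crac_equilibrium_chain(ca_er: float, params: ModelParameters) -> float:
    """Stationary CRAC open probability as a function of ER Ca²⁺ alone.

    Composition of the two closed forms; monotonically decreasing in ca_er.
    With default rates: ≈0.95 at a fully depleted ER, ≈0.032 at 594 µM and
    ≈0.69 at 139 µM.
    """
    return crac_equilibrium(stim1_equilibrium(ca_er, params), params)


# --------------------------------------------------------------------------
# IP3 receptor (six states: R, O, A, I1, I2, S)
# --------------------------------------------------------------------------

def _ip3r_phis(ca_cyt: float, p) -> tuple[float, float, float, float, float, float, float]:
    c = max(ca_cyt, 0.0)
    L1, L3, L5 = p.L1, p.L3, p.L5
    phi1 = (p.k1 * L1 + p.j2) * c / (L1 + c * (1 + L1 / L3))
    phi2 = (p.k2 * L3 + p.j4 * c) / (L3 + c * (1 + L3 / L1))
    phim2 = (p.km2 + p.jm4 * c) / (1 + c / L5)
    phi3 = p.k3 * L5 / (L5 + c)
    phi4 = (p.k4 * L5 + p.j6 * c) / (L5 + c)
    phim4 = L1 * (p.km4 + p.jm6) / (L1 + c)
    phi5 = (p.k1 * L1 + p.j2) * c / (L1 + c)
    return phi1, phi2, phim2, phi3, phi4, phim4, phi5


def ip3r_transition_matrix(ca_cyt: float, ip3: float, params: ModelParameters) -> np.ndarray:
    """Transition-rate matrix M of the six-state IP3R scheme (ds/dt = M·s).

    State order (R, O, A, I1, I2, S).  Edges of the scheme, with c = [Ca²⁺]
    and P = [IP3]:

        R  --φ2(c)·P-->  O      O  --φ-2(c)-->  R
        O  --φ4(c)----> A       A  --φ-4(c)-->  O
        O  --φ3(c)----> S       S  --k-3----->  O
        R  --φ1(c)----> I1      I1 --(k-1+j-2)-> R
        A  --φ5(c)----> I2      I2 --(k-1+j-2)-> A

    Every column of M sums to zero (probability conservation).
    """
    p = params.ip3r
    phi1, phi2, phim2, phi3, phi4, phim4, phi5 = _ip3r_phis(ca_cyt, p)
    k_inact = p.km1 + p.jm2
    ip3 = max(ip3, 0.0)
    M = np.zeros((6, 6))
    # indices: R=0, O=1, A=2, I1=3, I2=4, S=5
    _add_edge(M, 0, 1, phi2 * ip3, phim2)   # R <-> O
    _add_edge(M, 1, 2, phi4, phim4)         # O <-> A
    _add_edge(M, 1, 5, phi3, p.km3)         # O <-> S
    _add_edge(M, 0, 3, phi1, k_inact)       # R <-> I1
    _add_edge(M, 2, 4, phi5, k_inact)       # A <-> I2
    return M


def _add_edge(M: np.ndarray, i: int, j: int, fwd: float, bwd: float) -> None:
    M[i, i] -= fwd
    M[j, i] += fwd
    M[j, j] -= bwd
    M[i, j] += bwd


def ip3r_states_rhs(
    ip3r_states: np.ndarray, ca_cyt: float, ip3: float, params: ModelParameters
) -> np.ndarray:
    """Occupancy derivatives of the six IP3R states; components sum to zero."""
    s = np.asarray(ip3r_states, dtype=float)
    if np.any(s < _NEG_TOL) or np.any(s > 1 + 1e-6):
        raise ValueError("ip3r occupancy outside [0, 1]")
    return ip3r_transition_matrix(ca_cyt, ip3, params) @ s


def ip3r_open_probability(ip3r_states: np.ndarray) -> float:
    """Tetrameric open probability (0.1·O + 0.9·A)⁴."""
    return float((0.1 * ip3r_states[1] + 0.9 * ip3r_states[2]) ** 4)


# --------------------------------------------------------------------------
# Ryanodine receptor (four states: X00, X10, X11, X01)
# --------------------------------------------------------------------------

def ryr_transition_matrix(
    ca_cyt: float, csq_unbound: float, params: ModelParameters
) -> np.ndarray:
    """Transition-rate matrix of the four-state RyR cycle (ds/dt = M·s).

    Two gates: Ca²⁺ activation (first index) and Ca²⁺-dependent inactivation
    (second index); X10 and X11 conduct.  With c = [Ca²⁺]_Cyt and
    w = [CSQ]_free/[CSQ]_total the luminal regulation factor (w ≡ 1 when
    ``ryr.csq_coupling`` is off):

        X00 --k6·c·w--> X10     X10 --k-6 (=k-4)--> X00     (opening)
        X10 --k2·c²---> X11     X11 --k-2--------->  X10    (open-state inactivation)
        X01 --k7·c·w--> X11     X11 --k-4--------->  X01    (reopening, k7 = k4)
        X00 --k11·c²--> X01     X01 --k_rec------->  X00    (closed-state inactivation)

    The recovery rate k_rec = k-2·k4·k11/(k2·k6) closes the cycle under
    detailed balance, so the scheme is thermodynamically consistent for any
    (c, w).  Columns sum to zero.
    """
    p = params.ryr
    c = max(ca_cyt, 0.0)
    w = max(csq_unbound, 0.0) / params.buffer_csq.csq_total if p.csq_coupling else 1.0
    k_rec = p.km2 * p.k4 * p.k11 / (p.k2 * p.k6) if p.k2 * p.k6 > 0 else 0.0
    M = np.zeros((4, 4))
    # indices: X00=0, X10=1, X11=2, X01=3
    _add_edge(M, 0, 1, p.k6 * c * w, p.km4)   # X00 <-> X10
    _add_edge(M, 1, 2, p.k2 * c * c, p.km2)   # X10 <-> X11
    _add_edge(M, 3, 2, p.k4 * c * w, p.km4)   # X01 <-> X11
    _add_edge(M, 0, 3, p.k11 * c * c, k_rec)  # X00 <-> X01
    return M


def ryr_states_rhs(
    ryr_states: np.ndarray, ca_cyt: float, csq_unbound: float, params: ModelParameters
) -> np.ndarray:
    """Occupancy derivatives of the four RyR states; components sum to zero."""
    s = np.asarray(ryr_states, dtype=float)
    if np.any(s < _NEG_TOL) or np.any(s > 1 + 1e-6):
        raise ValueError("ryr occupancy outside [0, 1]")
    return ryr_transition_matrix(ca_cyt, csq_unbound, params) @ s


def ryr_open_fraction(ryr_states: np.ndarray) -> float:
    """Conducting fraction: activated states X10 + X11."""
    return float(ryr_states[1] + ryr_states[2])


# --------------------------------------------------------------------------
# IP3 and calcium buffers
# --------------------------------------------------------------------------

def ip3_rhs(ip3: float, ca_cyt: float, params: ModelParameters) -> float:
    """IP3 production (Ca-stimulated, Hill-2) minus relaxation to the resting level, µM/s."""
    _check_nonneg(ip3=ip3, ca_cyt=ca_cyt)
    p = params.ip3
    c2 = max(ca_cyt, 0.0) ** 2
    return p.R_ip_ca * c2 / (c2 + p.K_ca_m**2) - p.R_ip_d * (ip3 - p.ip3_rest)


def cytosolic_buffer_rhs(ca_buffered: float, ca_cyt: float, params: ModelParameters) -> float:
    """Mass-action binding of cytosolic Ca²⁺ to a single generic buffer site, µM/s."""
    p = params.buffer_cyt
    if ca_buffered > p.b_total * (1 + 1e-9):
        raise ValueError("ca_buffered exceeds b_total")
    return p.k_on * max(ca_cyt, 0.0) * (p.b_total - ca_buffered) - p.k_off * ca_buffered


def csq_buffer_rhs(csq_unbound: float, ca_er: float, params: ModelParameters) -> float:
    """Rate of change of Ca-free calsequestrin, µM/s.

    Unbound CSQ is consumed by Ca²⁺ binding and regenerated by unbinding of
    the Ca-loaded form; a fully depleted ER drives csq_unbound -> csq_total.
    """
    p = params.buffer_csq
    if csq_unbound > p.csq_total * (1 + 1e-9):
        raise ValueError("csq_unbound exceeds csq_total")
    binding = p.k_on * max(ca_er, 0.0) * csq_unbound - p.k_off * (p.csq_total - csq_unbound)
    return -binding
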