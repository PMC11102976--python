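"""Calcium flux laws between compartments.

Sign and unit conventions
-------------------------
Pump and release fluxes are expressed in µM/s of their *source-side*
compartment (cytosolic µM/s for SERCA_Cyt/PMCA/leak/IP3R/RyR, junctional µM/s
for CRAC and SERCA_Ju); the continuity equations in :mod:`socesim.engine`
apply the volume-ratio prefactors.  The junction-to-cytosol diffusion flux is
an *amount* flux (µM·L/s): dividing by the junction volume or scaling by
n_Ju/V_Cyt yields the concentration rates of the two sides.

The CRAC current follows the electrical convention (inward current negative);
its rectification forbids outward flow, so the converted calcium influx into
the junction is never negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

from .constants import FARADAY, GAS_CONSTANT, LITRE_PER_CUBIC_MICRON
from .parameters import ModelParameters

__all__ = [
    "FluxRecord",
    "FLUX_NAMES",
    "nernst_potential",
    "rectified_driving_force",
    "crac_flux",
    "serca_flux",
    "pmca_flux",
    "leak_flux",
    "ip3r_flux",
    "ryr_flux",
    "diffusion_flux",
]

CONC_FLOOR = 1e-12
"""Concentration floor (µM) applied inside logarithms only."""

FLUX_NAMES = (
    "j_ip3r",
    "j_ryr",
    "j_leak",
    "j_serca_cyt",
    "j_serca_jun",
    "j_pmca",
    "j_crac",
    "j_diff",
    "i_crac",
)


@dataclass
class FluxRecord:
    """All instantaneous fluxes; pump/release entries in µM/s, j_diff in µM·L/s, i_crac in A."""

    j_ip3r: float
    j_ryr: float
    j_leak: float
    j_serca_cyt: float
    j_serca_jun: float
    j_pmca: float
    j_crac: float
    j_diff: float
    i_crac: float


def nernst_potential(ca_ext: float, ca_jun: float, temperature: float, z_ca: float = 2.0) -> float:
    """Nernst potential for Ca²⁺ across the PM at the junction, in mV.

    Both concentrations are floored at 1e-12 µM before the logarithm; callers
    integrating the system never pass true zeros but protocol steps (e.g. a
    nominally Ca-free bath) may.
    """
    if ca_ext < 0 or ca_jun < 0:
        raise ValueError("nernst_potential requires non-negative concentrations")
    ratio = max(ca_ext, CONC_FLOOR) / max(ca_jun, CONC_FLOOR)
    return GAS_CONSTANT * temperature / (z_ca * FARADAY) * log(ratio) * 1e3


def rectified_driving_force(v_m: float, e_ca: float) -> float:
    """Inwardly rectified driving force (mV): v_m − e_ca where negative, else 0."""
    df = v_m - e_ca
    return df if df < 0 else 0.0


def crac_flux(
    v_m: float,
    ca_ext: float,
    ca_jun: float,
    rho_crac: float,
    params: ModelParameters,
) -> tuple[float, float]:
    """CRAC calcium influx into one junction.

    Returns ``(j_crac, i_crac)``: the junctional concentration flux in µM/s
    (non-negative by rectification) and the per-junction electrical current in
    A (negative = inward).  The current is
    i = n_CRAC·g_CRAC·ρ·(V − E_Ca) and the conversion constant
    1/(F·z·V_Ju) maps it onto the junction volume.
    """
    if not 0 <= rho_crac <= 1 + 1e-9:
        raise ValueError("rho_crac must be a fraction in [0, 1]")
    e_ca = nernst_potential(ca_ext, ca_jun, params.temperature, params.z_ca)
    df_volts = rectified_driving_force(v_m, e_ca) * 1e-3
    i_crac = params.crac.n_crac_per_junction * params.crac.g_crac * rho_crac * df_volts
    v_ju = params.geometry.junction_volume
    # mol/(L·s) -> µM/s; inward (negative) current is a positive Ca influx
    j_crac = -i_crac / (FARADAY * params.z_ca * v_ju) * 1e6
    return j_crac, i_crac


def serca_flux(ca_source: float, ca_er: float, params: ModelParameters) -> float:
    """SERCA uptake from the source compartment (cytosol or junction), µM/s.

    Hill activation by source-side Ca²⁺ with linear luminal inhibition
    1/(1 + I_SERCA·[Ca]_ER); the same law serves the cytosolic and the
    junctional pump populations.
    """
    if ca_source < 0 or ca_er < 0:
        raise ValueError("serca_flux requires non-negative concentrations")
    p = params.serca
    cn = ca_source**p.hill
    return p.R_serca * cn / (cn + p.K_serca**p.hill) / (1.0 + p.I_serca * ca_er)


def pmca_flux(ca_cyt: float, params: ModelParameters) -> float:
    """PMCA extrusion from the cytosol, µM/s (Hill kinetics, saturating at R_PMCA)."""
    if ca_cyt < 0:
        raise ValueError("pmca_flux requires non-negative ca_cyt")
    p = params.pmca
    cn = ca_cyt**p.hill
    return p.R_pmca * cn / (cn + p.K_pmca**p.hill)


def leak_flux(ca_er: float, ca_cyt: float, params: ModelParameters) -> float:
    """Passive ER leak R_leak·([Ca]_ER − [Ca]_Cyt), µM/s (cytosolic units)."""
    return params.leak.R_leak * (ca_er - ca_cyt)


def _release_flux(rate: float, p_open: float, ca_er: float, ca_cyt: float, ca_er_ref: float) -> float:
    if not 0 <= p_open <= 1 + 1e-9:
        raise ValueError("open probability must be a fraction in [0, 1]")
    return rate * p_open * (ca_er - ca_cyt) / ca_er_ref


def ip3r_flux(p_open: float, ca_er: float, ca_cyt: float, params: ModelParameters) -> float:
    """IP3R release flux, µM/s: R_IP3R·P_open·([Ca]_ER − [Ca]_Cyt)/[Ca]_ER,ref.

    The gradient is normalized by the reference (initial) ER concentration so
    that R_IP3R is the maximal flux in µM/s at a full gradient.
    """
    return _release_flux(params.ip3r.R_ip3r, p_open, ca_er, ca_cyt, params.ca_er_ref)


def ryr_flux(p_open: float, ca_er: float, ca_cyt: float, params: ModelParameters) -> float:
    """RyR release flux, µM/s; same normalized-gradient law with scale R_RyR."""
    return _release_flux(params.ryr.R_ryr, p_open, ca_er, ca_cyt, params.ca_er_ref)


def diffusion_flux(ca_jun: float, ca_cyt: float, params: ModelParameters) -> float:
    """Fickian junction-to-cytosol amount flux, µM·L/s.

    D_J·A_diff/d_diff·([Ca]_Jun − [Ca]_Cyt) across the cylinder's lateral
    surface; positive when the junction exceeds the cytosol.
    """
    g = params.geometry
    conductance = (
        params.diffusion_coefficient * g.diffusion_area / g.diffusion_distance
    ) * LITRE_PER_CUBIC_MICRON  # L/s
    return conductance * (ca_jun - ca_cyt)
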