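"""Model parameter registry: typed containers, validation, config loading.

Unit conventions used throughout the package: concentrations in µM, time in
seconds, volumes in litres, lengths as annotated per field (nm/µm), electrical
conductance in siemens, currents in amperes, potentials in mV (converted to
volts inside the Nernst/current formulas).

Two parameter sets ship with the package:

``table2_default``
    The single-cell SOCE parameterization (150 junctions, R_IP3R = 0.18 µM/s).
``combined_model``
    The variant used when the calcium subsystem is embedded in a whole-cell
    membrane model (300 junctions, R_IP3R = 1.8 µM/s).
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Union

import yaml
from pydantic import BaseModel, Field, model_validator

from .constants import LITRE_PER_CUBIC_MICRON

__all__ = [
    "Geometry",
    "CracParams",
    "SercaParams",
    "PmcaParams",
    "LeakParams",
    "Ip3rParams",
    "RyrParams",
    "Ip3Params",
    "CytosolicBufferParams",
    "CsqBufferParams",
    "ModelParameters",
    "load_parameters",
    "serialize_parameters",
    "SHIPPED_CONFIGS",
]

ConfigSource = Union[None, str, Path, Mapping[str, Any]]

SHIPPED_CONFIGS = ("table2_default", "combined_model")


class _StrictModel(BaseModel):
    model_config = {"extra": "forbid", "validate_assignment": True}


class Geometry(_StrictModel):
    """Cell and ER-PM junction geometry.

    The junction is a cylinder of diameter ``junction_diameter`` and height
    ``junction_height``; its volume and lateral (diffusion) surface are derived,
    never supplied.  The lateral ring surface acts as a diffusion layer of
    thickness ``diffusion_distance`` connecting the junction to the bulk cytosol.
    """

    cell_volume: float = Field(gt=0, description="whole-cell volume, µm³")
    cytosol_volume: float = Field(gt=0, description="free cytosol volume, L")
    er_volume: float = Field(gt=0, description="ER volume, L")
    junction_diameter: float = Field(gt=0, description="junction cylinder diameter, nm")
    junction_height: float = Field(gt=0, description="junction cylinder height, nm")
    n_junctions: float = Field(gt=0, description="number of ER-PM junctions")
    diffusion_distance: float = Field(gt=0, description="junction-to-cytosol diffusion length, µm")

    @property
    def junction_volume(self) -> float:
        """Cylinder volume π(d/2)²h, in litres."""
        d_um = self.junction_diameter * 1e-3
        h_um = self.junction_height * 1e-3
        return math.pi * (d_um / 2.0) ** 2 * h_um * LITRE_PER_CUBIC_MICRON

    @property
    def diffusion_area(self) -> float:
        """Cylinder lateral surface π·d·h, in µm²."""
        return math.pi * (self.junction_diameter * 1e-3) * (self.junction_height * 1e-3)


class CracParams(_StrictModel):
    """STIM1/ORAI1 binding kinetics and CRAC channel electrical parameters."""

    n_s: float = Field(gt=0, description="STIM1 Ca²⁺ binding cooperativity exponent")
    f_s: float = Field(ge=0, description="STIM1 Ca²⁺ binding rate, 1/(µMⁿ·s)")
    b_s: float = Field(ge=0, description="STIM1 Ca²⁺ dissociation rate, 1/s")
    f_o: float = Field(ge=0, description="STIM1-ORAI1 association rate, 1/(µM·s)")
    b_o: float = Field(ge=0, description="CRAC complex dissociation rate, 1/s")
    total_stim1: float = Field(ge=0, description="total STIM1 (normalized), µM")
    total_orai1: float = Field(ge=0, description="total ORAI1 (normalized), µM")
    g_crac: float = Field(ge=0, description="single CRAC channel conductance, S")
    n_crac_per_junction: float = Field(ge=0, description="CRAC channels per junction")


class SercaParams(_StrictModel):
    """SERCA pump: Hill activation by source-side Ca with linear luminal inhibition."""

    R_serca: float = Field(ge=0, description="maximal pump rate, µM/s")
    K_serca: float = Field(gt=0, description="half-activation constant, µM")
    I_serca: float = Field(ge=0, description="luminal inhibition coefficient, 1/µM")
    hill: float = Field(default=1.0, gt=0, description="Hill coefficient of cytosolic activation")


class PmcaParams(_StrictModel):
    """Plasma-membrane Ca²⁺ ATPase."""

    R_pmca: float = Field(ge=0, description="maximal extrusion rate, µM/s")
    K_pmca: float = Field(gt=0, description="half-activation constant, µM")
    hill: float = Field(default=2.0, gt=0, description="Hill coefficient")


class LeakParams(_StrictModel):
    R_leak: float = Field(ge=0, description="ER leak rate constant, 1/s")


class Ip3rParams(_StrictModel):
    """Six-state IP3 receptor kinetics (states R, O, A, I1, I2, S).

    Rate names follow the source kinetic model: k±1..k±4 and j±2, j±4, j±6 are
    binding/unbinding rates, L1/L3/L5 are the Ca²⁺ scales of the saturable
    transition functions.  ``R_ip3r`` is the maximal release flux.
    """

    R_ip3r: float = Field(ge=0, description="maximal release flux, µM/s")
    k1: float = Field(ge=0, description="1/(µM·s)")
    km1: float = Field(ge=0, description="1/s")
    k2: float = Field(ge=0, description="1/(µM·s)")
    km2: float = Field(ge=0, description="1/s")
    k3: float = Field(ge=0, description="1/(µM·s)")
    km3: float = Field(ge=0, description="1/s")
    k4: float = Field(ge=0, description="1/(µM·s)")
    km4: float = Field(ge=0, description="1/s")
    L1: float = Field(gt=0, description="µM")
    L3: float = Field(gt=0, description="µM")
    L5: float = Field(gt=0, description="µM")
    j2: float = Field(ge=0, description="1/s")
    jm2: float = Field(ge=0, description="1/s")
    j4: float = Field(ge=0, description="1/(µM·s)")
    jm4: float = Field(ge=0, description="1/(µM·s)")
    j6: float = Field(ge=0, description="1/s")
    jm6: float = Field(ge=0, description="1/s")


class RyrParams(_StrictModel):
    """Four-state ryanodine receptor kinetics (states X00, X10, X11, X01).

    ``csq_coupling`` switches the luminal regulation of the opening rates by
    the free-calsequestrin fraction; with it off, CSQ is a pure ER buffer and
    the gating ignores the luminal state.
    """

    R_ryr: float = Field(ge=0, description="maximal release flux, µM/s")
    k2: float = Field(ge=0, description="open-state inactivation, 1/(µM²·s)")
    km2: float = Field(ge=0, description="1/s")
    k4: float = Field(ge=0, description="reopening of inactivated receptor (k7 alias), 1/(µM·s)")
    km4: float = Field(ge=0, description="closing rate (k-6 alias), 1/s")
    k6: float = Field(ge=0, description="Ca²⁺ activation (opening), 1/(µM·s)")
    k11: float = Field(ge=0, description="closed-state inactivation, 1/(µM²·s)")
    Kd1: float = Field(gt=0, description="µM (registry value; not placed by the adopted scheme)")
    Kd3: float = Field(gt=0, description="µM (registry value; not placed by the adopted scheme)")
    Kd8: float = Field(gt=0, description="CSQ dissociation constant on the gating side, µM")
    csq_coupling: bool = Field(default=True, description="scale opening rates by free-CSQ fraction")


class Ip3Params(_StrictModel):
    """IP3 dynamics: Ca-stimulated production, first-order relaxation to rest."""

    R_ip_ca: float = Field(ge=0, description="maximal Ca-stimulated production, µM/s")
    K_ca_m: float = Field(gt=0, description="half-activation of production, µM")
    R_ip_d: float = Field(ge=0, description="relaxation rate toward rest, 1/s")
    ip3_rest: float = Field(ge=0, description="resting IP3 concentration, µM")


class CytosolicBufferParams(_StrictModel):
    """Generic single-site cytosolic Ca²⁺ buffer (mass action)."""

    k_on: float = Field(ge=0, description="1/(µM·s)")
    k_off: float = Field(ge=0, description="1/s")
    b_total: float = Field(ge=0, description="total buffer sites, µM")


class CsqBufferParams(_StrictModel):
    """Calsequestrin, the ER-luminal Ca²⁺ buffer (mass action)."""

    k_on: float = Field(ge=0, description="1/(µM·s)")
    k_off: float = Field(ge=0, description="1/s")
    csq_total: float = Field(ge=0, description="total calsequestrin, µM")
    k_d: float = Field(gt=0, description="printed dissociation constant, µM (kinetics use k_off/k_on)")


class ModelParameters(_StrictModel):
    """Full parameter set of the SOCE model."""

    geometry: Geometry
    ca_ext: float = Field(ge=0, description="external Ca²⁺ concentration, µM")
    temperature: float = Field(gt=0, description="K")
    z_ca: float = Field(gt=0, description="Ca²⁺ valence")
    membrane_potential: float = Field(description="fixed membrane potential for SOCE-only runs, mV")
    diffusion_coefficient: float = Field(ge=0, description="junctional Ca²⁺ diffusion coefficient, µm²/s")
    ca_er_ref: float = Field(gt=0, description="reference ER Ca²⁺ normalizing release fluxes, µM")
    crac: CracParams
    serca: SercaParams
    pmca: PmcaParams
    leak: LeakParams
    ip3r: Ip3rParams
    ryr: RyrParams
    ip3: Ip3Params
    buffer_cyt: CytosolicBufferParams
    buffer_csq: CsqBufferParams

    @model_validator(mode="after")
    def _exponent_consistency(self) -> "ModelParameters":
        if self.crac.n_s != int(self.crac.n_s) and self.crac.n_s <= 0:
            raise ValueError("crac.n_s must be positive")
        return self

    # -- dotted-path access so protocol events can target any parameter ------

    def get_value(self, path: str) -> Any:
        obj: Any = self
        for part in path.split("."):
            if not hasattr(obj, part):
                raise KeyError(f"unknown parameter path: {path!r}")
            obj = getattr(obj, part)
        return obj

    def set_value(self, path: str, value: Any) -> None:
        """Mutate a parameter in place by dotted path (re-validated on assignment)."""
        parts = path.split(".")
        obj: Any = self
        for part in parts[:-1]:
            if not hasattr(obj, part):
                raise KeyError(f"unknown parameter path: {path!r}")
            obj = getattr(obj, part)
        if not hasattr(obj, parts[-1]):
            raise KeyError(f"unknown parameter path: {path!r}")
        setattr(obj, parts[-1], value)

    def copy_with(self, overrides: Mapping[str, Any] | None = None) -> "ModelParameters":
        out = self.model_copy(deep=True)
        for path, value in (overrides or {}).items():
            out.set_value(path, value)
        return out


def _deep_merge(base: dict, override: Mapping[str, Any]) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def _shipped_config(name: str) -> dict:
    ref = resources.files("socesim").joinpath("params", f"{name}.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def load_parameters(config_source: ConfigSource = None) -> ModelParameters:
    """Build a validated parameter set from a config source.

    Parameters
    ----------
    config_source
        ``None`` or a shipped config name (``"table2_default"``,
        ``"combined_model"``) loads a shipped default set.  A path to a YAML
        file, a YAML document string, or a mapping supplies overrides that are
        merged over the ``table2_default`` set; only the keys present need to
        be given.

    Raises
    ------
    pydantic.ValidationError
        listing every offending key, on negative rates, non-numeric entries,
        or unknown keys.
    """
    base = _shipped_config("table2_default")
    if config_source is None or config_source == "table2_default":
        merged = base
    elif isinstance(config_source, str) and config_source in SHIPPED_CONFIGS:
        merged = _deep_merge(base, _shipped_config(config_source))
    elif isinstance(config_source, Mapping):
        merged = _deep_merge(base, config_source)
    else:
        path = Path(config_source)
        if path.exists():
            with open(path) as fh:
                doc = yaml.safe_load(fh)
        elif isinstance(config_source, str):
            doc = yaml.safe_load(config_source)
            if not isinstance(doc, Mapping):
                raise FileNotFoundError(f"config source not found: {config_source!r}")
        else:
            raise FileNotFoundError(f"config source not found: {config_source!r}")
        merged = _deep_merge(base, doc)
    return ModelParameters.model_validate(merged)


def serialize_parameters(params: ModelParameters, destination: str | Path | None = None) -> str:
    """Render a parameter set as a YAML document (round-trips through load)."""
    doc = yaml.safe_dump(params.model_dump(mode="json"), sort_keys=False, default_flow_style=False)
    if destination is not None:
        Path(destination).write_text(doc)
    return doc
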