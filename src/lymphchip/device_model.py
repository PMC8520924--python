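"""Device geometry, materials and solute registry.

The macrofluidic chip holds a central ECM channel filled with a type I
collagen (COL1) hydrogel, flanked by medium channels (a lymphangiogenic-
factor channel and cell-culture channels).  Lymphatic endothelial cells
grow as a monolayer on the gel wall of the stimulated channel.  This
module defines the parametric description of that device — channel
dimensions, porous layers with Darcy permeabilities, working fluids and
solutes — plus configuration (de)serialization with explicit units.

All stored values are SI.  Config files may use unit suffixes
(``"2 mm"``, ``"10 um"``); see :mod:`lymphchip.units`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import yaml

from .units import parse_quantity

__all__ = [
    "DeviceGeometry",
    "PorousLayer",
    "Fluid",
    "Solute",
    "DeviceConfig",
    "ConfigError",
    "ValidationError",
    "load_config",
    "save_config",
    "default_config",
    "stokes_einstein_diffusivity",
    "BOLTZMANN",
    "SCHEMA_VERSION",
]

BOLTZMANN = 1.380649e-23  # J/K
SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Malformed configuration (missing/unknown field, bad schema)."""


class ValidationError(ValueError):
    """A physical quantity violates an invariant (e.g. non-positive)."""


def _require_positive(obj: str, **fields: float) -> None:
    for name, value in fields.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValidationError(f"{obj}.{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class DeviceGeometry:
    """Channel and reservoir dimensions of the chip (SI, metres).

    Defaults are the as-fabricated dimensions: ECM channel 2 x 1 mm,
    medium channels 4 x 1.2 mm (width x height); medium and ECM
    reservoirs punched with 4-mm and 1-mm biopsy punches.  The channel
    length is a free design parameter (default 10 mm) and every result
    that depends on it reports it in its metadata.
    """

    ecm_channel_width: float = 2e-3
    ecm_channel_height: float = 1e-3
    medium_channel_width: float = 4e-3
    medium_channel_height: float = 1.2e-3
    channel_length: float = 10e-3
    medium_reservoir_diameter: float = 4e-3
    ecm_reservoir_diameter: float = 1e-3
    n_reservoirs_per_channel: int = 2

    def __post_init__(self) -> None:
        _require_positive(
            "DeviceGeometry",
            ecm_channel_width=self.ecm_channel_width,
            ecm_channel_height=self.ecm_channel_height,
            medium_channel_width=self.medium_channel_width,
            medium_channel_height=self.medium_channel_height,
            channel_length=self.channel_length,
            medium_reservoir_diameter=self.medium_reservoir_diameter,
            ecm_reservoir_diameter=self.ecm_reservoir_diameter,
        )
        if self.n_reservoirs_per_channel < 1:
            raise ValidationError("n_reservoirs_per_channel must be >= 1")

    @property
    def gel_interface_area(self) -> float:
        """Area (m^2) of the gel face normal to interstitial flow."""
        return self.channel_length * self.ecm_channel_height

    @property
    def medium_reservoir_area(self) -> float:
        """Total free-surface area (m^2) of one medium channel's reservoirs."""
        r = self.medium_reservoir_diameter / 2.0
        return self.n_reservoirs_per_channel * math.pi * r * r


@dataclass(frozen=True)
class PorousLayer:
    """A layer in the interstitial-flow / solute path.

    ``permeability`` is the Darcy permeability K (m^2).  ``diffusivity``
    maps solute name -> D (m^2/s); the key ``"default"`` is the fallback.
    A layer with ``solute_permeability`` set (m/s) is treated by the
    transport solver as a membrane interface conductance rather than a
    resolved slab — appropriate for the ~10-um endothelial monolayer.
    """

    name: str
    thickness: float
    permeability: float
    diffusivity: Mapping[str, float] = field(default_factory=dict)
    partition: Mapping[str, float] = field(default_factory=dict)
    solute_permeability: float | None = None

    def __post_init__(self) -> None:
        _require_positive(
            f"PorousLayer[{self.name}]",
            thickness=self.thickness,
            permeability=self.permeability,
        )
        for sol, d in self.diffusivity.items():
            if not d > 0:
                raise ValidationError(f"PorousLayer[{self.name}].diffusivity[{sol}] must be > 0")
        for sol, p in self.partition.items():
            if not p > 0:
                raise ValidationError(f"PorousLayer[{self.name}].partition[{sol}] must be > 0")
        if self.solute_permeability is not None and not self.solute_permeability > 0:
            raise ValidationError(f"PorousLayer[{self.name}].solute_permeability must be > 0")

    @property
    def is_membrane(self) -> bool:
        return self.solute_permeability is not None

    def diffusivity_for(self, solute: str) -> float:
        try:
            return self.diffusivity[solute]
        except KeyError:
            try:
                return self.diffusivity["default"]
            except KeyError:
                raise KeyError(
                    f"layer {self.name!r} has no diffusivity for solute {solute!r} and no default"
                ) from None

    def partition_for(self, solute: str) -> float:
        return self.partition.get(solute, self.partition.get("default", 1.0))


@dataclass(frozen=True)
class Fluid:
    """Working fluid (culture medium / COL1 precursor) properties."""

    density: float = 1000.0          # kg/m^3
    viscosity: float = 1.0e-3        # Pa s
    surface_tension: float = 0.072   # N/m, liquid-air
    g: float = 9.81                  # m/s^2

    def __post_init__(self) -> None:
        _require_positive(
            "Fluid",
            density=self.density,
            viscosity=self.viscosity,
            surface_tension=self.surface_tension,
            g=self.g,
        )


@dataclass(frozen=True)
class Solute:
    """A tracked molecule (dextran tracer, growth factor, chemokine)."""

    name: str
    molecular_weight: float            # kDa
    free_diffusivity: float            # m^2/s in medium
    gel_diffusivity: float             # m^2/s in COL1
    monolayer_permeability: float = 1e-8   # m/s across the endothelium
    initial_concentration: float = 1.0     # source-channel concentration (normalized)

    def __post_init__(self) -> None:
        _require_positive(
            f"Solute[{self.name}]",
            molecular_weight=self.molecular_weight,
            free_diffusivity=self.free_diffusivity,
            gel_diffusivity=self.gel_diffusivity,
            monolayer_permeability=self.monolayer_permeability,
        )


@dataclass(frozen=True)
class DeviceConfig:
    """A complete validated configuration bundle."""

    geometry: DeviceGeometry
    fluid: Fluid
    layers: tuple[PorousLayer, ...]
    solutes: tuple[Solute, ...]

    def layer(self, name: str) -> PorousLayer:
        for lay in self.layers:
            if lay.name == name:
                return lay
        raise KeyError(f"no layer named {name!r}")

    def solute(self, name: str) -> Solute:
        for sol in self.solutes:
            if sol.name == name:
                return sol
        raise KeyError(f"no solute named {name!r}")


# --------------------------------------------------------------------------
# defaults

#: Default gel diffusivity for a ~40 kDa dextran in 2 mg/ml COL1 (m^2/s).
DEFAULT_GEL_DIFFUSIVITY_40KDA = 6.5e-11

#: Darcy permeability of the COL1 hydrogel (m^2).
K_COL1 = 1.04e-13
#: Darcy permeability of the lymphatic endothelial monolayer (m^2).
K_ENDOTHELIUM = 2.46e-16
#: Default endothelial monolayer thickness (m); typical monolayer height.
MONOLAYER_THICKNESS = 10e-6


def default_config() -> DeviceConfig:
    """The stock device: COL1 gel + endothelial monolayer, dextran tracers."""
    geometry = DeviceGeometry()
    fluid = Fluid()
    gel = PorousLayer(
        name="COL1",
        thickness=geometry.ecm_channel_width,
        permeability=K_COL1,
        diffusivity={
            "default": DEFAULT_GEL_DIFFUSIVITY_40KDA,
            "dextran40": DEFAULT_GEL_DIFFUSIVITY_40KDA,
            "dextran10": 1.4e-10,
        },
    )
    endo = PorousLayer(
        name="endothelium",
        thickness=MONOLAYER_THICKNESS,
        permeability=K_ENDOTHELIUM,
        diffusivity={"default": 1e-11},
        solute_permeability=1e-8,
    )
    solutes = (
        Solute("dextran40", 40.0, free_diffusivity=9.0e-11,
               gel_diffusivity=DEFAULT_GEL_DIFFUSIVITY_40KDA),
        Solute("dextran10", 10.0, free_diffusivity=1.8e-10, gel_diffusivity=1.4e-10),
    )
    return DeviceConfig(geometry, fluid, (gel, endo), solutes)


# --------------------------------------------------------------------------
# config I/O

_GEOMETRY_DIMS = {
    "ecm_channel_width": "length",
    "ecm_channel_height": "length",
    "medium_channel_width": "length",
    "medium_channel_height": "length",
    "channel_length": "length",
    "medium_reservoir_diameter": "length",
    "ecm_reservoir_diameter": "length",
}
_FLUID_DIMS = {
    "density": "density",
    "viscosity": "viscosity",
    "surface_tension": "surface_tension",
    "g": "acceleration",
}
_LAYER_DIMS = {
    "thickness": "length",
    "permeability": "permeability_hydraulic",
    "solute_permeability": "velocity",
}
_SOLUTE_DIMS = {
    "molecular_weight": "mass",
    "free_diffusivity": "diffusivity",
    "gel_diffusivity": "diffusivity",
    "monolayer_permeability": "velocity",
    "initial_concentration": "dimensionless",
}


def _parse_section(raw: Mapping, dims: Mapping[str, str], where: str) -> dict:
    out = {}
    for key, value in raw.items():
        if key in dims:
            if value is None:
                continue
            out[key] = parse_quantity(value, dims[key])
        elif key in ("name", "n_reservoirs_per_channel"):
            out[key] = value
        elif key in ("diffusivity", "partition"):
            out[key] = {k: parse_quantity(v, "diffusivity" if key == "diffusivity" else "dimensionless")
                        for k, v in value.items()}
        else:
            raise ConfigError(f"unknown field {key!r} in {where}")
    return out


def load_config(path: str | Path) -> DeviceConfig:
    """Load and validate a device configuration (YAML or JSON).

    Unspecified fields fall back to the stock-device defaults.  Raises
    :class:`ConfigError` for schema problems and :class:`ValidationError`
    for non-physical values.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration root must be a mapping")

    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")

    base = default_config()

    geometry = base.geometry
    if "geometry" in raw and raw["geometry"]:
        geometry = replace(geometry, **_parse_section(raw["geometry"], _GEOMETRY_DIMS, "geometry"))

    fluid = base.fluid
    if "fluid" in raw and raw["fluid"]:
        fluid = replace(fluid, **_parse_section(raw["fluid"], _FLUID_DIMS, "fluid"))

    layers: tuple[PorousLayer, ...]
    if "layers" in raw and raw["layers"] is not None:
        parsed = []
        for i, lay in enumerate(raw["layers"]):
            if "name" not in lay:
                raise ConfigError(f"layers[{i}] missing mandatory field 'name'")
            kwargs = _parse_section(lay, _LAYER_DIMS, f"layers[{i}]")
            for mandatory in ("thickness", "permeability"):
                if mandatory not in kwargs:
                    raise ConfigError(f"layers[{i}] missing mandatory field {mandatory!r}")
            parsed.append(PorousLayer(**kwargs))
        layers = tuple(parsed)
    else:
        layers = base.layers
        # allow per-layer overrides keyed by name
        for key in ("layer_overrides",):
            if key in raw and raw[key]:
                updated = []
                for lay in layers:
                    if lay.name in raw[key]:
                        updated.append(replace(lay, **_parse_section(
                            raw[key][lay.name], _LAYER_DIMS, f"layer_overrides[{lay.name}]")))
                    else:
                        updated.append(lay)
                layers = tuple(updated)

    if "solutes" in raw and raw["solutes"] is not None:
        parsed_s = []
        for i, sol in enumerate(raw["solutes"]):
            if "name" not in sol:
                raise ConfigError(f"solutes[{i}] missing mandatory field 'name'")
            kwargs = _parse_section(sol, _SOLUTE_DIMS, f"solutes[{i}]")
            for mandatory in ("molecular_weight", "free_diffusivity", "gel_diffusivity"):
                if mandatory not in kwargs:
                    raise ConfigError(f"solutes[{i}] missing mandatory field {mandatory!r}")
            parsed_s.append(Solute(**kwargs))
        solutes = tuple(parsed_s)
    else:
        solutes = base.solutes

    return DeviceConfig(geometry, fluid, layers, solutes)


def save_config(config: DeviceConfig, path: str | Path) -> None:
    """Serialize a configuration to YAML (or JSON by extension), SI units.

    ``load_config(save_config(cfg))`` reproduces every field exactly:
    floats are written with full repr precision.
    """
    path = Path(path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "geometry": asdict(config.geometry),
        "fluid": asdict(config.fluid),
        "layers": [
            {k: v for k, v in asdict(lay).items() if v is not None}
            for lay in config.layers
        ],
        "solutes": [asdict(sol) for sol in config.solutes],
    }
    for lay in doc["layers"]:
        lay["diffusivity"] = dict(lay.get("diffusivity", {}))
        lay["partition"] = dict(lay.get("partition", {}))
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


# --------------------------------------------------------------------------
# physical helpers

#: Dextran hydrodynamic-radius correlation R_h[nm] = 0.0488 * MW[Da]^0.437.
_DEXTRAN_RH_PREFACTOR = 0.0488
_DEXTRAN_RH_EXPONENT = 0.437


def hydrodynamic_radius(mw_kda: float) -> float:
    """Hydrodynamic radius (m) of a dextran-like solute from its MW (kDa).

    Uses the empirical power law R_h[nm] = 0.0488 MW[Da]^0.437 for
    dextrans; a 40 kDa dextran gives ~5.0 nm, 10 kDa gives ~2.7 nm.
    """
    if not mw_kda > 0:
        raise ValidationError(f"molecular weight must be > 0, got {mw_kda!r}")
    return _DEXTRAN_RH_PREFACTOR * (mw_kda * 1e3) ** _DEXTRAN_RH_EXPONENT * 1e-9


def stokes_einstein_diffusivity(
    mw_kda: float | None = None,
    temperature: float = 310.0,
    viscosity: float = 0.7e-3,
    *,
    radius: float | None = None,
) -> float:
    """Stokes-Einstein diffusivity D = kT / (6 pi mu R_h) in m^2/s.

    Either ``mw_kda`` (radius from the dextran correlation) or an explicit
    ``radius`` in metres must be given.  Defaults are culture conditions:
    T = 310 K, medium viscosity 0.7 mPa s.
    """
    if radius is None:
        if mw_kda is None:
            raise ValidationError("either mw_kda or radius must be provided")
        radius = hydrodynamic_radius(mw_kda)
    if not radius > 0:
        raise ValidationError(f"radius must be > 0, got {radius!r}")
    if not temperature > 0 or not viscosity > 0:
        raise ValidationError("temperature and viscosity must be > 0")
    return BOLTZMANN * temperature / (6.0 * math.pi * viscosity * radius)
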