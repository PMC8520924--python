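"""Light-weight unit handling for configuration files.

All quantities are SI internally.  Configuration files may attach an
explicit unit suffix to a value (``"2 mm"``, ``"10 um"``,
``"1.04e-13 m^2"``); bare numbers are taken to be SI already.
"""

from __future__ import annotations

import re
from typing import Union

Quantity = Union[int, float, str]

# conversion factor to the SI unit of each dimension
_FACTORS: dict[str, dict[str, float]] = {
    "length": {
        "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "μm": 1e-6, "nm": 1e-9, "cm": 1e-2,
    },
    "area": {
        "m^2": 1.0, "m2": 1.0, "mm^2": 1e-6, "mm2": 1e-6, "um^2": 1e-12, "um2": 1e-12,
    },
    "diffusivity": {
        "m^2/s": 1.0, "m2/s": 1.0, "cm^2/s": 1e-4, "cm2/s": 1e-4, "um^2/s": 1e-12, "um2/s": 1e-12,
    },
    "velocity": {
        "m/s": 1.0, "mm/s": 1e-3, "um/s": 1e-6, "µm/s": 1e-6, "μm/s": 1e-6,
    },
    "viscosity": {
        "Pa*s": 1.0, "Pa.s": 1.0, "Pa·s": 1.0, "mPa*s": 1e-3, "mPa.s": 1e-3, "cP": 1e-3,
    },
    "density": {"kg/m^3": 1.0, "kg/m3": 1.0, "g/ml": 1e3, "g/cm^3": 1e3},
    "surface_tension": {"N/m": 1.0, "mN/m": 1e-3, "dyn/cm": 1e-3},
    "flow_rate": {
        "m^3/s": 1.0, "m3/s": 1.0, "ul/s": 1e-9, "µl/s": 1e-9, "μl/s": 1e-9,
        "ul/min": 1e-9 / 60.0, "ml/min": 1e-6 / 60.0, "ml/s": 1e-6,
    },
    "time": {"s": 1.0, "min": 60.0, "h": 3600.0, "d": 86400.0},
    "mass": {"kDa": 1.0, "Da": 1e-3},  # molecular weights stay in kDa
    "angle": {"deg": 1.0, "rad": 57.29577951308232},
    "acceleration": {"m/s^2": 1.0, "m/s2": 1.0},
    "permeability_hydraulic": {"m^2": 1.0, "m2": 1.0, "darcy": 9.869233e-13},
    "dimensionless": {"": 1.0},
}

_NUM_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(.*?)\s*$")


class UnitError(ValueError):
    """Raised when a quantity string cannot be interpreted."""


def parse_quantity(value: Quantity, dimension: str) -> float:
    """Convert ``value`` (number, or string with unit suffix) to SI.

    Parameters
    ----------
    value:
        A bare number (assumed SI) or a string such as ``"2 mm"``.
    dimension:
        Key into the supported dimension table (``"length"``, ``"area"``,
        ``"viscosity"``, ...).
    """
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise UnitError(f"cannot parse quantity of type {type(value).__name__}")
    m = _NUM_RE.match(value)
    if m is None:
        raise UnitError(f"malformed quantity {value!r}")
    number, unit = m.group(1), m.group(2)
    try:
        x = float(number)
    except ValueError as exc:
        raise UnitError(f"malformed number in quantity {value!r}") from exc
    if unit == "":
        return x
    try:
        factors = _FACTORS[dimension]
    except KeyError as exc:
        raise UnitError(f"unknown dimension {dimension!r}") from exc
    if unit not in factors:
        raise UnitError(
            f"unit {unit!r} not valid for dimension {dimension!r}; "
            f"expected one of {sorted(factors)}"
        )
    return x * factors[unit]
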