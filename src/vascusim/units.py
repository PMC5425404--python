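"""Unit-suffixed quantity parsing.

Internal unit system is micrometre / second / pascal / nanomolar. Config
files may give any physical parameter as a plain number (assumed already in
internal units) or as a string with a unit suffix, e.g. ``"30 min"``,
``"1.33 kPa"``, ``"3.0 nM"``, ``"20 um/h"``.
"""

from __future__ import annotations

import re

# unit -> (dimension, factor to internal units)
_UNITS: dict[str, tuple[str, float]] = {
    # time -> s
    "s": ("time", 1.0),
    "sec": ("time", 1.0),
    "min": ("time", 60.0),
    "h": ("time", 3600.0),
    "hr": ("time", 3600.0),
    "hour": ("time", 3600.0),
    "day": ("time", 86400.0),
    # length -> um
    "um": ("length", 1.0),
    "μm": ("length", 1.0),
    "mm": ("length", 1e3),
    "cm": ("length", 1e4),
    "m": ("length", 1e6),
    "nm": ("length", 1e-3),
    # pressure -> Pa
    "Pa": ("pressure", 1.0),
    "kPa": ("pressure", 1e3),
    "mmHg": ("pressure", 133.322),
    # concentration -> nM
    "nM": ("concentration", 1.0),
    "uM": ("concentration", 1e3),
    "μM": ("concentration", 1e3),
    "mM": ("concentration", 1e6),
    "M": ("concentration", 1e9),
    # rate -> 1/s
    "1/s": ("rate", 1.0),
    "/s": ("rate", 1.0),
    "1/min": ("rate", 1.0 / 60.0),
    "1/h": ("rate", 1.0 / 3600.0),
    # speed -> um/s
    "um/s": ("speed", 1.0),
    "um/min": ("speed", 1.0 / 60.0),
    "um/h": ("speed", 1.0 / 3600.0),
    "mm/s": ("speed", 1e3),
    # dynamic viscosity -> Pa s
    "Pa.s": ("viscosity", 1.0),
    "Pa*s": ("viscosity", 1.0),
    "Pa s": ("viscosity", 1.0),
    "mPa.s": ("viscosity", 1e-3),
    "mPa*s": ("viscosity", 1e-3),
    "cP": ("viscosity", 1e-3),
    # diffusivity -> um^2/s
    "um^2/s": ("diffusivity", 1.0),
    "um2/s": ("diffusivity", 1.0),
    "mm^2/s": ("diffusivity", 1e6),
    "cm^2/s": ("diffusivity", 1e8),
    # concentration rate -> nM/s
    "nM/s": ("concentration_rate", 1.0),
    "nM/min": ("concentration_rate", 1.0 / 60.0),
    "nM/h": ("concentration_rate", 1.0 / 3600.0),
    # flow -> um^3/s
    "um^3/s": ("flow", 1.0),
    "um3/s": ("flow", 1.0),
    # shear/adaptation sometimes dimensionless
}

_NUM = re.compile(r"^\s*([+-]?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?)\s*(.*)$")


class UnitError(ValueError):
    """Raised for an unknown unit or a unit of the wrong dimension."""


def parse_quantity(value: float | int | str, dimension: str | None = None) -> float:
    """Convert ``value`` to internal units.

    Plain numbers pass through unchanged.  Strings must look like
    ``"<number> <unit>"`` (the space is optional); the unit must be known
    and, if ``dimension`` is given, must carry that dimension.
    """
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise UnitError(f"cannot parse quantity from {value!r}")
    m = _NUM.match(value)
    if not m:
        raise UnitError(f"cannot parse quantity {value!r}")
    num = float(m.group(1))
    unit = m.group(2).strip()
    if not unit:
        return num
    if unit not in _UNITS:
        raise UnitError(f"unknown unit {unit!r} in {value!r}")
    dim, factor = _UNITS[unit]
    if dimension is not None and dim != dimension:
        raise UnitError(
            f"unit {unit!r} has dimension {dim!r}, expected {dimension!r}"
        )
    return num * factor
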