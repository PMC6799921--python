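"""Long-form units vocabulary shared by the schema, writer and validator.

HDF5 attribute values avoid Greek letters, superscripts and the multiply
sign, so every unit is written out in ASCII long form ("picofarad",
"micrometer x micrometer").  Each entry maps the long-form string to the
factor that converts a stored value into the package's internal
representation.  Electrical and geometric quantities are held internally
in SI base units (volt, farad, ohm, siemens, ampere, coulomb, meter,
second, hertz); temperature, pressure, age and osmolality are held in
their customary display unit (factor 1) because nothing downstream does
arithmetic across those dimensions.
"""

from __future__ import annotations

from .errors import UnknownUnitError

#: long-form unit -> factor converting a stored value to internal units
UNITS_TABLE: dict[str, float] = {
    "millivolt": 1e-3,
    "picofarad": 1e-12,
    "megaohm": 1e6,
    "picocoulomb": 1e-12,
    "per millivolt": 1e3,          # voltage sensitivity alpha
    "micrometer": 1e-6,
    "micrometer x micrometer": 1e-12,
    "millimolar": 1e-3,            # internal: molar
    "degree celsius": 1.0,
    "millimeter of mercury": 1.0,
    "second": 1.0,
    "hertz": 1.0,
    "nanosiemens": 1e-9,
    "nanoampere": 1e-9,
    "gram": 1.0,
    "day": 1.0,
    "milliosmole per kilogram": 1.0,
    "dimensionless": 1.0,
}


def to_internal(value, units: str):
    """Convert a value carrying a long-form unit to internal units."""
    return value * factor(units)


def from_internal(value, units: str):
    """Convert an internal-unit value to the given long-form display unit."""
    return value / factor(units)


def factor(units: str) -> float:
    if units not in UNITS_TABLE:
        raise UnknownUnitError(f"unit string not in long-form table: {units!r}")
    return UNITS_TABLE[units]


def is_known(units: str) -> bool:
    return units in UNITS_TABLE
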