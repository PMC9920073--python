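"""Unit conversion helpers.

Internally everything is strict SI (metres, newtons, pascals).  Interface
layers (file I/O, CLI, reports) speak the AFM-native units nm / nN / kPa and
convert at the boundary; these constants and tables are the single place
where the scale factors live.
"""

from __future__ import annotations

from .errors import FormatError

NM = 1e-9   # metre per nanometre
UM = 1e-6   # metre per micrometre
NN = 1e-9   # newton per nanonewton
PN = 1e-12  # newton per piconewton
KPA = 1e3   # pascal per kilopascal

#: multiplier that converts a value in the given length unit to metres
LENGTH_UNITS: dict[str, float] = {
    "m": 1.0,
    "mm": 1e-3,
    "um": UM,
    "µm": UM,
    "nm": NM,
}

#: multiplier that converts a value in the given force unit to newtons
FORCE_UNITS: dict[str, float] = {
    "N": 1.0,
    "mN": 1e-3,
    "uN": 1e-6,
    "µN": 1e-6,
    "nN": NN,
    "pN": PN,
}

#: multiplier that converts a value in the given pressure unit to pascals
PRESSURE_UNITS: dict[str, float] = {
    "Pa": 1.0,
    "kPa": KPA,
    "MPa": 1e6,
    "GPa": 1e9,
}


def length_to_si(unit: str) -> float:
    try:
        return LENGTH_UNITS[unit]
    except KeyError:
        raise FormatError(f"unknown length unit {unit!r}; known: {sorted(LENGTH_UNITS)}") from None


def force_to_si(unit: str) -> float:
    try:
        return FORCE_UNITS[unit]
    except KeyError:
        raise FormatError(f"unknown force unit {unit!r}; known: {sorted(FORCE_UNITS)}") from None
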