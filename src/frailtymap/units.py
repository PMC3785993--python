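"""Unit conversion for quantitative frailty variables.

Before a similarity comparison every quantitative value must be in its
variable's canonical unit (all weights in kilograms, all heights in
centimetres, ...).  Conversions are multiplicative; the small registry
below covers the units that occur in geriatric records for the
canonical schema.
"""

from __future__ import annotations

from .errors import UnitConversionError

#: (from_unit, to_unit) -> multiplicative factor
_FACTORS: dict[tuple[str, str], float] = {
    # mass
    ("g", "kg"): 1e-3,
    ("mg", "kg"): 1e-6,
    ("lb", "kg"): 0.45359237,
    # length
    ("m", "cm"): 100.0,
    ("mm", "cm"): 0.1,
    ("in", "cm"): 2.54,
    # concentration
    ("g/l", "g/dl"): 0.1,
    ("mg/dl", "g/dl"): 1e-3,
    ("g/dl", "mg/dl"): 1e3,
    ("mg/l", "mg/dl"): 0.1,
    ("ug/l", "ng/ml"): 1.0,
    ("ng/dl", "ug/dl"): 1e-3,
    ("pmol/l", "pg/ml"): 1.355,  # vitamin B12 molar mass conversion
    # counts
    ("/mcl", "thousand/mcl"): 1e-3,
    ("million/l", "thousand/mcl"): 1e-3,
    # acceleration
    ("g0", "m/s2"): 9.80665,
}


def convert(value: float, from_unit: str, to_unit: str, variable: str = "?") -> float:
    """Convert ``value`` from ``from_unit`` into ``to_unit``.

    Raises :class:`UnitConversionError` naming the variable and unit
    when no conversion is registered.
    """
    if from_unit == to_unit:
        return value
    try:
        return value * _FACTORS[(from_unit, to_unit)]
    except KeyError:
        raise UnitConversionError(
            f"cannot convert variable {variable!r} from unit {from_unit!r} "
            f"to canonical unit {to_unit!r}") from None
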