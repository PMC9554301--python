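"""Unit tags and conversion to internal SI units.

Internally every concentration is molar (M), every time is seconds, every
unimolecular rate constant is 1/s and every bimolecular gain is 1/(M*s).
Published kinetic constants mix mM, uM and nM, so boundary code (netlists,
motif helpers) accepts explicitly unit-tagged quantities like ``"0.167 mM"``
or ``"2903 per_s"`` and converts here.  Bare numbers are rejected for any
dimensioned quantity: a concentration without a unit tag is ambiguous.
"""

from __future__ import annotations

#: multiplicative factors to molar
CONCENTRATION_UNITS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}

#: rate-constant tags -> factor to 1/s or 1/(M*s)
RATE_UNITS = {
    "per_s": 1.0,
    "per_M_s": 1.0,
    "per_mM_s": 1e3,
    "per_uM_s": 1e6,
    "per_nM_s": 1e9,
}

#: dimensionless / auxiliary tags passed through unchanged
PLAIN_UNITS = {
    "s": 1.0,
    "nt": 1.0,
    "nt_per_s": 1.0,
    "dimensionless": 1.0,
}


class UnitError(ValueError):
    """Missing, unknown, or dimensionally wrong unit tag."""


def _split(text: str) -> tuple[float, str]:
    parts = str(text).split()
    if len(parts) != 2:
        raise UnitError(
            f"quantity {text!r} must be '<number> <unit>' (e.g. '0.167 mM', '2903 per_s')"
        )
    try:
        value = float(parts[0])
    except ValueError as exc:
        raise UnitError(f"cannot parse number in quantity {text!r}") from exc
    return value, parts[1]


def molar(text: str | float) -> float:
    """Parse a unit-tagged concentration, returning molar.

    Floats are rejected: concentrations must carry an explicit unit tag.
    """
    if isinstance(text, (int, float)):
        raise UnitError(
            f"concentration {text!r} has no unit tag; write e.g. '{text} mM'"
        )
    value, unit = _split(text)
    try:
        return value * CONCENTRATION_UNITS[unit]
    except KeyError as exc:
        raise UnitError(
            f"unknown concentration unit {unit!r}; expected one of {sorted(CONCENTRATION_UNITS)}"
        ) from exc


def rate(text: str | float) -> float:
    """Parse a unit-tagged rate constant, returning 1/s or 1/(M*s)."""
    if isinstance(text, (int, float)):
        raise UnitError(f"rate constant {text!r} has no unit tag; write e.g. '{text} per_s'")
    value, unit = _split(text)
    try:
        return value * RATE_UNITS[unit]
    except KeyError as exc:
        raise UnitError(
            f"unknown rate unit {unit!r}; expected one of {sorted(RATE_UNITS)}"
        ) from exc


def quantity(text: str | float) -> float:
    """Parse any tagged quantity (concentration, rate, time, length)."""
    if isinstance(text, (int, float)):
        raise UnitError(f"quantity {text!r} has no unit tag")
    value, unit = _split(text)
    for table in (CONCENTRATION_UNITS, RATE_UNITS, PLAIN_UNITS):
        if unit in table:
            return value * table[unit]
    raise UnitError(f"unknown unit {unit!r} in quantity {text!r}")
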