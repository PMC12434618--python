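"""Unit conventions and magnetic-field unit conversion.

Everything in the package is SI internally (m, kg, s, A, V).  Magnetic
fields are carried as flux densities in tesla, identified with the field
strength through B = mu0*H in vacuum; the oersted and the centimetre appear
only in the magnetoelectric-coefficient formula, which is the field's
customary mixed-unit convention (mV Oe^-1 cm^-1).
"""

from __future__ import annotations

import math

MU0 = 4.0e-7 * math.pi          # vacuum permeability, T m A^-1
EPS0 = 8.8541878128e-12         # vacuum permittivity, F m^-1

#: conversion factors to tesla for the supported field units
_TO_TESLA = {
    "T": 1.0,
    "mT": 1.0e-3,
    "Oe": 1.0e-4,               # 1 Oe corresponds to 0.1 mT (B = mu0*H)
    "A/m": MU0,
}


def convert_field_units(value: float, unit_from: str, unit_to: str) -> float:
    """Convert a magnetic-field magnitude between T, mT, Oe and A/m.

    The conversion identifies B and H in vacuum (1 mT = 10 Oe,
    1 T = 10^4 Oe, H[A/m] = B[T]/mu0).

    Raises
    ------
    ValueError
        If either unit label is not supported.
    """
    for u in (unit_from, unit_to):
        if u not in _TO_TESLA:
            raise ValueError(
                f"unknown field unit {u!r}; supported: {sorted(_TO_TESLA)}"
            )
    return value * _TO_TESLA[unit_from] / _TO_TESLA[unit_to]


def parse_field(text: float | int | str) -> float:
    """Parse a magnetic field given as a number (tesla) or a string with an
    explicit unit suffix, e.g. ``"300 mT"``, ``"4 T"``, ``"3000 Oe"``.

    Returns the value in tesla.
    """
    if isinstance(text, (int, float)):
        return float(text)
    parts = str(text).split()
    if len(parts) == 1:
        # allow e.g. "300mT"
        for u in sorted(_TO_TESLA, key=len, reverse=True):
            if parts[0].endswith(u):
                return convert_field_units(float(parts[0][: -len(u)]), u, "T")
        return float(parts[0])
    if len(parts) != 2:
        raise ValueError(f"cannot parse field specification {text!r}")
    return convert_field_units(float(parts[0]), parts[1], "T")
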