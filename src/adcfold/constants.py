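"""Physical constants and unit conversions (CODATA 2018).

All internal quantities are in Hartree atomic units; conversions are applied
only at the I/O boundary.
"""

from __future__ import annotations

#: Hartree energy in electronvolt.
HARTREE_TO_EV = 27.211386245988
#: Hartree energy in wavenumbers (cm^-1).
HARTREE_TO_CM1 = 219474.6313632
#: Bohr radius in Angstrom.
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM
#: Fine-structure constant (dimensionless); 1/c in atomic units.
FINE_STRUCTURE = 7.2973525693e-3
SPEED_OF_LIGHT_AU = 1.0 / FINE_STRUCTURE

_ENERGY_IN_HARTREE = {
    "hartree": 1.0,
    "au": 1.0,
    "ev": 1.0 / HARTREE_TO_EV,
    "cm-1": 1.0 / HARTREE_TO_CM1,
}


class UnitError(ValueError):
    """Raised for an unsupported unit conversion pair."""


def convert_units(value: float, unit_from: str, unit_to: str) -> float:
    """Convert an energy-like quantity between hartree, eV, cm-1 and au.

    Frequencies in atomic units are numerically identical to energies in
    hartree (hbar = 1), so 'au' covers both.
    """
    try:
        f = _ENERGY_IN_HARTREE[unit_from.lower()]
        t = _ENERGY_IN_HARTREE[unit_to.lower()]
    except KeyError as exc:
        supported = ", ".join(sorted(_ENERGY_IN_HARTREE))
        raise UnitError(
            f"unsupported unit {exc.args[0]!r}; supported: {supported}"
        ) from None
    return value * f / t
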