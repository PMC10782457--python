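"""Molecular geometry handling: elements, XYZ parsing, nuclear frame data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_TO_BOHR

#: Element symbol -> atomic number, for the elements the package supports.
ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}

#: Standard atomic weights (u), used for the center-of-mass gauge origin.
ATOMIC_MASSES = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948,
}


class XYZParseError(ValueError):
    """Raised when an XYZ-format geometry cannot be parsed."""


@dataclass
class Molecule:
    """A molecule: element symbols and Cartesian coordinates in Angstrom.

    Only closed-shell (multiplicity 1) molecules are supported by the
    correlated modules; the invariant is checked where it matters.
    """

    atoms: list  # list of (symbol, (x, y, z)) with coordinates in Angstrom
    charge: int = 0
    multiplicity: int = 1
    comment: str = field(default="", compare=False)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("a molecule needs at least one atom")
        for sym, xyz in self.atoms:
            if sym not in ATOMIC_NUMBERS:
                raise ValueError(f"unknown element symbol {sym!r}")
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"non-finite coordinate for atom {sym}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def symbols(self) -> list:
        return [sym for sym, _ in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        """Nuclear charges Z."""
        return np.array([ATOMIC_NUMBERS[s] for s in self.symbols], dtype=float)

    @property
    def coords_angstrom(self) -> np.ndarray:
        return np.array([xyz for _, xyz in self.atoms], dtype=float)

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coords_angstrom * ANGSTROM_TO_BOHR

    @property
    def n_electrons(self) -> int:
        return int(self.charges.sum()) - self.charge

    def nuclear_repulsion(self) -> float:
        """Nuclear repulsion energy in hartree."""
        z = self.charges
        r = self.coords_bohr
        e = 0.0
        for i in range(self.n_atoms):
            for j in range(i):
                e += z[i] * z[j] / np.linalg.norm(r[i] - r[j])
        return e

    def center_of_mass(self) -> np.ndarray:
        """Nuclear center of mass in bohr."""
        m = np.array([ATOMIC_MASSES[s] for s in self.symbols])
        return m @ self.coords_bohr / m.sum()

    def rotated(self, rotation: np.ndarray) -> "Molecule":
        """Rigidly rotated copy (3x3 orthogonal matrix acting on coordinates)."""
        xyz = self.coords_angstrom @ np.asarray(rotation).T
        atoms = [(s, tuple(x)) for s, x in zip(self.symbols, xyz)]
        return Molecule(atoms, self.charge, self.multiplicity, self.comment)

    def mirrored(self, axis: int = 0) -> "Molecule":
        """Mirror image (negate one Cartesian axis) — the enantiomer."""
        xyz = self.coords_angstrom.copy()
        xyz[:, axis] *= -1.0
        atoms = [(s, tuple(x)) for s, x in zip(self.symbols, xyz)]
        return Molecule(atoms, self.charge, self.multiplicity, self.comment)

    def to_xyz(self) -> str:
        lines = [str(self.n_atoms), self.comment]
        for sym, xyz in self.atoms:
            lines.append(f"{sym} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}")
        return "\n".join(lines) + "\n"


def parse_xyz(text: str, charge: int = 0, multiplicity: int = 1) -> Molecule:
    """Parse an XYZ-format string (two header lines, coordinates in Angstrom)."""
    lines = text.splitlines()
    if not lines:
        raise XYZParseError("empty XYZ input")
    try:
        n_atoms = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(
            f"line 1: expected an atom count, got {lines[0]!r}"
        ) from None
    comment = lines[1] if len(lines) > 1 else ""
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < n_atoms:
        raise XYZParseError(
            f"header declares {n_atoms} atoms but only {len(body)} coordinate "
            "lines follow"
        )
    atoms = []
    for k in range(n_atoms):
        parts = body[k].split()
        lineno = k + 3
        if len(parts) < 4:
            raise XYZParseError(f"line {lineno}: expected 'El x y z'")
        sym = parts[0].capitalize()
        if sym not in ATOMIC_NUMBERS:
            raise XYZParseError(f"line {lineno}: unknown element symbol {parts[0]!r}")
        try:
            xyz = tuple(float(v) for v in parts[1:4])
        except ValueError:
            raise XYZParseError(
                f"line {lineno}: non-numeric coordinate in {parts[1:4]}"
            ) from None
        atoms.append((sym, xyz))
    return Molecule(atoms, charge=charge, multiplicity=multiplicity, comment=comment)
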