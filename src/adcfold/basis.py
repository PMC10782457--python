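"""Registry of standard Gaussian basis sets and contracted-function counting.

Two kinds of entries exist:

* full entries (STO-3G, 6-31G for selected elements) carry primitive
  exponents and contraction coefficients and can drive integral evaluation;
* composition-only entries (cc-pVDZ, aug-cc-pVDZ, 6-311G**) carry the shell
  structure per element and support counting of contracted functions, which
  is all that is needed to size a calculation before running it.

The numerical parameters are the standard published values of these basis
sets (Hehre/Stewart/Pople STO-3G; Hehre/Ditchfield/Pople 6-31G).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mol import Molecule


class BasisError(KeyError):
    """Raised when a basis set or element entry is unavailable."""


@dataclass(frozen=True)
class Shell:
    """One contracted shell: angular momentum l, primitive exponents and
    contraction coefficients (raw, pre-normalization)."""

    l: int
    exponents: tuple
    coefficients: tuple

    def n_cartesian(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2

    def n_spherical(self) -> int:
        return 2 * self.l + 1


# STO-3G shares one set of contraction coefficients per shell type across
# elements; only the exponents are element-specific.
_STO3G_C1S = (0.1543289673, 0.5353281423, 0.4446345422)
_STO3G_C2S = (-0.09996722919, 0.3995128261, 0.7001154689)
_STO3G_C2P = (0.1559162750, 0.6076837186, 0.3919573931)

_STO3G = {
    "H": [Shell(0, (3.425250914, 0.6239137298, 0.1688554040), _STO3G_C1S)],
    "He": [Shell(0, (6.362421394, 1.158922999, 0.3136497915), _STO3G_C1S)],
    "Li": [
        Shell(0, (16.11957475, 2.936200663, 0.7946504870), _STO3G_C1S),
        Shell(0, (0.6362897469, 0.1478600533, 0.0480886784), _STO3G_C2S),
        Shell(1, (0.6362897469, 0.1478600533, 0.0480886784), _STO3G_C2P),
    ],
    "C": [
        Shell(0, (71.61683735, 13.04509632, 3.530512160), _STO3G_C1S),
        Shell(0, (2.941249355, 0.6834830964, 0.2222899159), _STO3G_C2S),
        Shell(1, (2.941249355, 0.6834830964, 0.2222899159), _STO3G_C2P),
    ],
    "N": [
        Shell(0, (99.10616896, 18.05231239, 4.885660238), _STO3G_C1S),
        Shell(0, (3.780455879, 0.8784966449, 0.2857143744), _STO3G_C2S),
        Shell(1, (3.780455879, 0.8784966449, 0.2857143744), _STO3G_C2P),
    ],
    "O": [
        Shell(0, (130.7093214, 23.80886605, 6.443608313), _STO3G_C1S),
        Shell(0, (5.033151319, 1.169596125, 0.3803889600), _STO3G_C2S),
        Shell(1, (5.033151319, 1.169596125, 0.3803889600), _STO3G_C2P),
    ],
}

_631G = {
    "H": [
        Shell(0, (18.73113696, 2.825394365, 0.6401216923),
              (0.03349460434, 0.2347269535, 0.8137573261)),
        Shell(0, (0.1612777588,), (1.0,)),
    ],
    "O": [
        Shell(0, (5484.671660, 825.2349460, 188.0469580, 52.96450000,
                  16.89757040, 5.799635340),
              (0.001831074430, 0.01395017220, 0.06844507810, 0.2327143360,
               0.4701928980, 0.3585208530)),
        Shell(0, (15.53961625, 3.599933586, 1.013761750),
              (-0.1107775495, -0.1480262627, 1.130767015)),
        Shell(1, (15.53961625, 3.599933586, 1.013761750),
              (0.07087426823, 0.3397528391, 0.7271585773)),
        Shell(0, (0.2700058226,), (1.0,)),
        Shell(1, (0.2700058226,), (1.0,)),
    ],
}

_FULL_BASES = {"sto-3g": _STO3G, "6-31g": _631G}

# Composition-only entries: element -> tuple of shell angular momenta.
_FIRST_ROW = ("B", "C", "N", "O", "F", "Ne")

_COMPOSITIONS = {
    # cc-pVDZ: H [2s1p]; first row [3s2p1d]
    "cc-pvdz": {
        "H": (0, 0, 1),
        **{el: (0, 0, 0, 1, 1, 2) for el in _FIRST_ROW},
    },
    # aug-cc-pVDZ: H [3s2p]; first row [4s3p2d]
    "aug-cc-pvdz": {
        "H": (0, 0, 0, 1, 1),
        **{el: (0, 0, 0, 0, 1, 1, 1, 2, 2) for el in _FIRST_ROW},
    },
    # 6-311G**: H [3s1p]; first row [4s3p1d]
    "6-311g**": {
        "H": (0, 0, 0, 1),
        **{el: (0, 0, 0, 0, 1, 1, 1, 2) for el in _FIRST_ROW},
    },
}
# Full entries also support counting.
for _name, _data in _FULL_BASES.items():
    _COMPOSITIONS[_name] = {
        el: tuple(sh.l for sh in shells) for el, shells in _data.items()
    }


def _normalize_name(name: str) -> str:
    return name.strip().lower()


def shell_composition(element: str, basis_name: str) -> tuple:
    """Angular momenta of the contracted shells of ``element`` in the basis."""
    key = _normalize_name(basis_name)
    if key not in _COMPOSITIONS:
        raise BasisError(
            f"basis {basis_name!r} not in registry; known: "
            + ", ".join(sorted(_COMPOSITIONS))
        )
    table = _COMPOSITIONS[key]
    if element not in table:
        raise BasisError(
            f"element {element!r} has no {basis_name!r} entry in the registry"
        )
    return table[element]


def count_contracted_basis(
    molecule: Molecule, basis_name: str, spherical: bool = True
) -> int:
    """Number of contracted basis functions for the molecule.

    Spherical shells contribute 2l+1 functions, Cartesian (l+1)(l+2)/2.
    """
    total = 0
    for sym in molecule.symbols:
        for l in shell_composition(sym, basis_name):
            total += (2 * l + 1) if spherical else (l + 1) * (l + 2) // 2
    return total


def shells_for_molecule(molecule: Molecule, basis_name: str):
    """List of (atom_index, center_bohr, Shell) for integral evaluation.

    Only bases with full primitive data support this; composition-only
    entries raise a :class:`BasisError`.
    """
    key = _normalize_name(basis_name)
    if key not in _FULL_BASES:
        known = ", ".join(sorted(_FULL_BASES))
        raise BasisError(
            f"basis {basis_name!r} has no primitive data in the registry "
            f"(integral evaluation supports: {known})"
        )
    table = _FULL_BASES[key]
    coords = molecule.coords_bohr
    out = []
    for ia, sym in enumerate(molecule.symbols):
        if sym not in table:
            raise BasisError(
                f"element {sym!r} has no {basis_name!r} entry in the registry"
            )
        for shell in table[sym]:
            out.append((ia, np.array(coords[ia]), shell))
    return out
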