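"""Shared fixtures: small molecular workspaces built once per session."""

import math
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from adcfold.adc import AdcWorkspace
from adcfold.moints import mo_integral_set
from adcfold.mol import Molecule, parse_xyz
from adcfold.mp import t2_amplitudes
from adcfold.properties import TransitionMomentBuilder
from adcfold.scf import build_reference

H2O_XYZ = """3
water
O 0.000000 0.000000 -0.066575
H 0.000000 0.754175 0.528381
H 0.000000 -0.754175 0.528381
"""

H2_XYZ = """2
hydrogen at 1.4 bohr
H 0 0 0
H 0 0 0.7408481486
"""

LIH_XYZ = """2
lithium hydride
Li 0 0 0
H 0 0 1.5949
"""


def twisted_h2o2(dihedral_deg: float = 112.0) -> Molecule:
    """Hydrogen peroxide with a chiral O-O torsion."""
    roo, roh, ang = 1.475, 0.95, math.radians(100.0)
    dih = math.radians(dihedral_deg)
    o1 = np.array([0.0, 0.0, 0.0])
    o2 = np.array([0.0, 0.0, roo])
    h1 = np.array([roh * math.sin(ang), 0.0, -roh * math.cos(ang)])
    h2 = np.array([
        roh * math.sin(ang) * math.cos(dih),
        roh * math.sin(ang) * math.sin(dih),
        roo + roh * math.cos(ang),
    ])
    return Molecule([
        ("O", tuple(o1)), ("O", tuple(o2)),
        ("H", tuple(h1)), ("H", tuple(h2)),
    ])


def make_workspace(molecule: Molecule, basis: str,
                   operators=("dipole", "linmom", "magdip")):
    ref = build_reference(molecule, basis)
    ints = mo_integral_set(ref, operators=operators)
    ws = AdcWorkspace(ints, t2_amplitudes(ints))
    return ws, TransitionMomentBuilder(ws)


@pytest.fixture(scope="session")
def h2_molecule():
    return parse_xyz(H2_XYZ)


@pytest.fixture(scope="session")
def h2o_molecule():
    return parse_xyz(H2O_XYZ)


@pytest.fixture(scope="session")
def lih_molecule():
    return parse_xyz(LIH_XYZ)


@pytest.fixture(scope="session")
def h2_ws(h2_molecule):
    return make_workspace(h2_molecule, "6-31g")


@pytest.fixture(scope="session")
def h2_sto_ws(h2_molecule):
    return make_workspace(h2_molecule, "sto-3g")


@pytest.fixture(scope="session")
def lih_ws(lih_molecule):
    return make_workspace(lih_molecule, "sto-3g")


@pytest.fixture(scope="session")
def h2o_ws(h2o_molecule):
    return make_workspace(h2o_molecule, "sto-3g")


@pytest.fixture(scope="session")
def h2o2_pair():
    """Chiral H2O2 workspace and its mirror image (enantiomer)."""
    mol = twisted_h2o2()
    return make_workspace(mol, "sto-3g"), make_workspace(
        mol.mirrored(), "sto-3g"
    )
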