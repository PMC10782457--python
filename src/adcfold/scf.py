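"""Restricted Hartree-Fock reference with DIIS convergence acceleration."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from . import integrals
from .mol import Molecule


class SCFError(RuntimeError):
    """Raised when the SCF procedure fails to converge."""

    def __init__(self, message: str, last_residual: float | None = None):
        super().__init__(message)
        self.last_residual = last_residual


@dataclass
class ReferenceState:
    """Converged closed-shell SCF data anchoring all correlated quantities."""

    molecule: Molecule
    basis_name: str
    aos: list = field(repr=False)
    mo_coefficients: np.ndarray = field(repr=False)  # AO x MO
    orbital_energies: np.ndarray = field(repr=False)
    n_occupied: int = 0  # spatial orbitals
    n_virtual: int = 0
    ao_overlap: np.ndarray = field(default=None, repr=False)
    ao_eri: np.ndarray = field(default=None, repr=False)
    core_hamiltonian: np.ndarray = field(default=None, repr=False)
    scf_energy: float = 0.0

    @property
    def n_mo(self) -> int:
        return self.n_occupied + self.n_virtual

    def validate(self, tol: float = 1e-10) -> None:
        C, S = self.mo_coefficients, self.ao_overlap
        dev = np.max(np.abs(C.T @ S @ C - np.eye(self.n_mo)))
        if dev > tol:
            raise AssertionError(f"MO orthonormality violated: {dev:.2e}")
        eo = self.orbital_energies[: self.n_occupied]
        ev = self.orbital_energies[self.n_occupied:]
        if np.any(np.diff(eo) < -tol) or np.any(np.diff(ev) < -tol):
            raise AssertionError("orbital energies not ascending within blocks")


def build_reference(
    molecule: Molecule,
    basis_name: str,
    conv_tol: float = 1e-10,
    max_cycles: int = 120,
    diis_size: int = 8,
) -> ReferenceState:
    """Converge a restricted SCF and package the reference data.

    conv_tol applies to the DIIS error (orbital-gradient) norm; the density
    is idempotent to well below 1e-8 at that point.
    """
    if molecule.multiplicity != 1 or molecule.n_electrons % 2 != 0:
        raise ValueError("only closed-shell (multiplicity 1, even N) references")
    n_occ = molecule.n_electrons // 2

    aos = integrals.build_ao_basis(molecule, basis_name)
    S = integrals.overlap_matrix(aos)
    T = integrals.kinetic_matrix(aos)
    V = integrals.nuclear_attraction_matrix(aos, molecule)
    eri = integrals.eri_tensor(aos)
    hcore = T + V
    e_nuc = molecule.nuclear_repulsion()

    n_ao = len(aos)
    if n_occ > n_ao:
        raise ValueError("more occupied orbitals than basis functions")

    # symmetric orthogonalization
    s_val, s_vec = np.linalg.eigh(S)
    if np.min(s_val) < 1e-10:
        raise SCFError("near-singular AO overlap (linear dependence)")
    X = s_vec @ np.diag(s_val ** -0.5) @ s_vec.T

    def fock(D):
        J = np.einsum("mnls,ls->mn", eri, D)
        K = np.einsum("mlns,ls->mn", eri, D)
        return hcore + 2.0 * J - K

    def density(C):
        Cocc = C[:, :n_occ]
        return Cocc @ Cocc.T

    # core guess
    e, Cp = np.linalg.eigh(X.T @ hcore @ X)
    C = X @ Cp
    D = density(C)

    errs, focks = [], []
    last_res = None
    for _ in range(max_cycles):
        F = fock(D)
        err = X.T @ (F @ D @ S - S @ D @ F) @ X
        last_res = np.linalg.norm(err)
        if last_res < conv_tol:
            break
        errs.append(err)
        focks.append(F)
        if len(errs) > diis_size:
            errs.pop(0)
            focks.pop(0)
        if len(errs) > 1:
            m = len(errs)
            B = np.empty((m + 1, m + 1))
            B[-1, :] = B[:, -1] = -1.0
            B[-1, -1] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = np.sum(errs[i] * errs[j])
            rhs = np.zeros(m + 1)
            rhs[-1] = -1.0
            try:
                w = np.linalg.solve(B, rhs)[:m]
                F = sum(wi * Fi for wi, Fi in zip(w, focks))
            except np.linalg.LinAlgError:
                pass
        e, Cp = np.linalg.eigh(X.T @ F @ X)
        C = X @ Cp
        D = density(C)
    else:
        raise SCFError(
            f"SCF not converged in {max_cycles} cycles "
            f"(last DIIS residual {last_res:.3e})",
            last_residual=last_res,
        )

    F = fock(D)
    e_elec = np.sum(D * (hcore + F))
    mo_e = np.diag(C.T @ F @ C).copy()
    order = np.argsort(mo_e)
    # keep occupied block first (aufbau holds for our gapped references)
    mo_e = mo_e[order]
    C = C[:, order]

    ref = ReferenceState(
        molecule=molecule,
        basis_name=basis_name,
        aos=aos,
        mo_coefficients=C,
        orbital_energies=mo_e,
        n_occupied=n_occ,
        n_virtual=n_ao - n_occ,
        ao_overlap=S,
        ao_eri=eri,
        core_hamiltonian=hcore,
        scf_energy=float(e_elec + e_nuc),
    )
    ref.validate()
    return ref
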