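"""MO-basis integrals: batched auxiliary-Fock-matrix transformation and
one-electron property operators.

The two-electron transformation builds, for every MO pair (k,l), a density
D^{kl} = C_k C_l^T and contracts it with the AO integrals like a Coulomb
Fock build, F^{kl}_{mn} = sum_{ls} (mn|ls) D^{kl}_{ls}; transforming F^{kl}
to the MO basis yields the chemists' integrals (ij|kl).  Pairs are processed
in batches so peak memory stays at (batch size) x (one AO matrix).

Spin orbitals are interleaved (so = 2*spatial + spin) so that energies stay
ascending within the occupied and virtual blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import integrals
from .scf import ReferenceState


class ResourceError(MemoryError):
    """Raised when a requested block would exceed the memory budget."""


OPERATORS = ("dipole", "linmom", "magdip", "angmom")

_COMPONENTS = {"x": 0, "y": 1, "z": 2}


def mo_eri_spatial_direct(ref: ReferenceState) -> np.ndarray:
    """Direct O(N^5) four-index transformation; the transformation oracle."""
    C = ref.mo_coefficients
    out = np.einsum("mnls,mp->pnls", ref.ao_eri, C, optimize=True)
    out = np.einsum("pnls,nq->pqls", out, C, optimize=True)
    out = np.einsum("pqls,lr->pqrs", out, C, optimize=True)
    return np.einsum("pqrt,ts->pqrs", out, C, optimize=True)


def mo_eri_spatial_fock(ref: ReferenceState, batch_size: int | None = None,
                        memory_budget_mb: float = 2048.0) -> np.ndarray:
    """Chemists' (ij|kl) over spatial MOs via batched auxiliary Fock builds."""
    C = ref.mo_coefficients
    n = ref.n_mo
    n_ao = C.shape[0]
    pair_list = [(k, l) for k in range(n) for l in range(k + 1)]
    if batch_size is None or batch_size <= 0:
        batch_size = len(pair_list)
    need_mb = batch_size * n_ao * n_ao * 8 / 2 ** 20
    if need_mb > memory_budget_mb:
        raise ResourceError(
            f"batch of {batch_size} auxiliary Fock matrices needs "
            f"{need_mb:.0f} MB > budget {memory_budget_mb:.0f} MB; "
            "use a smaller batch size"
        )
    out = np.zeros((n, n, n, n))
    for start in range(0, len(pair_list), batch_size):
        batch = pair_list[start:start + batch_size]
        D = np.stack([np.outer(C[:, k], C[:, l]) for k, l in batch])
        # Coulomb-type auxiliary Fock build for the whole batch
        F = np.einsum("mnls,bls->bmn", ref.ao_eri, D, optimize=True)
        Fmo = np.einsum("mi,bmn,nj->bij", C, F, C, optimize=True)
        for (k, l), m in zip(batch, Fmo):
            out[:, :, k, l] = m
            if k != l:
                out[:, :, l, k] = m
    return out


def spin_orbital_antisym(mo_eri_spatial: np.ndarray) -> np.ndarray:
    """Antisymmetrized <pq||rs> over interleaved spin orbitals."""
    n = mo_eri_spatial.shape[0]
    nso = 2 * n
    if nso > 80:
        raise ResourceError(
            f"{nso} spin orbitals exceed the in-memory antisymmetrized "
            "tensor budget"
        )
    phys = mo_eri_spatial.transpose(0, 2, 1, 3)  # <PQ|RS> spatial
    d = np.eye(2)
    coul = np.einsum("PQRS,ac,bd->PaQbRcSd", phys, d, d, optimize=True)
    coul = coul.reshape(nso, nso, nso, nso)
    return coul - coul.transpose(0, 1, 3, 2)


def expand_spin(mat: np.ndarray) -> np.ndarray:
    """Expand a spatial one-electron MO matrix to interleaved spin orbitals."""
    return np.kron(mat, np.eye(2))


def property_integrals(
    ref: ReferenceState,
    operator: str,
    component: str | int | None = None,
    gauge_origin: np.ndarray | None = None,
) -> np.ndarray:
    """MO matrix (complex) of a one-electron operator.

    Conventions (atomic units, electron charge -1):

    * ``dipole``: electric dipole mu = -(r - O); real symmetric.
    * ``linmom``: p = -i nabla; purely imaginary, antisymmetric.
    * ``angmom``: L = -i (r - O) x nabla; purely imaginary, antisymmetric.
    * ``magdip``: m = -(1/2) L (orbital magnetic dipole without the 1/c).

    The gauge origin O defaults to the nuclear center of mass.
    """
    if operator not in OPERATORS:
        raise ValueError(
            f"unsupported operator {operator!r}; supported: {OPERATORS}"
        )
    if gauge_origin is None:
        gauge_origin = ref.molecule.center_of_mass()
    C = ref.mo_coefficients
    if operator == "dipole":
        ao = -integrals.moment_matrices(ref.aos, gauge_origin).astype(complex)
    elif operator == "linmom":
        ao = -1j * integrals.nabla_matrices(ref.aos)
    elif operator == "angmom":
        ao = -1j * integrals.angular_momentum_matrices(ref.aos, gauge_origin)
    else:  # magdip
        ao = 0.5j * integrals.angular_momentum_matrices(ref.aos, gauge_origin)
    mo = np.einsum("mi,dmn,nj->dij", C, ao, C, optimize=True)
    if component is None:
        return mo
    idx = _COMPONENTS[component] if isinstance(component, str) else int(component)
    return mo[idx]


@dataclass
class RawSpinOrbitalIntegrals:
    """Minimal spin-orbital integral container (synthetic/model systems).

    Provides the same block/energy interface as :class:`MOIntegralSet` so the
    correlated modules run on hand-built or random integral sets.
    """

    eps_so: np.ndarray  # spin-orbital energies, occupied first, ascending
    n_occ: int
    antisym: np.ndarray = field(repr=False)  # <pq||rs>, spin orbitals
    operators: dict = field(default_factory=dict, repr=False)
    gauge_origin: np.ndarray | None = None

    @property
    def n_virt(self) -> int:
        return len(self.eps_so) - self.n_occ

    def block(self, spaces: str) -> np.ndarray:
        return _block(self.antisym, self.n_occ, spaces)

    def operator_so(self, operator: str, component=0) -> np.ndarray:
        """Look up a stored spin-orbital operator matrix."""
        mats = self.operators[operator]
        idx = _COMPONENTS[component] if isinstance(component, str) else int(component)
        return np.asarray(mats)[idx]


def _block(antisym: np.ndarray, n_occ: int, spaces: str) -> np.ndarray:
    if len(spaces) != 4 or set(spaces) - {"o", "v"}:
        raise ValueError(f"bad block spec {spaces!r}")
    sl = {"o": slice(0, n_occ), "v": slice(n_occ, None)}
    return antisym[tuple(sl[s] for s in spaces)]


@dataclass
class MOIntegralSet:
    """Antisymmetrized spin-orbital two-electron integrals plus requested
    one-electron operator matrices for one reference state."""

    ref: ReferenceState
    antisym: np.ndarray = field(repr=False)  # <pq||rs>, spin orbitals
    operators: dict = field(default_factory=dict, repr=False)
    gauge_origin: np.ndarray | None = None

    @property
    def eps_so(self) -> np.ndarray:
        """Spin-orbital energies (interleaved spins)."""
        return np.repeat(self.ref.orbital_energies, 2)

    @property
    def n_occ(self) -> int:
        """Occupied spin orbitals."""
        return 2 * self.ref.n_occupied

    @property
    def n_virt(self) -> int:
        return 2 * self.ref.n_virtual

    def block(self, spaces: str) -> np.ndarray:
        """Slice <pq||rs> by space string, e.g. 'oovv', 'ovov', 'vvvv'."""
        return _block(self.antisym, self.n_occ, spaces)

    def operator_so(self, operator: str, component) -> np.ndarray:
        """Spin-orbital matrix of an operator component (complex)."""
        key = operator
        if key not in self.operators:
            self.operators[key] = property_integrals(
                self.ref, operator, None, self.gauge_origin
            )
        idx = _COMPONENTS[component] if isinstance(component, str) else int(component)
        return expand_spin(self.operators[key][idx])


def mo_integral_set(
    ref: ReferenceState,
    batch_size: int | None = None,
    operators: tuple = (),
    gauge_origin: np.ndarray | None = None,
) -> MOIntegralSet:
    """Build the spin-orbital integral set for correlated calculations."""
    spatial = mo_eri_spatial_fock(ref, batch_size=batch_size)
    ints = MOIntegralSet(
        ref=ref, antisym=spin_orbital_antisym(spatial), gauge_origin=gauge_origin
    )
    for op in operators:
        ints.operators[op] = property_integrals(ref, op, None, gauge_origin)
    return ints
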