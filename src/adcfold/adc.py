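"""ADC(2) secular matrix: matrix-free sigma builds and the dense oracle.

Spin-orbital working equations through second order in the fluctuation
potential for the p-h/p-h block, first order for the p-h/2p-2h coupling,
zeroth order (diagonal) for the 2p-2h/2p-2h block.  The 2p-2h manifold is
indexed by ordered spin-orbital pairs i<j, a<b, which keeps the doubles
block strictly diagonal and the folding denominators unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .moints import MOIntegralSet
from .mp import Amplitudes


class OracleCapError(MemoryError):
    """Dense assembly requested beyond the configured size cap."""


@dataclass
class DenseAdcMatrix:
    """Explicit singles+doubles ADC(2) matrix; the validation oracle."""

    matrix: np.ndarray = field(repr=False)
    n_s: int = 0
    n_d: int = 0

    @property
    def M_ss(self) -> np.ndarray:
        return self.matrix[: self.n_s, : self.n_s]

    @property
    def M_sd(self) -> np.ndarray:
        return self.matrix[: self.n_s, self.n_s:]

    @property
    def M_ds(self) -> np.ndarray:
        return self.matrix[self.n_s:, : self.n_s]

    @property
    def M_dd(self) -> np.ndarray:
        return self.matrix[self.n_s:, self.n_s:]

    def eigenstates(self):
        """All eigenpairs of the full singles+doubles matrix."""
        return np.linalg.eigh(self.matrix)


class AdcWorkspace:
    """MP2 amplitudes plus MO integral blocks; provides the sigma builds.

    Parameters
    ----------
    ints : MOIntegralSet
        Spin-orbital antisymmetrized integrals.
    amps : Amplitudes
        First-order doubles amplitudes.
    """

    def __init__(self, ints: MOIntegralSet, amps: Amplitudes):
        self.ints = ints
        self.amps = amps
        eps = ints.eps_so
        self.n_occ = ints.n_occ
        self.n_virt = ints.n_virt
        self.e_occ = eps[: self.n_occ]
        self.e_virt = eps[self.n_occ:]
        self.n_s = self.n_occ * self.n_virt
        # ordered 2p-2h index maps (i<j, a<b)
        io, jo = np.triu_indices(self.n_occ, k=1)
        av, bv = np.triu_indices(self.n_virt, k=1)
        self._io, self._jo = io, jo
        self._av, self._bv = av, bv
        self.n_d = len(io) * len(av)

        t2 = amps.t2
        oovv = ints.block("oovv")
        # second-order p-h/p-h intermediates (delta_ij and delta_ab terms)
        q_vv = np.einsum("klac,klbc->ab", t2, oovv, optimize=True)
        self._c_vv = -0.25 * (q_vv + q_vv.T)
        q_oo = np.einsum("ikcd,jkcd->ij", t2, oovv, optimize=True)
        self._c_oo = -0.25 * (q_oo + q_oo.T)

    # -- singles-space contraction ------------------------------------------

    def sigma_singles(self, b: np.ndarray) -> np.ndarray:
        """M_ss . b with M_ss correct through second order."""
        bm = self._as_singles(b)
        ints, t2 = self.ints, self.amps.t2
        sig = (self.e_virt[None, :] - self.e_occ[:, None]) * bm
        sig += np.einsum("ajib,jb->ia", ints.block("voov"), bm, optimize=True)
        sig += bm @ self._c_vv.T
        sig += self._c_oo @ bm
        oovv = ints.block("oovv")
        u = np.einsum("jkbc,jb->kc", oovv, bm, optimize=True)
        w = np.einsum("jkbc,jb->kc", t2, bm, optimize=True)
        sig += 0.5 * np.einsum("ikac,kc->ia", t2, u, optimize=True)
        sig += 0.5 * np.einsum("ikac,kc->ia", oovv, w, optimize=True)
        return sig.reshape(-1)

    def singles_diagonal(self) -> np.ndarray:
        """Orbital-energy differences over the p-h index (preconditioner)."""
        return (self.e_virt[None, :] - self.e_occ[:, None]).reshape(-1)

    # -- coupling blocks ----------------------------------------------------

    def _coupling_full(self, bm: np.ndarray) -> np.ndarray:
        """M_ds . b as the full antisymmetric (o,o,v,v) tensor."""
        ints = self.ints
        ooov = ints.block("ooov")
        vovv = ints.block("vovv")
        out = -np.einsum("klid,ic->klcd", ooov, bm, optimize=True)
        out += np.einsum("klic,id->klcd", ooov, bm, optimize=True)
        out += np.einsum("alcd,ka->klcd", vovv, bm, optimize=True)
        out -= np.einsum("akcd,la->klcd", vovv, bm, optimize=True)
        return out

    def couple_ds(self, b: np.ndarray) -> np.ndarray:
        """First-order 2p-2h <- p-h coupling applied to a singles vector."""
        full = self._coupling_full(self._as_singles(b))
        io, jo, av, bv = self._io, self._jo, self._av, self._bv
        return full[io[:, None], jo[:, None], av[None, :], bv[None, :]].reshape(-1)

    def couple_sd(self, v: np.ndarray) -> np.ndarray:
        """Adjoint p-h <- 2p-2h coupling applied to a doubles vector."""
        vfull = self._doubles_to_full(v)
        ints = self.ints
        ooov = ints.block("ooov")
        vovv = ints.block("vovv")
        sig = -0.5 * np.einsum("klid,klad->ia", ooov, vfull, optimize=True)
        sig += 0.5 * np.einsum("alcd,ilcd->ia", vovv, vfull, optimize=True)
        return sig.reshape(-1)

    def doubles_diagonal(self) -> np.ndarray:
        """Zeroth-order 2p-2h diagonal e_a + e_b - e_i - e_j (i<j, a<b)."""
        io, jo, av, bv = self._io, self._jo, self._av, self._bv
        d = (
            self.e_virt[av][None, :] + self.e_virt[bv][None, :]
            - self.e_occ[io][:, None] - self.e_occ[jo][:, None]
        )
        return d.reshape(-1)

    # -- helpers ------------------------------------------------------------

    def _as_singles(self, b: np.ndarray) -> np.ndarray:
        b = np.asarray(b)
        if b.size != self.n_s:
            raise ValueError(f"singles vector of length {b.size}, expected {self.n_s}")
        if np.iscomplexobj(b):
            raise TypeError(
                "contractions take real vectors; split complex vectors into "
                "real and imaginary parts"
            )
        return b.reshape(self.n_occ, self.n_virt)

    def _doubles_to_full(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v)
        if v.size != self.n_d:
            raise ValueError(f"doubles vector of length {v.size}, expected {self.n_d}")
        io, jo, av, bv = self._io, self._jo, self._av, self._bv
        vm = v.reshape(len(io), len(av))
        full = np.zeros(
            (self.n_occ, self.n_occ, self.n_virt, self.n_virt), dtype=v.dtype
        )
        full[io[:, None], jo[:, None], av[None, :], bv[None, :]] = vm
        full[jo[:, None], io[:, None], av[None, :], bv[None, :]] = -vm
        full[io[:, None], jo[:, None], bv[None, :], av[None, :]] = -vm
        full[jo[:, None], io[:, None], bv[None, :], av[None, :]] = vm
        return full

    def full_to_doubles(self, full: np.ndarray) -> np.ndarray:
        """Restrict an antisymmetric (o,o,v,v) tensor to the ordered index."""
        io, jo, av, bv = self._io, self._jo, self._av, self._bv
        return full[io[:, None], jo[:, None], av[None, :], bv[None, :]].reshape(-1)

    # -- dense oracle -------------------------------------------------------

    def assemble_dense(self, cap: int = 5000) -> DenseAdcMatrix:
        """Explicit dense singles+doubles matrix (small systems only)."""
        dim = self.n_s + self.n_d
        if dim > cap:
            raise OracleCapError(
                f"dense oracle dimension {dim} exceeds cap {cap}"
            )
        M = np.zeros((dim, dim))
        eye = np.eye(self.n_s)
        for col in range(self.n_s):
            M[: self.n_s, col] = self.sigma_singles(eye[:, col])
            M[self.n_s:, col] = self.couple_ds(eye[:, col])
        M[: self.n_s, self.n_s:] = M[self.n_s:, : self.n_s].T
        M[self.n_s:, self.n_s:] = np.diag(self.doubles_diagonal())
        return DenseAdcMatrix(matrix=M, n_s=self.n_s, n_d=self.n_d)

    def adc1_matrix(self) -> np.ndarray:
        """Singles block through first order (the ADC(1) matrix)."""
        ints = self.ints
        m = np.einsum("ajib->iajb", ints.block("voov")).astype(float)
        m = m.reshape(self.n_s, self.n_s).copy()
        m[np.diag_indices(self.n_s)] += self.singles_diagonal()
        return m
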