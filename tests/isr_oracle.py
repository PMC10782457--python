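"""Order-tracked numerical intermediate-state-representation oracle.

Builds, in the full determinant space of a small system, the ADC secular
matrix blocks and the modified transition moments by their defining
construction: Moller-Plesset ground-state orders, excitation-class precursor
states, Gram-Schmidt orthogonalization between classes and symmetric
(Lowdin) orthonormalization within a class, all with explicit bookkeeping of
the perturbation order.  Everything is numerical linear algebra on
determinant-space vectors; no closed-form ADC working equation enters, which
makes this a genuinely independent oracle for the package's contractions.

Orders kept: p-h/p-h block through 2nd, p-h/2p-2h coupling through 1st,
2p-2h diagonal through 0th, p-h transition moments through 2nd, 2p-2h
transition moments through 1st -- the ADC(2) truncation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

MAX_ORDER = 2


# -- determinant algebra ----------------------------------------------------

def _ann(det: int, p: int):
    if not det & (1 << p):
        return None, 0
    sign = (-1) ** bin(det & ((1 << p) - 1)).count("1")
    return det & ~(1 << p), sign


def _cre(det: int, p: int):
    if det & (1 << p):
        return None, 0
    sign = (-1) ** bin(det & ((1 << p) - 1)).count("1")
    return det | (1 << p), sign


class DetSpace:
    """Full determinant space of n_elec electrons in n_so spin orbitals."""

    def __init__(self, n_so: int, n_elec: int):
        self.n_so = n_so
        self.n_elec = n_elec
        self.dets = [
            sum(1 << p for p in occ)
            for occ in combinations(range(n_so), n_elec)
        ]
        self.index = {d: k for k, d in enumerate(self.dets)}
        self.dim = len(self.dets)

    def one_body_matrix(self, h: np.ndarray) -> np.ndarray:
        out = np.zeros((self.dim, self.dim))
        n = self.n_so
        for col, det in enumerate(self.dets):
            for q in range(n):
                d1, s1 = _ann(det, q)
                if d1 is None:
                    continue
                for p in range(n):
                    if h[p, q] == 0.0:
                        continue
                    d2, s2 = _cre(d1, p)
                    if d2 is None:
                        continue
                    out[self.index[d2], col] += h[p, q] * s1 * s2
        return out

    def two_body_matrix(self, asym: np.ndarray) -> np.ndarray:
        """(1/4) sum <pq||rs> a+_p a+_q a_s a_r."""
        out = np.zeros((self.dim, self.dim))
        n = self.n_so
        for col, det in enumerate(self.dets):
            occ = [p for p in range(n) if det & (1 << p)]
            for r in occ:
                d1, s1 = _ann(det, r)
                for s in occ:
                    if s == r:
                        continue
                    d2, s2 = _ann(d1, s)
                    for q in range(n):
                        d3, s3 = _cre(d2, q)
                        if d3 is None:
                            continue
                        for p in range(n):
                            v = asym[p, q, r, s]
                            if v == 0.0:
                                continue
                            d4, s4 = _cre(d3, p)
                            if d4 is None:
                                continue
                            out[self.index[d4], col] += (
                                0.25 * v * s1 * s2 * s3 * s4
                            )
        return out

    def excitation_vector(self, det0: int, holes, particles):
        """C_J |det0> as a basis vector with sign; operators applied
        right-to-left: a+_{p1} a+_{p0} a_{h1} a_{h0} for holes=(h0,h1)."""
        det, sign = det0, 1
        for h in holes:
            det, s = _ann(det, h)
            if det is None:
                return None, 0
            sign *= s
        for p in reversed(particles):
            det, s = _cre(det, p)
            if det is None:
                return None, 0
            sign *= s
        return det, sign


# -- order-series helpers ---------------------------------------------------

def _series_dot(A, B, k):
    return sum(A[m] @ B[k - m] for m in range(k + 1))


def _series_opdot(A, Op, B, k):
    return sum(A[m] @ (Op @ B[k - m]) for m in range(k + 1))


class IsrOracle:
    """ADC(2)-truncated ISR blocks for an arbitrary small spin-orbital
    Hamiltonian (eps, <pq||rs>) with a canonical (Brillouin) reference."""

    def __init__(self, eps: np.ndarray, asym: np.ndarray, n_occ: int):
        self.eps = np.asarray(eps, dtype=float)
        self.n_so = len(eps)
        self.n_occ = n_occ
        self.n_virt = self.n_so - n_occ
        self.space = DetSpace(self.n_so, n_occ)
        sp = self.space

        # one-body part chosen so the Fock matrix is diagonal with energies
        # eps for the chosen occupied set (canonical orbitals, Brillouin).
        h = np.diag(self.eps) - np.einsum(
            "piqi->pq", asym[:, :n_occ, :, :n_occ]
        )
        H = sp.one_body_matrix(h) + sp.two_body_matrix(asym)
        e_det = np.array(
            [sum(self.eps[p] for p in range(self.n_so) if d & (1 << p))
             for d in sp.dets]
        )
        self.H0_diag = e_det
        self.V = H - np.diag(e_det)

        self.hf = sum(1 << p for p in range(n_occ))
        self.hf_idx = sp.index[self.hf]
        self.E0 = e_det[self.hf_idx]

        self._ground_state()
        self.singles = [
            (i, a) for i in range(n_occ) for a in range(n_occ, self.n_so)
        ]
        self.doubles = [
            (i, j, a, b)
            for i, j in combinations(range(n_occ), 2)
            for a, b in combinations(range(n_occ, self.n_so), 2)
        ]
        self._intermediate_states()

    # ground-state Moller-Plesset orders, normalized
    def _ground_state(self):
        sp = self.space
        psi0 = np.zeros(sp.dim)
        psi0[self.hf_idx] = 1.0
        denom = self.E0 - self.H0_diag
        denom[self.hf_idx] = 1.0  # masked below
        E1 = self.V[self.hf_idx, self.hf_idx]
        w = self.V @ psi0
        w[self.hf_idx] = 0.0
        psi1 = w / denom
        w2 = self.V @ psi1 - E1 * psi1
        w2[self.hf_idx] = 0.0
        psi2 = w2 / denom
        self.E_gs = [self.E0, E1, float(psi0 @ self.V @ psi1)]
        n2 = float(psi1 @ psi1)
        self.g = [psi0, psi1, psi2 - 0.5 * n2 * psi0]

    def _series_H(self, A, B, k):
        out = sum((A[m] * self.H0_diag) @ B[k - m] for m in range(k + 1))
        if k >= 1:
            out += sum(A[m] @ (self.V @ B[k - 1 - m]) for m in range(k))
        return out

    def _apply_excitation(self, holes, particles):
        """C_J applied to the ground-state series, as a series."""
        sp = self.space
        out = [np.zeros(sp.dim) for _ in range(MAX_ORDER + 1)]
        for order in range(MAX_ORDER + 1):
            src = self.g[order]
            for col in np.nonzero(src)[0]:
                det, sign = sp.excitation_vector(sp.dets[col], holes, particles)
                if det is not None:
                    out[order][sp.index[det]] += sign * src[col]
        return out

    def _intermediate_states(self):
        ns, nd = len(self.singles), len(self.doubles)
        dim = self.space.dim

        # class-1 precursors
        prec1 = []
        for (i, a) in self.singles:
            cjg = self._apply_excitation((i,), (a,))
            # subtract |g><g|C_J|g> order by order
            ov = [sum(self.g[m] @ cjg[k - m] for m in range(k + 1))
                  for k in range(MAX_ORDER + 1)]
            p = []
            for k in range(MAX_ORDER + 1):
                v = cjg[k].copy()
                for m in range(k + 1):
                    v -= ov[m] * self.g[k - m]
                p.append(v)
            prec1.append(p)

        # overlap series within class 1 and Lowdin inverse square root
        S = [np.zeros((ns, ns)) for _ in range(MAX_ORDER + 1)]
        for K in range(ns):
            for L in range(ns):
                for k in range(MAX_ORDER + 1):
                    S[k][K, L] = sum(
                        prec1[K][m] @ prec1[L][k - m] for m in range(k + 1)
                    )
        assert np.allclose(S[0], np.eye(ns), atol=1e-12)
        T = [np.eye(ns), -0.5 * S[1], -0.5 * S[2] + 0.375 * (S[1] @ S[1])]

        # intermediate states of class 1
        self.itilde1 = []
        for J in range(ns):
            st = []
            for k in range(MAX_ORDER + 1):
                v = np.zeros(dim)
                for m in range(k + 1):
                    for K in range(ns):
                        if T[m][K, J] != 0.0:
                            v += prec1[K][k - m] * T[m][K, J]
                st.append(v)
            self.itilde1.append(st)

        # class-2 precursors: Gram-Schmidt against ground state and class 1
        prec2 = []
        for (i, j, a, b) in self.doubles:
            cjg = self._apply_excitation((i, j), (a, b))
            p = [cjg[k].copy() for k in range(MAX_ORDER + 1)]
            ov = [sum(self.g[m] @ cjg[k - m] for m in range(k + 1))
                  for k in range(MAX_ORDER + 1)]
            for k in range(MAX_ORDER + 1):
                for m in range(k + 1):
                    p[k] -= ov[m] * self.g[k - m]
            for K in range(ns):
                ovk = [
                    sum(self.itilde1[K][m] @ cjg[k - m] for m in range(k + 1))
                    for k in range(MAX_ORDER + 1)
                ]
                for k in range(MAX_ORDER + 1):
                    for m in range(k + 1):
                        p[k] -= ovk[m] * self.itilde1[K][k - m]
            prec2.append(p)

        # Lowdin within class 2 (orders 0..1 suffice for ADC(2) blocks)
        S2 = [np.zeros((nd, nd)) for _ in range(2)]
        for K in range(nd):
            for L in range(nd):
                for k in range(2):
                    S2[k][K, L] = sum(
                        prec2[K][m] @ prec2[L][k - m] for m in range(k + 1)
                    )
        assert np.allclose(S2[0], np.eye(nd), atol=1e-12)
        T2 = [np.eye(nd), -0.5 * S2[1]]
        self.itilde2 = []
        for J in range(nd):
            st = []
            for k in range(2):
                v = np.zeros(dim)
                for m in range(k + 1):
                    for K in range(nd):
                        if T2[m][K, J] != 0.0:
                            v += prec2[K][k - m] * T2[m][K, J]
                st.append(v)
            self.itilde2.append(st)

    # -- public blocks ------------------------------------------------------

    def m_ss(self) -> np.ndarray:
        """p-h/p-h block through second order."""
        ns = len(self.singles)
        M = np.zeros((ns, ns))
        for I in range(ns):
            for J in range(ns):
                val = 0.0
                for k in range(MAX_ORDER + 1):
                    val += self._series_H(self.itilde1[I], self.itilde1[J], k)
                    for m in range(k + 1):
                        val -= self.E_gs[m] * (
                            sum(self.itilde1[I][q] @ self.itilde1[J][k - m - q]
                                for q in range(k - m + 1))
                        )
                M[I, J] = val
        return M

    def m_ds(self) -> np.ndarray:
        """2p-2h/p-h coupling through first order."""
        ns, nd = len(self.singles), len(self.doubles)
        M = np.zeros((nd, ns))
        for I in range(nd):
            for J in range(ns):
                val = 0.0
                for k in range(2):
                    val += self._series_H(
                        self.itilde2[I][: k + 1], self.itilde1[J][: k + 1], k
                    )
                    for m in range(k + 1):
                        val -= self.E_gs[m] * sum(
                            self.itilde2[I][q] @ self.itilde1[J][k - m - q]
                            for q in range(k - m + 1)
                        )
                M[I, J] = val
        return M

    def m_dd_diagonal(self) -> np.ndarray:
        """Zeroth-order doubles diagonal."""
        out = np.empty(len(self.doubles))
        for K, (i, j, a, b) in enumerate(self.doubles):
            out[K] = self.eps[a] + self.eps[b] - self.eps[i] - self.eps[j]
        return out

    def mp_wavefunction_amplitudes(self):
        """Determinant-extracted MP amplitudes: (t2, s2, td2).

        t2[i,j,a,b] are first-order doubles, s2[i,a] and td2[i,j,a,b] the
        singles and doubles amplitudes of the second-order wave function
        (intermediate normalization), with the operator phase convention of
        :meth:`DetSpace.excitation_vector`.
        """
        sp = self.space
        no, nv = self.n_occ, self.n_virt
        t2 = np.zeros((no, no, nv, nv))
        td2 = np.zeros((no, no, nv, nv))
        for (i, j, a, b) in self.doubles:
            det, sign = sp.excitation_vector(self.hf, (i, j), (a, b))
            idx = sp.index[det]
            for arr, src in ((t2, self.g[1]), (td2, self.g[2])):
                v = sign * src[idx]
                ia, jb = i, j
                aa, bb = a - no, b - no
                arr[ia, jb, aa, bb] = v
                arr[jb, ia, aa, bb] = -v
                arr[ia, jb, bb, aa] = -v
                arr[jb, ia, bb, aa] = v
        s2 = np.zeros((no, nv))
        for (i, a) in self.singles:
            det, sign = sp.excitation_vector(self.hf, (i,), (a,))
            s2[i, a - no] = sign * self.g[2][sp.index[det]]
        return t2, s2, td2

    def transition_moments_orders(self, d_matrix: np.ndarray):
        """Per-order modified transition moments: F_s orders [0,1,2],
        F_d orders [0,1]."""
        D = self.space.one_body_matrix(d_matrix)
        ns, nd = len(self.singles), len(self.doubles)
        F_s = [np.zeros(ns) for _ in range(MAX_ORDER + 1)]
        for J in range(ns):
            for k in range(MAX_ORDER + 1):
                F_s[k][J] = _series_opdot(self.itilde1[J], D, self.g, k)
        F_d = [np.zeros(nd) for _ in range(2)]
        for J in range(nd):
            for k in range(2):
                F_d[k][J] = _series_opdot(self.itilde2[J][: k + 1], D, self.g, k)
        return F_s, F_d

    def transition_moments(self, d_matrix: np.ndarray):
        """Modified transition moments: (F_s through 2nd, F_d through 1st).

        d_matrix is the spin-orbital matrix of a one-particle operator.
        """
        D = self.space.one_body_matrix(d_matrix)
        ns, nd = len(self.singles), len(self.doubles)
        F_s = np.zeros(ns)
        for J in range(ns):
            F_s[J] = sum(
                _series_opdot(self.itilde1[J], D, self.g, k)
                for k in range(MAX_ORDER + 1)
            )
        F_d = np.zeros(nd)
        for J in range(nd):
            F_d[J] = sum(
                _series_opdot(self.itilde2[J][: k + 1], D, self.g, k)
                for k in range(2)
            )
        return F_s, F_d


def random_system(n_occ: int, n_virt: int, seed: int, scale: float = 0.15):
    """Random canonical spin-orbital system with proper integral symmetry."""
    rng = np.random.default_rng(seed)
    n = n_occ + n_virt
    eps = np.sort(rng.uniform(-2.0, -0.5, n_occ))
    eps = np.concatenate([eps, np.sort(rng.uniform(0.5, 2.5, n_virt))])
    w = rng.normal(scale=scale, size=(n, n, n, n))
    w = w + w.transpose(1, 0, 2, 3)
    w = w + w.transpose(0, 1, 3, 2)
    w = w + w.transpose(2, 3, 0, 1)  # 8-fold "chemist" symmetry
    coul = w.transpose(0, 2, 1, 3)  # <pq|rs>
    asym = coul - coul.transpose(0, 1, 3, 2)
    return eps, asym
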