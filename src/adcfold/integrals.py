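"""Gaussian-basis AO integrals via the McMurchie–Davidson scheme.

Contracted Cartesian Gaussians; one-electron integrals (overlap, kinetic,
nuclear attraction, multipole moments, nabla and angular-momentum matrices)
and the full electron-repulsion tensor in chemists' notation (mu nu | la si).

The Hermite-expansion recursions and Hermite Coulomb integrals follow the
standard presentation (Helgaker/Jorgensen/Olsen conventions).  Angular
momenta are unrestricted in the recursions; the shipped basis registry uses
s and p shells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import hyp1f1

from .basis import shells_for_molecule
from .mol import Molecule

_CART_POWERS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)],
}


def _double_factorial(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, powers) -> float:
    """Normalization constant of a primitive Cartesian Gaussian."""
    lx, ly, lz = powers
    L = lx + ly + lz
    num = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (L / 2.0)
    den = np.sqrt(
        _double_factorial(2 * lx - 1)
        * _double_factorial(2 * ly - 1)
        * _double_factorial(2 * lz - 1)
    )
    return num / den


@dataclass
class CGTO:
    """One contracted Cartesian Gaussian basis function."""

    center: np.ndarray
    powers: tuple
    alphas: np.ndarray
    coeffs: np.ndarray  # primitive norms folded in; contraction normalized
    atom_index: int = -1
    shell_index: int = -1


def build_ao_basis(molecule: Molecule, basis_name: str) -> list:
    """Expand the shells of ``basis_name`` into normalized CGTOs."""
    aos = []
    for ishell, (ia, center, shell) in enumerate(
        shells_for_molecule(molecule, basis_name)
    ):
        if shell.l not in _CART_POWERS:
            raise NotImplementedError(f"angular momentum l={shell.l} not supported")
        alphas = np.asarray(shell.exponents, dtype=float)
        raw = np.asarray(shell.coefficients, dtype=float)
        for powers in _CART_POWERS[shell.l]:
            norms = np.array([primitive_norm(a, powers) for a in alphas])
            ao = CGTO(center, powers, alphas, raw * norms, ia, ishell)
            s = _overlap_cgto(ao, ao)
            ao.coeffs = ao.coeffs / np.sqrt(s)
            aos.append(ao)
    return aos


# ---------------------------------------------------------------------------
# Hermite expansion coefficients
# ---------------------------------------------------------------------------

def _e_table(imax: int, jmax: int, ab: float, a: float, b: float) -> np.ndarray:
    """E[i, j, t] Hermite expansion coefficients for one Cartesian direction.

    ab = A - B (bra center minus ket center component).
    """
    p = a + b
    mu = a * b / p
    E = np.zeros((imax + 1, jmax + 1, imax + jmax + 1))
    E[0, 0, 0] = np.exp(-mu * ab * ab)
    x_pa = -b * ab / p  # P - A
    x_pb = a * ab / p  # P - B
    for i in range(1, imax + 1):
        for t in range(i + 1):
            val = x_pa * E[i - 1, 0, t]
            if t > 0:
                val += E[i - 1, 0, t - 1] / (2 * p)
            if t + 1 <= i - 1:
                val += (t + 1) * E[i - 1, 0, t + 1]
            E[i, 0, t] = val
    for j in range(1, jmax + 1):
        for i in range(imax + 1):
            for t in range(i + j + 1):
                val = x_pb * E[i, j - 1, t]
                if t > 0:
                    val += E[i, j - 1, t - 1] / (2 * p)
                if t + 1 <= i + j - 1:
                    val += (t + 1) * E[i, j - 1, t + 1]
                E[i, j, t] = val
    return E


def boys(nmax: int, T: float) -> np.ndarray:
    """Boys functions F_0..F_nmax at T, by downward recursion."""
    out = np.empty(nmax + 1)
    out[nmax] = hyp1f1(nmax + 0.5, nmax + 1.5, -T) / (2 * nmax + 1)
    expT = np.exp(-T)
    for n in range(nmax, 0, -1):
        out[n - 1] = (2 * T * out[n] + expT) / (2 * n - 1)
    return out


def _hermite_coulomb(tmax: int, umax: int, vmax: int, p: float, pc: np.ndarray):
    """Hermite Coulomb integrals R_{tuv} at (p, PC) for t<=tmax etc."""
    nmax = tmax + umax + vmax
    T = p * float(pc @ pc)
    F = boys(nmax, T)
    # R^n stored as arrays; build by recursion over total order.
    R = np.zeros((nmax + 1, tmax + 1, umax + 1, vmax + 1))
    minus2p = -2.0 * p
    for n in range(nmax + 1):
        R[n, 0, 0, 0] = (minus2p ** n) * F[n]
    x, y, z = pc
    for t in range(1, tmax + 1):
        for n in range(nmax - t + 1):
            val = x * R[n + 1, t - 1, 0, 0]
            if t > 1:
                val += (t - 1) * R[n + 1, t - 2, 0, 0]
            R[n, t, 0, 0] = val
    for u in range(1, umax + 1):
        for t in range(tmax + 1):
            for n in range(nmax - t - u + 1):
                val = y * R[n + 1, t, u - 1, 0]
                if u > 1:
                    val += (u - 1) * R[n + 1, t, u - 2, 0]
                R[n, t, u, 0] = val
    for v in range(1, vmax + 1):
        for u in range(umax + 1):
            for t in range(tmax + 1):
                for n in range(nmax - t - u - v + 1):
                    val = z * R[n + 1, t, u, v - 1]
                    if v > 1:
                        val += (v - 1) * R[n + 1, t, u, v - 2]
                    R[n, t, u, v] = val
    return R[0]


# ---------------------------------------------------------------------------
# One-electron integrals
# ---------------------------------------------------------------------------

def _overlap_1d(E: np.ndarray, i: int, j: int, p: float) -> float:
    return E[i, j, 0] * np.sqrt(np.pi / p)


def _pair_tables(ga: CGTO, gb: CGTO, ka: int, kb: int, extra: int = 0):
    a = ga.alphas[ka]
    b = gb.alphas[kb]
    AB = ga.center - gb.center
    tabs = [
        _e_table(ga.powers[d], gb.powers[d] + extra, AB[d], a, b) for d in range(3)
    ]
    return a, b, tabs


def _overlap_cgto(ga: CGTO, gb: CGTO) -> float:
    val = 0.0
    for ka, ca in enumerate(ga.coeffs):
        for kb, cb in enumerate(gb.coeffs):
            a, b, (Ex, Ey, Ez) = _pair_tables(ga, gb, ka, kb)
            p = a + b
            s = (
                _overlap_1d(Ex, ga.powers[0], gb.powers[0], p)
                * _overlap_1d(Ey, ga.powers[1], gb.powers[1], p)
                * _overlap_1d(Ez, ga.powers[2], gb.powers[2], p)
            )
            val += ca * cb * s
    return val


def overlap_matrix(aos: list) -> np.ndarray:
    n = len(aos)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            S[i, j] = S[j, i] = _overlap_cgto(aos[i], aos[j])
    return S


def _kinetic_cgto(ga: CGTO, gb: CGTO) -> float:
    val = 0.0
    la = ga.powers
    lb = gb.powers
    for ka, ca in enumerate(ga.coeffs):
        for kb, cb in enumerate(gb.coeffs):
            a, b, tabs = _pair_tables(ga, gb, ka, kb, extra=2)
            p = a + b
            s1d = [_overlap_1d(tabs[d], la[d], lb[d], p) for d in range(3)]

            def d2(d):
                j = lb[d]
                out = -2.0 * b * (2 * j + 1) * tabs[d][la[d], j, 0]
                out += 4.0 * b * b * tabs[d][la[d], j + 2, 0]
                if j >= 2:
                    out += j * (j - 1) * tabs[d][la[d], j - 2, 0]
                return out * np.sqrt(np.pi / p)

            lap = d2(0) * s1d[1] * s1d[2] + s1d[0] * d2(1) * s1d[2] \
                + s1d[0] * s1d[1] * d2(2)
            val += ca * cb * (-0.5) * lap
    return val


def kinetic_matrix(aos: list) -> np.ndarray:
    n = len(aos)
    T = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            T[i, j] = T[j, i] = _kinetic_cgto(aos[i], aos[j])
    return T


def nuclear_attraction_matrix(aos: list, molecule: Molecule) -> np.ndarray:
    """V_{mu nu} = -sum_A Z_A <mu| 1/r_A |nu>."""
    n = len(aos)
    V = np.zeros((n, n))
    charges = molecule.charges
    centers = molecule.coords_bohr
    for i in range(n):
        ga = aos[i]
        for j in range(i + 1):
            gb = aos[j]
            val = 0.0
            for ka, ca in enumerate(ga.coeffs):
                for kb, cb in enumerate(gb.coeffs):
                    a, b, (Ex, Ey, Ez) = _pair_tables(ga, gb, ka, kb)
                    p = a + b
                    P = (a * ga.center + b * gb.center) / p
                    etuv = np.einsum(
                        "t,u,v->tuv",
                        Ex[ga.powers[0], gb.powers[0]],
                        Ey[ga.powers[1], gb.powers[1]],
                        Ez[ga.powers[2], gb.powers[2]],
                    )
                    tm, um, vm = (s - 1 for s in etuv.shape)
                    acc = 0.0
                    for A in range(molecule.n_atoms):
                        R = _hermite_coulomb(tm, um, vm, p, P - centers[A])
                        acc += -charges[A] * float(np.sum(etuv * R))
                    val += ca * cb * (2.0 * np.pi / p) * acc
            V[i, j] = V[j, i] = val
    return V


def moment_matrices(aos: list, origin) -> np.ndarray:
    """First-moment (dipole-length, electron coordinate) matrices.

    Returns array (3, n, n) of <mu| r_d - origin_d |nu>; symmetric.
    """
    origin = np.asarray(origin, dtype=float)
    n = len(aos)
    M = np.zeros((3, n, n))
    for i in range(n):
        ga = aos[i]
        for j in range(i + 1):
            gb = aos[j]
            vals = np.zeros(3)
            for ka, ca in enumerate(ga.coeffs):
                for kb, cb in enumerate(gb.coeffs):
                    a, b, tabs = _pair_tables(ga, gb, ka, kb)
                    p = a + b
                    P = (a * ga.center + b * gb.center) / p
                    s1d = np.array(
                        [_overlap_1d(tabs[d], ga.powers[d], gb.powers[d], p)
                         for d in range(3)]
                    )
                    for d in range(3):
                        E = tabs[d][ga.powers[d], gb.powers[d]]
                        e1 = E[1] if len(E) > 1 else 0.0
                        m1 = (e1 + (P[d] - origin[d]) * E[0]) * np.sqrt(np.pi / p)
                        other = np.prod(np.delete(s1d, d))
                        vals[d] += ca * cb * m1 * other
            M[:, i, j] = vals
            M[:, j, i] = vals
    return M


def _deriv_1d(tab: np.ndarray, i: int, j: int, b: float, p: float) -> float:
    """<i| d/dx |j> in one dimension (ket-side derivative)."""
    out = -2.0 * b * tab[i, j + 1, 0]
    if j >= 1:
        out += j * tab[i, j - 1, 0]
    return out * np.sqrt(np.pi / p)


def nabla_matrices(aos: list) -> np.ndarray:
    """Matrices of <mu| d/dr_d |nu>; real antisymmetric.

    The linear-momentum operator is p = -i * nabla.
    """
    n = len(aos)
    D = np.zeros((3, n, n))
    for i in range(n):
        ga = aos[i]
        for j in range(n):
            gb = aos[j]
            vals = np.zeros(3)
            for ka, ca in enumerate(ga.coeffs):
                for kb, cb in enumerate(gb.coeffs):
                    a, b, tabs = _pair_tables(ga, gb, ka, kb, extra=1)
                    p = a + b
                    s1d = np.array(
                        [_overlap_1d(tabs[d], ga.powers[d], gb.powers[d], p)
                         for d in range(3)]
                    )
                    for d in range(3):
                        dd = _deriv_1d(tabs[d], ga.powers[d], gb.powers[d], b, p)
                        other = np.prod(np.delete(s1d, d))
                        vals[d] += ca * cb * dd * other
            D[:, i, j] = vals
    return D


def angular_momentum_matrices(aos: list, origin) -> np.ndarray:
    """Matrices of <mu| (r-origin) x nabla |nu>; real antisymmetric.

    The angular-momentum operator is L = -i * (r-origin) x nabla.
    """
    origin = np.asarray(origin, dtype=float)
    n = len(aos)
    L = np.zeros((3, n, n))
    # component d: eps_{d e f} (r_e - O_e) * d/dr_f
    comps = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
    for i in range(n):
        ga = aos[i]
        for j in range(n):
            gb = aos[j]
            vals = np.zeros(3)
            for ka, ca in enumerate(ga.coeffs):
                for kb, cb in enumerate(gb.coeffs):
                    a, b, tabs = _pair_tables(ga, gb, ka, kb, extra=1)
                    p = a + b
                    P = (a * ga.center + b * gb.center) / p
                    s1d = np.empty(3)
                    m1d = np.empty(3)
                    d1d = np.empty(3)
                    for d in range(3):
                        ia, jb = ga.powers[d], gb.powers[d]
                        E = tabs[d][ia, jb]
                        s1d[d] = E[0] * np.sqrt(np.pi / p)
                        e1 = E[1] if len(E) > 1 else 0.0
                        m1d[d] = (e1 + (P[d] - origin[d]) * E[0]) * np.sqrt(np.pi / p)
                        d1d[d] = _deriv_1d(tabs[d], ia, jb, b, p)
                    for d, e, f in comps:
                        vals[d] += ca * cb * (
                            m1d[e] * d1d[f] - m1d[f] * d1d[e]
                        ) * s1d[d]
            L[:, i, j] = vals
    return L


# ---------------------------------------------------------------------------
# Electron repulsion integrals
# ---------------------------------------------------------------------------

def _pair_hermite(ga: CGTO, gb: CGTO):
    """Per-primitive-pair Hermite data for a CGTO pair.

    Returns list of (p, P, coeff, Etuv) with Etuv of shape
    (la+lb+1 per dimension).
    """
    out = []
    for ka, ca in enumerate(ga.coeffs):
        for kb, cb in enumerate(gb.coeffs):
            a, b, (Ex, Ey, Ez) = _pair_tables(ga, gb, ka, kb)
            p = a + b
            P = (a * ga.center + b * gb.center) / p
            etuv = np.einsum(
                "t,u,v->tuv",
                Ex[ga.powers[0], gb.powers[0]],
                Ey[ga.powers[1], gb.powers[1]],
                Ez[ga.powers[2], gb.powers[2]],
            )
            out.append((p, P, ca * cb, etuv))
    return out


def _eri_cgto(pair_ab, pair_cd) -> float:
    val = 0.0
    for p, P, cab, E1 in pair_ab:
        for q, Q, ccd, E2 in pair_cd:
            alpha = p * q / (p + q)
            n1 = E1.shape
            n2 = E2.shape
            R = _hermite_coulomb(
                n1[0] + n2[0] - 2, n1[1] + n2[1] - 2, n1[2] + n2[2] - 2,
                alpha, P - Q,
            )
            W = np.lib.stride_tricks.sliding_window_view(R, n2)
            sgn = (-1.0) ** (
                np.add.outer(
                    np.add.outer(np.arange(n2[0]), np.arange(n2[1])),
                    np.arange(n2[2]),
                )
            )
            term = np.einsum("tuv,xyz,tuvxyz->", E1, E2 * sgn, W)
            val += cab * ccd * 2.0 * np.pi ** 2.5 / (
                p * q * np.sqrt(p + q)
            ) * term
    return val


def eri_tensor(aos: list) -> np.ndarray:
    """Full (mu nu | la si) tensor in chemists' notation, 8-fold symmetry."""
    n = len(aos)
    pairs = {}
    for i in range(n):
        for j in range(i + 1):
            pairs[(i, j)] = _pair_hermite(aos[i], aos[j])
    eri = np.zeros((n, n, n, n))
    for i in range(n):
        for j in range(i + 1):
            ij = i * (i + 1) // 2 + j
            for k in range(n):
                for l in range(k + 1):
                    kl = k * (k + 1) // 2 + l
                    if kl > ij:
                        continue
                    v = _eri_cgto(pairs[(i, j)], pairs[(k, l)])
                    for a, b in ((i, j), (j, i)):
                        for c, d in ((k, l), (l, k)):
                            eri[a, b, c, d] = v
                            eri[c, d, a, b] = v
    return eri
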