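"""Folded complex-polarization-propagator (CPP) linear-response solver.

The complex response equation over the full singles+doubles manifold,

    (M - (omega + i gamma) 1) X = B,

is folded into the p-h space through the diagonal 2p-2h block: with the
complex resolvent weights w = 1/(d - omega - i gamma) the effective folded
matrix splits into real symmetric frequency-dependent parts M'(omega) and
M''(omega) whose actions on a trial vector are the sigma' / sigma'' pairs.
The coupled real form of the complex equation is solved in an iterative
subspace of real trial vectors, with either a common subspace pooled over
all response equations or a separate subspace per frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diagnostics import SolverDiagnostics


class ConfigurationError(ValueError):
    pass


class DegeneracyError(ArithmeticError):
    pass


class IllConditionedError(RuntimeError):
    def __init__(self, message, condition=None):
        super().__init__(message)
        self.condition = condition


def freq_grid(start: float, stop: float, count: int | None = None,
              step: float | None = None) -> np.ndarray:
    """Equidistant frequency grid, endpoints inclusive."""
    if (count is None) == (step is None):
        raise ConfigurationError("specify exactly one of count or step")
    if count is not None:
        if count < 1:
            raise ConfigurationError("count must be >= 1")
        if count == 1:
            return np.array([float(start)])
        if stop <= start:
            raise ConfigurationError("stop must exceed start")
        return np.linspace(start, stop, count)
    if step <= 0:
        raise ConfigurationError("step must be positive")
    if stop <= start:
        raise ConfigurationError("stop must exceed start")
    n = int(round((stop - start) / step)) + 1
    grid = start + step * np.arange(n)
    return grid[grid <= stop + 1e-12 * max(1.0, abs(stop))]


def fold_weights(d: np.ndarray, omega: float, gamma: float,
                 floor: float = 1e-10):
    """Elementwise real/imaginary parts of 1/(d - omega - i*gamma)."""
    d = np.asarray(d, dtype=float)
    if gamma < 0.0:
        raise ConfigurationError("gamma must be non-negative")
    if gamma == 0.0 and np.min(np.abs(d - omega)) < floor:
        raise DegeneracyError(
            "undamped resolvent hit a 2p-2h pole (omega on the doubles "
            "diagonal); use gamma > 0"
        )
    den = (d - omega) ** 2 + gamma**2
    return (d - omega) / den, gamma / den


def build_sigma_pair(ws, b: np.ndarray, omega: float, gamma: float):
    """(sigma', sigma'') = (M'(omega) b, M''(omega) b).

    M'(omega) = M_ss - C_sd diag(w') C_ds and M''(omega) = C_sd diag(w'') C_ds
    fold the doubles resolvent into the singles space.
    """
    wr, wi = fold_weights(ws.doubles_diagonal(), omega, gamma)
    cds = ws.couple_ds(b)
    sig_p = ws.sigma_singles(b) - ws.couple_sd(wr * cds)
    sig_pp = ws.couple_sd(wi * cds)
    return sig_p, sig_pp


def fold_rhs(ws, b_s: np.ndarray, b_d: np.ndarray | None, omega: float,
             gamma: float, branch: int = +1) -> np.ndarray:
    """Folded complex right-hand side B_s' = B_s - C_sd diag(w) B_d.

    branch +1/-1 selects the +omega or -omega term (resolvent at
    +/-omega + i*gamma); with B_d = 0 this reduces to B_s exactly.
    """
    b_s = np.asarray(b_s)
    out = b_s.astype(complex)
    if b_d is not None and np.any(b_d):
        wr, wi = fold_weights(ws.doubles_diagonal(), branch * omega, gamma)
        b_d = np.asarray(b_d)
        out = out - ws.couple_sd(wr * b_d) - 1j * ws.couple_sd(wi * b_d)
    return out


@dataclass
class FoldedSystem:
    """One folded complex response equation."""

    label: str
    omega: float  # unsigned frequency
    gamma: float
    branch: int = +1  # +1: +omega term, -1: -omega term
    rhs_s: np.ndarray = None  # real singles RHS
    rhs_d: np.ndarray = None  # real doubles RHS (may be zero/None)
    phase: complex = 1.0 + 0.0j  # overall phase of the true (complex) RHS
    threshold: float = 1e-4  # relative residual

    def __post_init__(self):
        if self.gamma < 0 or (self.gamma == 0.0 and self.omega != 0.0):
            raise ConfigurationError(
                "gamma must be > 0 for complex solves (gamma = 0 only off "
                "resonance at omega = 0)"
            )

    @property
    def omega_signed(self) -> float:
        return self.branch * self.omega

    @property
    def freq_key(self):
        return (round(self.omega_signed, 12), round(self.gamma, 12))


@dataclass
class ResponseSolution:
    """Converged (or flagged) solution of one folded system."""

    system: FoldedSystem
    x_s: np.ndarray = None  # complex singles solution (phase included)
    x_d: np.ndarray = None  # complex reconstructed doubles part
    converged: bool = False
    n_iterations: int = 0
    residual_history: list = field(default_factory=list)

    @property
    def relative_residual(self) -> float:
        return self.residual_history[-1] if self.residual_history else np.inf


def solve_reduced(V: np.ndarray, sig_p: np.ndarray, sig_pp: np.ndarray,
                  omega_signed: float, gamma: float,
                  b_fold: np.ndarray) -> np.ndarray:
    """Solve the reduced coupled real response equation; returns complex
    reduced coefficients c such that X = V (cR + i cI)."""
    m = V.shape[1]
    if m == 0:
        raise ConfigurationError("empty trial subspace")
    S = V.T @ V
    Ep = V.T @ sig_p
    Epp = V.T @ sig_pp
    Ep = 0.5 * (Ep + Ep.T)
    Epp = 0.5 * (Epp + Epp.T)
    A = Ep - omega_signed * S
    Bm = Epp + gamma * S
    red = np.block([[A, Bm], [Bm, -A]])
    rhs = np.concatenate([V.T @ b_fold.real, -(V.T @ b_fold.imag)])
    cond = np.linalg.cond(red)
    if not np.isfinite(cond) or cond > 1e14:
        raise IllConditionedError(
            f"reduced response matrix ill-conditioned (cond ~ {cond:.2e})",
            condition=cond,
        )
    sol = np.linalg.solve(red, rhs)
    return sol[:m] + 1j * sol[m:]


class _SigmaCache:
    """Per-frequency sigma'/sigma'' columns aligned with the trial matrix."""

    def __init__(self, ws, diag: SolverDiagnostics):
        self.ws = ws
        self.diag = diag
        self.store = {}

    def get(self, V: np.ndarray, freq_key) -> tuple:
        omega_signed, gamma = freq_key
        if freq_key not in self.store:
            n = V.shape[0]
            self.store[freq_key] = (np.zeros((n, 0)), np.zeros((n, 0)))
        sp, spp = self.store[freq_key]
        have = sp.shape[1]
        if have < V.shape[1]:
            new_p, new_pp = [], []
            for col in range(have, V.shape[1]):
                p, pp = build_sigma_pair(self.ws, V[:, col], omega_signed, gamma)
                new_p.append(p)
                new_pp.append(pp)
                self.diag.sigma_pairs_computed += 1
            sp = np.column_stack([sp] + new_p)
            spp = np.column_stack([spp] + new_pp)
            self.store[freq_key] = (sp, spp)
        return sp[:, : V.shape[1]], spp[:, : V.shape[1]]


def _orthonormalize_against(V: np.ndarray, vecs, drop_tol: float = 1e-8):
    """Modified Gram-Schmidt with re-orthogonalization; returns new columns."""
    cols = [] if V is None or V.size == 0 else [V]
    added = []
    for v in vecs:
        w = np.asarray(v, dtype=float).copy()
        nrm0 = np.linalg.norm(w)
        if nrm0 == 0.0:
            continue
        w /= nrm0
        for _ in range(2):  # re-orthogonalization pass
            if cols:
                basis = np.column_stack(cols)
                w -= basis @ (basis.T @ w)
            for u in added:
                w -= u * (u @ w)
        nrm = np.linalg.norm(w)
        if nrm > drop_tol:
            w /= nrm
            added.append(w)
            if cols:
                cols = [np.column_stack(cols + [w[:, None]])]
            else:
                cols = [w[:, None]]
    return added


def reconstruct_doubles(ws, system: FoldedSystem, x_s: np.ndarray) -> np.ndarray:
    """X_d = diag(w) (B_d - C_ds X_s) at the system's signed frequency."""
    wr, wi = fold_weights(
        ws.doubles_diagonal(), system.omega_signed, system.gamma
    )
    w = wr + 1j * wi
    b_d = system.rhs_d
    cds = ws.couple_ds(x_s.real) + 1j * ws.couple_ds(x_s.imag)
    base = -cds
    if b_d is not None and np.any(b_d):
        base = base + b_d
    return w * base


def cpp_solve(ws, systems, strategy: str = "separate", max_iter: int = 100,
              pool_across_operators: bool = True):
    """Solve a set of folded complex response equations.

    Returns (list of ResponseSolution aligned with ``systems``,
    SolverDiagnostics).  strategy='common' pools one orthonormal trial set
    over all systems (by default across operators and frequencies alike;
    with pool_across_operators=False, one pooled subspace per operator
    label); 'separate' builds one subspace per (signed frequency, gamma).
    """
    if not systems:
        raise ConfigurationError("no systems to solve")
    if strategy not in ("common", "separate"):
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    diag = SolverDiagnostics()
    if strategy == "common":
        if pool_across_operators:
            groups = {"common": list(range(len(systems)))}
        else:
            groups = {}
            for k, sys_ in enumerate(systems):
                op = sys_.label.split("@")[0].rstrip("+-")
                groups.setdefault(f"common:{op}", []).append(k)
    else:
        groups = {}
        for k, sys_ in enumerate(systems):
            groups.setdefault(f"freq{sys_.freq_key}", []).append(k)

    solutions: list = [None] * len(systems)
    precond_diag = ws.singles_diagonal()

    for gname, idxs in groups.items():
        _solve_group(ws, systems, idxs, gname, solutions, diag,
                     precond_diag, max_iter)
    return solutions, diag


def _precondition(r: np.ndarray, diag0: np.ndarray, omega: float,
                  floor: float = 1e-3) -> np.ndarray:
    den = diag0 - omega
    den = np.where(np.abs(den) < floor, np.sign(den + (den == 0)) * floor, den)
    return r / den


def _solve_group(ws, systems, idxs, gname, solutions, diag, precond_diag,
                 max_iter):
    folded = {}
    for k in idxs:
        s = systems[k]
        folded[k] = fold_rhs(ws, s.rhs_s, s.rhs_d, s.omega, s.gamma, s.branch)
        solutions[k] = ResponseSolution(system=s)

    # initial trial vectors: preconditioned real/imag folded RHS
    V = None
    init = []
    for k in idxs:
        b = folded[k]
        w = systems[k].omega_signed
        init.append(_precondition(b.real, precond_diag, w))
        if np.linalg.norm(b.imag) > 0:
            init.append(_precondition(b.imag, precond_diag, w))
    new_cols = _orthonormalize_against(None, init)
    if not new_cols:
        # zero RHS: zero solutions, one trivial iteration
        for k in idxs:
            sol = solutions[k]
            sol.x_s = np.zeros(ws.n_s, dtype=complex)
            sol.x_d = np.zeros(ws.n_d, dtype=complex)
            sol.converged = True
            sol.n_iterations = 1
            sol.residual_history.append(0.0)
        return
    V = np.column_stack(new_cols)
    diag.trial_vectors += len(new_cols)
    cache = _SigmaCache(ws, diag)
    unconverged = set(idxs)
    n_new = len(new_cols)

    for it in range(1, max_iter + 1):
        diag.sigma_pairs_accounted += n_new * len(unconverged)
        residual_vecs = {}
        for k in sorted(unconverged):
            s = systems[k]
            b = folded[k]
            sp, spp = cache.get(V, s.freq_key)
            c = solve_reduced(V, sp, spp, s.omega_signed, s.gamma, b)
            x = V @ c
            mpx = sp @ c  # M'(w) X
            mppx = spp @ c  # M''(w) X
            r = (mpx - s.omega_signed * x) - 1j * (mppx + s.gamma * x) - b
            rel = np.linalg.norm(r) / max(np.linalg.norm(b), 1e-300)
            sol = solutions[k]
            sol.residual_history.append(float(rel))
            sol.n_iterations = it
            conv = rel <= s.threshold
            diag.record(
                solver="cpp", group=gname, iteration=it, system=s.label,
                residual=float(rel), subspace_dim=V.shape[1],
                new_vectors=n_new,
                sigma_pairs_computed=diag.sigma_pairs_computed,
                sigma_pairs_accounted=diag.sigma_pairs_accounted,
                converged=bool(conv),
            )
            if conv:
                sol.x_s = s.phase * x
                sol.x_d = s.phase * reconstruct_doubles(ws, s, x)
                sol.converged = True
            else:
                residual_vecs[k] = r
        unconverged -= {k for k in list(unconverged) if solutions[k].converged}
        if not unconverged:
            return
        # spawn preconditioned residual vectors
        cand = []
        for k in sorted(residual_vecs):
            w = systems[k].omega_signed
            cand.append(_precondition(residual_vecs[k].real, precond_diag, w))
            cand.append(_precondition(residual_vecs[k].imag, precond_diag, w))
        new_cols = _orthonormalize_against(V, cand)
        n_new = len(new_cols)
        if n_new == 0 or V.shape[1] >= ws.n_s:
            break  # subspace saturated; leave the rest flagged unconverged
        V = np.column_stack([V] + new_cols)
        diag.trial_vectors += n_new

    # non-convergence: store best-effort partial results, flagged
    for k in sorted(unconverged):
        s = systems[k]
        sp, spp = cache.get(V, s.freq_key)
        c = solve_reduced(V, sp, spp, s.omega_signed, s.gamma, folded[k])
        x = V @ c
        sol = solutions[k]
        sol.x_s = s.phase * x
        sol.x_d = s.phase * reconstruct_doubles(ws, s, x)
        sol.converged = False


def response_value(F_A, solution: ResponseSolution,
                   allow_unconverged: bool = False) -> complex:
    """A-dagger . X including the folded doubles reconstruction."""
    if not solution.converged and not allow_unconverged:
        raise RuntimeError(
            f"system {solution.system.label!r} not converged; pass "
            "allow_unconverged=True to override"
        )
    return complex(
        np.conj(F_A.F_s) @ solution.x_s + np.conj(F_A.F_d) @ solution.x_d
    )


# ---------------------------------------------------------------------------
# high-level drivers
# ---------------------------------------------------------------------------

def make_cpp_systems(rhs_sets, omegas, gamma: float,
                     threshold: float = 1e-4) -> list:
    """Enumerate folded systems: one per (RHS operator component, frequency,
    +/- branch).  rhs_sets is a list of TransitionMomentSet objects."""
    systems = []
    for F in rhs_sets:
        g_s, g_d = F.real_parts()
        for omega in np.atleast_1d(omegas):
            for branch in (+1, -1):
                systems.append(FoldedSystem(
                    label=f"{F.operator}.{F.component}{'+' if branch > 0 else '-'}"
                          f"@{omega:.6f}",
                    omega=float(omega), gamma=float(gamma), branch=branch,
                    rhs_s=g_s, rhs_d=g_d, phase=F.phase, threshold=threshold,
                ))
    return systems


def response_functions(ws, pairs, omegas, gamma: float,
                       strategy: str = "separate", threshold: float = 1e-4,
                       max_iter: int = 100):
    """Damped response values for (A, B) operator pairs over a grid.

    pairs: list of (F_A, F_B) TransitionMomentSet pairs.  Returns
    (values array of shape (n_pairs, n_freqs), diagnostics); each value is
    F_A^dagger X_B(+omega) + conj(F_A^dagger X_B(-omega)).
    """
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    rhs_unique = []
    rhs_index = {}
    for _, F_B in pairs:
        key = (F_B.operator, F_B.component)
        if key not in rhs_index:
            rhs_index[key] = len(rhs_unique)
            rhs_unique.append(F_B)
    systems = make_cpp_systems(rhs_unique, omegas, gamma, threshold)
    solutions, diag = cpp_solve(ws, systems, strategy=strategy,
                                max_iter=max_iter)
    # index solutions by (rhs key, branch, freq position)
    lookup = {}
    pos = 0
    for F in rhs_unique:
        for iw in range(len(omegas)):
            for branch in (+1, -1):
                lookup[(F.operator, F.component, branch, iw)] = solutions[pos]
                pos += 1
    values = np.zeros((len(pairs), len(omegas)), dtype=complex)
    for ip, (F_A, F_B) in enumerate(pairs):
        key = (F_B.operator, F_B.component)
        for iw in range(len(omegas)):
            sol_p = lookup[(key[0], key[1], +1, iw)]
            sol_m = lookup[(key[0], key[1], -1, iw)]
            values[ip, iw] = response_value(F_A, sol_p) + np.conj(
                response_value(F_A, sol_m)
            )
    return values, diag, solutions
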