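"""Folded nonlinear ADC(2) eigensolver.

Eliminating the diagonal doubles block turns the Hermitian eigenproblem into
a nonlinear one in the singles space,

    M_eff(omega) Y_s = omega Y_s,
    M_eff(omega) = M_ss + M_sd (omega - M_dd)^-1 M_ds,

solved by a reduced-space block method: Ritz pairs of the projected
M_eff(omega) provide eigenvector updates, the Newton-Raphson step on
Theta(omega) = y^T M_eff(omega) y refines the eigenvalue, and the subspace
is collapsed under controlled conditions.  Roots are processed
progressively; expansion vectors come from the residuals of the current and
the next few higher roots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cpp import _orthonormalize_against, _precondition
from .diagnostics import SolverDiagnostics


class ConfigurationError(ValueError):
    pass


class DegeneracyError(ArithmeticError):
    pass


@dataclass
class EigenState:
    """One converged folded ADC(2) root."""

    omega: float
    y_s: np.ndarray = field(repr=False)  # singles part, full vector normalized
    y_d: np.ndarray = field(repr=False)  # reconstructed doubles part
    converged: bool = False
    residual_norm: float = np.inf
    eigenvalue_error: float = np.inf
    n_iterations: int = 0


def adc1_guess(ws, n_states: int):
    """Lowest ADC(1) eigenpairs as start vectors and eigenvalue guesses."""
    if n_states < 1 or n_states > ws.n_s:
        raise ConfigurationError(
            f"n_states must be in 1..{ws.n_s} (p-h dimension), got {n_states}"
        )
    vals, vecs = np.linalg.eigh(ws.adc1_matrix())
    return vals[:n_states], vecs[:, :n_states]


def _resolvent(ws, omega: float, floor: float = 1e-8) -> np.ndarray:
    d = ws.doubles_diagonal()
    den = omega - d
    if np.min(np.abs(den)) < floor:
        k = int(np.argmin(np.abs(den)))
        raise DegeneracyError(
            f"omega = {omega:.8f} collides with 2p-2h diagonal entry {k} "
            f"({d[k]:.8f})"
        )
    return 1.0 / den


def apply_meff(ws, y: np.ndarray, omega: float) -> np.ndarray:
    """M_eff(omega) y."""
    w = _resolvent(ws, omega)
    return ws.sigma_singles(y) + ws.couple_sd(w * ws.couple_ds(y))


def theta(ws, y: np.ndarray, omega: float) -> float:
    """Theta(omega) = y^T M_eff(omega) y (y normalized)."""
    return float(y @ apply_meff(ws, y, omega))


def theta_deriv(ws, y: np.ndarray, omega: float) -> float:
    """d Theta / d omega = -y^T M_sd (omega - M_dd)^-2 M_ds y <= 0."""
    w = _resolvent(ws, omega)
    cds = ws.couple_ds(y)
    return float(-np.sum((w * cds) ** 2))


def newton_update(omega: float, th: float, thp: float,
                  floor: float = 1e-12) -> float:
    """omega_{n+1} = omega_n - (Theta - omega_n) / (Theta' - 1)."""
    den = thp - 1.0
    if abs(den) < floor:
        raise DegeneracyError("Theta'(omega) - 1 below floor; step rejected")
    return omega - (th - omega) / den


@dataclass
class SolverOptions:
    tol_residual: float = 1e-5
    tol_eigenvalue: float = 1e-6  # hartree
    max_iter: int = 200
    max_subspace: int = 200
    block_width: int = 5
    stall_window: int = 12


def solve_states(ws, n_states: int, opts: SolverOptions | None = None):
    """Solve for the lowest folded ADC(2) roots with transition-ready
    eigenvectors.

    Returns (list of EigenState sorted ascending, SolverDiagnostics).
    Stalled roots are flagged (converged=False) and the solver continues.
    """
    opts = opts or SolverOptions()
    diag = SolverDiagnostics()
    guess_vals, guess_vecs = adc1_guess(ws, n_states)

    V = np.array(guess_vecs, dtype=float)
    diag.trial_vectors += V.shape[1]
    refs = [guess_vecs[:, k].copy() for k in range(n_states)]
    omegas = list(guess_vals)
    states: list = [None] * n_states
    precond_diag = ws.singles_diagonal()
    active = 0
    stall_hist: dict = {}

    for it in range(1, opts.max_iter + 1):
        if active >= n_states:
            break
        omega_cur = omegas[active]
        # project M_eff(omega_cur) into the subspace
        AV = np.column_stack([
            apply_meff(ws, V[:, k], omega_cur) for k in range(V.shape[1])
        ])
        diag.sigma_pairs_computed += V.shape[1]
        H = V.T @ AV
        H = 0.5 * (H + H.T)
        rvals, rvecs = np.linalg.eigh(H)
        ritz = V @ rvecs

        # assign Ritz vectors to roots by maximal overlap with references
        assign = {}
        used = set()
        for root in range(active, min(n_states, active + opts.block_width)):
            ov = np.abs(refs[root] @ ritz)
            for col in used:
                ov[col] = -1.0
            col = int(np.argmax(ov))
            used.add(col)
            assign[root] = col
            refs[root] = ritz[:, col].copy()
            omegas[root] = float(rvals[col])

        # Newton-Raphson refinement for the current root
        y = refs[active]
        th = theta(ws, y, omega_cur)
        thp = theta_deriv(ws, y, omega_cur)
        omega_new = newton_update(omega_cur, th, thp)
        eig_err = abs(omega_new - omega_cur)
        omegas[active] = omega_new

        # residuals for the active block, expansion candidates
        cand = []
        res_active = None
        for root in range(active, min(n_states, active + opts.block_width)):
            yv = refs[root]
            w_root = omega_new if root == active else omegas[root]
            try:
                res = apply_meff(ws, yv, w_root) - w_root * yv
            except DegeneracyError:
                continue
            if root == active:
                res_active = res
            cand.append(_precondition(res, precond_diag, w_root))
        res_norm = np.linalg.norm(res_active) if res_active is not None else np.inf
        diag.record(
            solver="eigen", group="states", iteration=it,
            system=f"root{active}", residual=float(res_norm),
            subspace_dim=V.shape[1], new_vectors=0,
            sigma_pairs_computed=diag.sigma_pairs_computed,
            sigma_pairs_accounted=diag.sigma_pairs_accounted,
            converged=bool(
                res_norm <= opts.tol_residual
                and eig_err <= opts.tol_eigenvalue
            ),
        )

        hist = stall_hist.setdefault(active, [])
        hist.append(res_norm)
        stalled = (
            len(hist) > opts.stall_window
            and min(hist[-opts.stall_window:])
            > 0.9 * min(hist[: -opts.stall_window] or [np.inf])
        )

        if (res_norm <= opts.tol_residual and eig_err <= opts.tol_eigenvalue) \
                or stalled:
            y = refs[active]
            states[active] = _finalize_state(
                ws, y, omega_new, res_norm, eig_err, it,
                converged=not stalled,
            )
            active += 1
            continue

        new_cols = _orthonormalize_against(V, cand)
        collapse = (
            V.shape[1] + len(new_cols) > opts.max_subspace or not new_cols
        )
        if collapse:
            keep = [
                states[k].y_s / np.linalg.norm(states[k].y_s)
                for k in range(active) if states[k] is not None
            ]
            keep += [
                refs[r]
                for r in range(active, min(n_states, active + opts.block_width))
            ]
            cols = _orthonormalize_against(None, keep)
            V = np.column_stack(cols)
            new_cols = _orthonormalize_against(V, cand)
            if new_cols:
                V = np.column_stack([V] + new_cols)
                diag.trial_vectors += len(new_cols)
        else:
            V = np.column_stack([V] + new_cols)
            diag.trial_vectors += len(new_cols)

    # any remaining roots: flagged with best current data
    for root in range(active, n_states):
        y = refs[root]
        y = y / np.linalg.norm(y)
        try:
            res = apply_meff(ws, y, omegas[root]) - omegas[root] * y
            rn = float(np.linalg.norm(res))
        except DegeneracyError:
            rn = np.inf
        states[root] = _finalize_state(
            ws, y, omegas[root], rn, np.inf, opts.max_iter, converged=False
        )

    order = np.argsort([s.omega for s in states])
    return [states[k] for k in order], diag


def _finalize_state(ws, y_s, omega, res_norm, eig_err, n_iter, converged):
    """Reconstruct the doubles part and normalize the full vector."""
    y_s = y_s / np.linalg.norm(y_s)
    w = _resolvent(ws, omega)
    y_d = w * ws.couple_ds(y_s)
    nrm = np.sqrt(y_s @ y_s + y_d @ y_d)
    return EigenState(
        omega=float(omega),
        y_s=y_s / nrm,
        y_d=y_d / nrm,
        converged=converged,
        residual_norm=float(res_norm),
        eigenvalue_error=float(eig_err),
        n_iterations=n_iter,
    )
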