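"""Synthetic ADC(2)-structured model problems.

Generates block matrices with the folded structure (dense symmetric singles
block, low-rank-free coupling to a strictly diagonal doubles block) so the
CPP and eigensolvers are testable without any quantum-chemistry backend.
The spectral density of the singles block and the coupling norm are the two
knobs that matter for solver convergence studies: a higher density of states
in the probed window drives up iteration counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adc import DenseAdcMatrix, OracleCapError
from .constants import HARTREE_TO_EV


@dataclass
class ModelProblem:
    """Synthetic folded-structure problem; implements the same contraction
    protocol as :class:`adcfold.adc.AdcWorkspace`."""

    M_ss: np.ndarray = field(repr=False)
    M_sd: np.ndarray = field(repr=False)  # (n_s, n_d)
    d: np.ndarray = field(repr=False)  # doubles diagonal
    rhs: np.ndarray = field(repr=False)  # (n_rhs, n_s)
    seed: int = 0
    params: dict = field(default_factory=dict)

    @property
    def n_s(self) -> int:
        return self.M_ss.shape[0]

    @property
    def n_d(self) -> int:
        return len(self.d)

    def sigma_singles(self, b):
        return self.M_ss @ b

    def couple_ds(self, b):
        return self.M_sd.T @ b

    def couple_sd(self, v):
        return self.M_sd @ v

    def doubles_diagonal(self):
        return self.d

    def singles_diagonal(self):
        return np.diag(self.M_ss).copy()

    def adc1_matrix(self):
        return self.M_ss

    def assemble_dense(self, cap: int = 5000) -> DenseAdcMatrix:
        dim = self.n_s + self.n_d
        if dim > cap:
            raise OracleCapError(f"dense dimension {dim} exceeds cap {cap}")
        M = np.zeros((dim, dim))
        M[: self.n_s, : self.n_s] = self.M_ss
        M[: self.n_s, self.n_s:] = self.M_sd
        M[self.n_s:, : self.n_s] = self.M_sd.T
        M[self.n_s:, self.n_s:] = np.diag(self.d)
        return DenseAdcMatrix(matrix=M, n_s=self.n_s, n_d=self.n_d)


def generate(
    n_s: int,
    n_d: int,
    dos: float = 2.0,
    coupling: float = 0.1,
    seed: int = 0,
    n_rhs: int = 1,
    singles_floor: float = 1.0,
    doubles_gap: float = 0.5,
    doubles_spread: float = 2.0,
    mixing: float = 0.02,
) -> ModelProblem:
    """Reproducible model problem.

    dos controls the eigenvalue clustering of the singles block: its
    spectrum is drawn over a window of width n_s / dos (states per unit
    energy), so larger dos means denser spectra.  ``mixing`` sets how far
    the singles block departs from diagonality (real ADC singles blocks are
    diagonally dominant, which is what makes diagonal preconditioning
    work).  The doubles diagonal is drawn strictly above the singles
    spectral range (by ``doubles_gap``) so the folding denominators in a
    typical probing window behave like the real method; lower it
    deliberately for stress tests.
    """
    if n_s < 1 or n_d < 1:
        raise ValueError("n_s and n_d must be >= 1")
    rng = np.random.default_rng(seed)
    width = n_s / dos
    lam = np.sort(rng.uniform(singles_floor, singles_floor + width, n_s))
    if n_s > 1:
        q, _ = np.linalg.qr(
            np.eye(n_s) + mixing * rng.normal(size=(n_s, n_s))
        )
    else:
        q = np.eye(1)
    M_ss = q @ np.diag(lam) @ q.T
    M_ss = 0.5 * (M_ss + M_ss.T)
    M_sd = coupling * rng.normal(size=(n_s, n_d)) / np.sqrt(n_d)
    top = singles_floor + width
    d = np.sort(rng.uniform(top + doubles_gap, top + doubles_gap
                            + doubles_spread, n_d))
    rhs = rng.normal(size=(n_rhs, n_s))
    return ModelProblem(
        M_ss=M_ss, M_sd=M_sd, d=d, rhs=rhs, seed=seed,
        params=dict(n_s=n_s, n_d=n_d, dos=dos, coupling=coupling,
                    singles_floor=singles_floor, doubles_gap=doubles_gap,
                    doubles_spread=doubles_spread),
    )


def scalar_root(a: float, d: float, c: float, branch: str = "lower") -> float:
    """Closed-form root of the n_s = n_d = 1 folded problem
    a + c^2/(omega - d) = omega (the quadratic formula)."""
    disc = np.sqrt((a - d) ** 2 + 4.0 * c * c)
    if branch == "lower":
        return 0.5 * (a + d - disc)
    return 0.5 * (a + d + disc)


def dos_estimate(problem: ModelProblem, window, broadening: float) -> float:
    """Gaussian-broadened density of states (states per eV) in a window.

    window is (lo, hi) in the problem's energy units (treated as hartree
    for the per-eV normalization).
    """
    import warnings
    from scipy.stats import norm

    lo, hi = window
    if hi <= lo:
        warnings.warn("empty DOS window; returning 0")
        return 0.0
    evals = problem.assemble_dense().eigenstates()[0]
    weight = norm.cdf(hi, loc=evals, scale=broadening) - norm.cdf(
        lo, loc=evals, scale=broadening
    )
    width_ev = (hi - lo) * HARTREE_TO_EV
    return float(np.sum(weight)) / width_ev


def to_hdf5(problem: ModelProblem, path) -> None:
    """Dump a model problem for regression suites."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("M_ss", data=problem.M_ss)
        fh.create_dataset("M_sd", data=problem.M_sd)
        fh.create_dataset("d", data=problem.d)
        fh.create_dataset("rhs", data=problem.rhs)
        fh.attrs["seed"] = problem.seed
        for k, v in problem.params.items():
            fh.attrs[k] = v


def from_hdf5(path) -> ModelProblem:
    import h5py

    with h5py.File(path, "r") as fh:
        return ModelProblem(
            M_ss=fh["M_ss"][()], M_sd=fh["M_sd"][()], d=fh["d"][()],
            rhs=fh["rhs"][()], seed=int(fh.attrs["seed"]),
            params={k: fh.attrs[k] for k in fh.attrs if k != "seed"},
        )
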