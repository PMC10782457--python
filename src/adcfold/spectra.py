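"""High-level spectrum drivers tying solvers and properties together."""

from __future__ import annotations

import numpy as np

from .adc import AdcWorkspace
from .cpp import response_functions
from .eigensolver import SolverOptions, solve_states
from .properties import (
    SpectrumResult,
    TransitionMomentBuilder,
    absorption_cross_section,
    cd_spectrum,
    lorentzian_broadening,
    oscillator_strength,
    rotatory_strength,
    transition_amplitude,
)


def uvvis_cpp(ws: AdcWorkspace, builder: TransitionMomentBuilder,
              omegas, gamma: float, strategy: str = "separate",
              threshold: float = 1e-4, max_iter: int = 100) -> SpectrumResult:
    """Absorption cross section sigma(omega) from the damped dipole response."""
    dips = builder.build_components("dipole")
    pairs = [(F, F) for F in dips]
    vals, diag, _ = response_functions(
        ws, pairs, omegas, gamma, strategy=strategy, threshold=threshold,
        max_iter=max_iter,
    )
    im_alpha_iso = vals.imag.mean(axis=0)
    sigma = absorption_cross_section(im_alpha_iso, omegas)
    return SpectrumResult(np.atleast_1d(np.asarray(omegas, float)),
                          sigma_au=sigma, provenance="cpp", diagnostics=diag)


def ecd_cpp(ws: AdcWorkspace, builder: TransitionMomentBuilder,
            omegas, gamma: float, strategy: str = "separate",
            threshold: float = 1e-4, max_iter: int = 100) -> SpectrumResult:
    """Delta-epsilon(omega) from the damped mixed linear-momentum /
    magnetic-dipole (velocity-gauge) response."""
    ps = builder.build_components("linmom")
    ms = builder.build_components("magdip")
    pairs = list(zip(ps, ms))
    vals, diag, _ = response_functions(
        ws, pairs, omegas, gamma, strategy=strategy, threshold=threshold,
        max_iter=max_iter,
    )
    de = cd_spectrum(vals.imag.sum(axis=0), omegas)
    return SpectrumResult(np.atleast_1d(np.asarray(omegas, float)),
                          delta_epsilon=de, provenance="cpp",
                          diagnostics=diag)


def excited_states_table(ws: AdcWorkspace, builder: TransitionMomentBuilder,
                         n_states: int, opts: SolverOptions | None = None,
                         with_rotatory: bool = True):
    """Solve the folded eigenproblem and attach transition properties.

    Returns (states, rows, diagnostics) where rows are dicts with state
    index, energy (au and eV), oscillator strength and rotatory strengths.
    """
    from .constants import HARTREE_TO_EV

    states, diag = solve_states(ws, n_states, opts)
    dips = builder.build_components("dipole")
    ps = builder.build_components("linmom") if with_rotatory else None
    ms = builder.build_components("magdip") if with_rotatory else None
    rows = []
    for k, st in enumerate(states):
        xd = [transition_amplitude(F, st, allow_unconverged=True)
              for F in dips]
        row = {
            "state": k + 1,
            "energy_au": st.omega,
            "energy_ev": st.omega * HARTREE_TO_EV,
            "converged": st.converged,
            "osc_strength": oscillator_strength(st.omega, xd),
        }
        if with_rotatory:
            xp = [transition_amplitude(F, st, allow_unconverged=True)
                  for F in ps]
            xm = [transition_amplitude(F, st, allow_unconverged=True)
                  for F in ms]
            row["rot_strength_velocity"] = rotatory_strength(
                st.omega, xp, xm, gauge="velocity"
            )
            row["rot_strength_length"] = rotatory_strength(
                st.omega, xd, xm, gauge="length"
            )
        rows.append(row)
    return states, rows, diag


def uvvis_sticks(rows, gamma: float, grid) -> SpectrumResult:
    """Lorentzian-broadened stick spectrum from an excited-state table."""
    sticks = [(r["energy_au"], r["osc_strength"]) for r in rows]
    return lorentzian_broadening(sticks, gamma, np.asarray(grid, float),
                                 kind="absorption")


def ecd_sticks(rows, gamma: float, grid,
               gauge: str = "velocity") -> SpectrumResult:
    key = ("rot_strength_velocity" if gauge == "velocity"
           else "rot_strength_length")
    sticks = [(r["energy_au"], r[key]) for r in rows]
    return lorentzian_broadening(sticks, gamma, np.asarray(grid, float),
                                 kind="cd")
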