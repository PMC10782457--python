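"""Transition properties and spectral observables.

Modified transition moments through second order in the p-h block and first
order in the 2p-2h block; transition amplitudes, oscillator and rotatory
strengths; the absorption cross section sigma(omega) and the circular
dichroism Delta-epsilon(omega); Lorentzian stick broadening and unit
conversions.

Operator conventions (atomic units, real orbitals): the electric dipole MO
matrix is real symmetric, linear momentum and magnetic dipole are purely
imaginary antisymmetric; modified transition moments are therefore real or
purely imaginary vectors and all property formulas are written for complex
amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adc import AdcWorkspace
from .constants import (
    HARTREE_TO_CM1,
    HARTREE_TO_EV,
    SPEED_OF_LIGHT_AU,
    convert_units,
)

#: rotatory strength, atomic units -> 1e-40 erg cm^3 (cgs)
ROTATORY_AU_TO_CGS40 = 235.7220
#: integrated-CD conversion constant in R[1e-40 cgs] = 22.97 int dE de/E
CD_INTEGRAL_CONST = 22.97


@dataclass
class TransitionMomentSet:
    """Modified transition moments of one operator component.

    F_s carries the zeroth-, first- and all thirteen second-order terms of
    the p-h block; F_d the first-order 2p-2h block.
    """

    operator: str
    component: str | int
    F_s: np.ndarray = field(repr=False)  # complex, length n_s
    F_d: np.ndarray = field(repr=False)  # complex, length n_d
    gauge_origin: np.ndarray | None = None

    @property
    def phase(self) -> complex:
        """1 for real vectors, 1j for purely imaginary ones."""
        if np.max(np.abs(self.F_s.imag)) <= 1e-14 * max(
            1.0, np.max(np.abs(self.F_s.real))
        ):
            return 1.0 + 0.0j
        return 1j

    def real_parts(self):
        """(G_s, G_d) real vectors with F = phase * G."""
        ph = self.phase
        return (self.F_s / ph).real, (self.F_d / ph).real


class TransitionMomentBuilder:
    """Builds modified transition moments, reusing the operator-independent
    second-order intermediates across operators and components.

    The expensive intermediate is the second-order doubles amplitude
    td2 = (ladder_vv + ladder_oo - P(ij)P(ab) ring) / D; its ladder_vv part
    contains the <vv||vv> integrals whose doubly nested occupied/virtual
    loop structure dominates the formal scaling.
    """

    def __init__(self, ws: AdcWorkspace):
        self.ws = ws
        ints, t2 = ws.ints, ws.amps.t2
        eo, ev = ws.e_occ, ws.e_virt
        self.t2 = t2
        self.rho_oo = 0.5 * np.einsum("ikab,jkab->ij", t2, t2, optimize=True)
        self.rho_vv = 0.5 * np.einsum("ijac,ijbc->ab", t2, t2, optimize=True)
        D = (
            eo[:, None, None, None] + eo[None, :, None, None]
            - ev[None, None, :, None] - ev[None, None, None, :]
        )
        lvv = 0.5 * np.einsum(
            "abcd,ijcd->ijab", ints.block("vvvv"), t2, optimize=True
        )
        loo = 0.5 * np.einsum(
            "klij,klab->ijab", ints.block("oooo"), t2, optimize=True
        )
        ring = np.einsum(
            "kbjc,ikac->ijab", ints.block("ovov"), t2, optimize=True
        )
        # P(ij)P(ab)-antisymmetrized ring
        pring = (
            ring - ring.transpose(1, 0, 2, 3)
            - ring.transpose(0, 1, 3, 2) + ring.transpose(1, 0, 3, 2)
        )
        self.td2_lvv = lvv / D
        self.td2_loo = loo / D
        self.td2_ring = -pring / D
        self.td2 = self.td2_lvv + self.td2_loo + self.td2_ring
        dia = eo[:, None] - ev[None, :]
        self.s2a = 0.5 * np.einsum(
            "ajbc,ijbc->ia", ints.block("vovv"), t2, optimize=True
        ) / dia
        self.s2b = -0.5 * np.einsum(
            "jkib,jkab->ia", ints.block("ooov"), t2, optimize=True
        ) / dia
        self.s2 = self.s2a + self.s2b

    # ------------------------------------------------------------------

    def second_order_terms(self, d: np.ndarray) -> dict:
        """The 13 second-order p-h terms for a spin-orbital operator matrix.

        Returned in a fixed order; their sum is the second-order correction.
        The 7 terms built from t2-quadratic or second-order-amplitude
        contractions carry the doubly nested (o,o)/(v,v) loop structure; the
        ladder_vv entry is the <vv||vv> class.
        """
        no = self.ws.n_occ
        d_oo, d_ov = d[:no, :no], d[:no, no:]
        d_vo, d_vv = d[no:, :no], d[no:, no:]
        t2 = self.t2
        terms = {
            "rho_oo": -0.5 * np.einsum("ij,aj->ia", self.rho_oo, d_vo),
            "rho_vv": -0.5 * np.einsum("bi,ba->ia", d_vo, self.rho_vv),
            "tt_chain": 0.5 * np.einsum(
                "ijab,jkbc,ck->ia", t2, t2, d_vo, optimize=True
            ),
            "ladder_vv": np.einsum("ijab,jb->ia", self.td2_lvv, d_ov),
            "ladder_oo": np.einsum("ijab,jb->ia", self.td2_loo, d_ov),
            "ring_1": None,  # filled below from the four ring permutations
            "ring_2": None,
            "ring_3": None,
            "ring_4": None,
            "s2_vv_a": np.einsum("ab,ib->ia", d_vv, self.s2a),
            "s2_vv_b": np.einsum("ab,ib->ia", d_vv, self.s2b),
            "s2_oo_a": -np.einsum("ji,ja->ia", d_oo, self.s2a),
            "s2_oo_b": -np.einsum("ji,ja->ia", d_oo, self.s2b),
        }
        ints = self.ws.ints
        eo, ev = self.ws.e_occ, self.ws.e_virt
        D = (
            eo[:, None, None, None] + eo[None, :, None, None]
            - ev[None, None, :, None] - ev[None, None, None, :]
        )
        ring = np.einsum(
            "kbjc,ikac->ijab", ints.block("ovov"), t2, optimize=True
        )
        perms = {
            "ring_1": -ring,
            "ring_2": ring.transpose(1, 0, 2, 3),
            "ring_3": ring.transpose(0, 1, 3, 2),
            "ring_4": -ring.transpose(1, 0, 3, 2),
        }
        for key, arr in perms.items():
            terms[key] = np.einsum("ijab,jb->ia", arr / D, d_ov)
        return terms

    def build(self, operator: str, component) -> TransitionMomentSet:
        """Modified transition moments for one operator component."""
        ws = self.ws
        d = ws.ints.operator_so(operator, component)
        no = ws.n_occ
        d_ov, d_vo = d[:no, no:], d[no:, :no]
        d_oo, d_vv = d[:no, :no], d[no:, no:]
        t2 = self.t2
        # order 0 and 1
        F = d_vo.T.astype(complex).copy()
        F += np.einsum("ijab,jb->ia", t2, d_ov, optimize=True)
        # order 2
        F += -0.5 * np.einsum("ij,aj->ia", self.rho_oo, d_vo)
        F += -0.5 * np.einsum("bi,ba->ia", d_vo, self.rho_vv)
        F += 0.5 * np.einsum("ijab,jkbc,ck->ia", t2, t2, d_vo, optimize=True)
        F += np.einsum("ijab,jb->ia", self.td2, d_ov, optimize=True)
        F += np.einsum("ab,ib->ia", d_vv, self.s2)
        F += -np.einsum("ji,ja->ia", d_oo, self.s2)
        # doubles block, first order
        x = np.einsum("ac,ijcb->ijab", d_vv, t2, optimize=True)
        x = x - x.transpose(0, 1, 3, 2)
        y = np.einsum("ki,kjab->ijab", d_oo, t2, optimize=True)
        y = y - y.transpose(1, 0, 2, 3)
        F_d = ws.full_to_doubles(x - y)
        return TransitionMomentSet(
            operator=operator,
            component=component,
            F_s=F.reshape(-1),
            F_d=F_d,
            gauge_origin=ws.ints.gauge_origin
            if hasattr(ws.ints, "gauge_origin") else None,
        )

    def build_components(self, operator: str, components=("x", "y", "z")):
        """Batch over components; intermediates are shared by construction."""
        return [self.build(operator, c) for c in components]


# ---------------------------------------------------------------------------
# amplitudes and strengths
# ---------------------------------------------------------------------------

class UnconvergedStateError(RuntimeError):
    pass


def transition_amplitude(F: TransitionMomentSet, state, allow_unconverged=False):
    """x_f = F_s^T Y_s + F_d^T Y_d for one eigenstate."""
    if not getattr(state, "converged", True) and not allow_unconverged:
        raise UnconvergedStateError(
            "refusing amplitudes of an unconverged state (override explicitly)"
        )
    return complex(F.F_s @ state.y_s + F.F_d @ state.y_d)


def oscillator_strength(omega: float, dipole_amplitudes) -> float:
    """f = (2/3) omega sum_alpha |x(mu_alpha)|^2 (length gauge, au)."""
    return (2.0 / 3.0) * omega * float(
        sum(abs(x) ** 2 for x in dipole_amplitudes)
    )


def rotatory_strength(
    omega: float, electric_amplitudes, magnetic_amplitudes, gauge: str = "velocity"
) -> float:
    """Rotatory strength in au.

    velocity gauge: electric amplitudes are the linear-momentum ones,
    R = -(1/omega) Re sum_alpha x(p_a) conj(x(m_a));
    length gauge: electric amplitudes are dipole ones,
    R = Im sum_alpha x(mu_a) conj(x(m_a)).
    """
    prod = sum(
        xe * np.conj(xm)
        for xe, xm in zip(electric_amplitudes, magnetic_amplitudes)
    )
    if gauge == "velocity":
        return float(-prod.real / omega)
    if gauge == "length":
        return float(prod.imag)
    raise ValueError(f"unknown gauge {gauge!r} (velocity|length)")


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumResult:
    """Frequency grid with sigma(omega) and/or Delta-epsilon(omega)."""

    omega_au: np.ndarray
    sigma_au: np.ndarray | None = None
    delta_epsilon: np.ndarray | None = None  # L mol^-1 cm^-1
    provenance: str = "cpp"
    diagnostics: object = None

    @property
    def omega_ev(self) -> np.ndarray:
        return self.omega_au * HARTREE_TO_EV


def absorption_cross_section(imag_alpha_iso: np.ndarray, omega: np.ndarray):
    """sigma(omega) = (4 pi omega / c) Im alpha_iso(omega), atomic units."""
    omega = np.asarray(omega, dtype=float)
    imag_alpha_iso = np.asarray(imag_alpha_iso, dtype=float)
    if omega.shape != imag_alpha_iso.shape:
        raise ValueError("frequency grid and response grid differ in shape")
    return 4.0 * np.pi * omega / SPEED_OF_LIGHT_AU * imag_alpha_iso


def cd_spectrum(imag_pm_response: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Delta-epsilon(omega) in L mol^-1 cm^-1 from the damped mixed
    linear-momentum/magnetic-dipole response.

    imag_pm_response is Im sum_alpha V_alpha(omega) with
    V = sum_n [conj(x(p)) x(m) / (w_n - w - i g)] + conj branch; since
    R_n^velocity = -(1/w_n) Re sum_alpha x(p) conj(x(m)), a pole carries
    -w_n * R_n * Lorentzian (au), which is converted with the standard
    rotatory-strength and integrated-CD constants so that a positive R gives
    a positive Delta-epsilon band.
    """
    omega = np.asarray(omega, dtype=float)
    imag_pm_response = np.asarray(imag_pm_response, dtype=float)
    if omega.shape != imag_pm_response.shape:
        raise ValueError("frequency grid and response grid differ in shape")
    return (
        -ROTATORY_AU_TO_CGS40 / (CD_INTEGRAL_CONST * np.pi) * imag_pm_response
    )


def lorentzian_broadening(
    sticks, gamma: float, grid: np.ndarray, kind: str = "absorption"
) -> SpectrumResult:
    """Broaden (energy, strength) sticks with normalized Lorentzians.

    kind='absorption': sticks are (omega_f, oscillator strength f) and the
    result is sigma(omega) in au, scaled to the same units as the CPP path.
    kind='cd': sticks are (omega_f, rotatory strength R in au) and the result
    is Delta-epsilon(omega) in L mol^-1 cm^-1.
    """
    import warnings

    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    sticks = list(sticks)
    if not sticks:
        warnings.warn("empty stick list; returning a zero spectrum")
    for omega_f, strength in sticks:
        line = (gamma / np.pi) / ((grid - omega_f) ** 2 + gamma**2)
        if kind == "absorption":
            out += 2.0 * np.pi**2 / SPEED_OF_LIGHT_AU * strength * line
        elif kind == "cd":
            out += (
                ROTATORY_AU_TO_CGS40 / CD_INTEGRAL_CONST
                * omega_f * strength * line
            )
        else:
            raise ValueError(f"unknown kind {kind!r}")
    if kind == "absorption":
        return SpectrumResult(grid, sigma_au=out, provenance="lorentzian")
    return SpectrumResult(grid, delta_epsilon=out, provenance="lorentzian")


__all__ = [
    "TransitionMomentSet",
    "TransitionMomentBuilder",
    "transition_amplitude",
    "oscillator_strength",
    "rotatory_strength",
    "SpectrumResult",
    "absorption_cross_section",
    "cd_spectrum",
    "lorentzian_broadening",
    "convert_units",
    "HARTREE_TO_CM1",
]
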