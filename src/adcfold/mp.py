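"""Moller-Plesset ground state: first-order doubles amplitudes and MP2 energy."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .moints import MOIntegralSet


class DegeneracyError(ArithmeticError):
    """Raised when an orbital-energy denominator falls below the floor."""


@dataclass
class Amplitudes:
    """First-order doubles amplitudes t_{ijab} (spin orbitals) and the MP2
    correlation energy."""

    t2: np.ndarray = field(repr=False)  # (occ, occ, virt, virt)
    mp2_energy: float = 0.0


def t2_amplitudes(ints: MOIntegralSet, denom_floor: float = 1e-8) -> Amplitudes:
    """t_{ijab} = <ij||ab> / (e_i + e_j - e_a - e_b); E_MP2 = 1/4 sum <ij||ab> t."""
    eps = ints.eps_so
    no = ints.n_occ
    e_occ = eps[:no]
    e_virt = eps[no:]
    denom = (
        e_occ[:, None, None, None]
        + e_occ[None, :, None, None]
        - e_virt[None, None, :, None]
        - e_virt[None, None, None, :]
    )
    small = np.abs(denom) < denom_floor
    oovv = ints.block("oovv")
    if np.any(small & (np.abs(oovv) > 0)):
        i, j, a, b = np.argwhere(small & (np.abs(oovv) > 0))[0]
        raise DegeneracyError(
            f"orbital-energy denominator below {denom_floor:g} for "
            f"(i,j,a,b)=({i},{j},{a + no},{b + no})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(small, 0.0, oovv / denom)
    e_mp2 = 0.25 * float(np.sum(oovv * t2))
    return Amplitudes(t2=t2, mp2_energy=e_mp2)
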