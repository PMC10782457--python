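"""Closed-form s-type Gaussian integrals (textbook two-center expressions).

Independent of the package's McMurchie-Davidson machinery: only elementary
functions and erf enter.  Higher angular momenta are reached in the tests by
differentiating these closed forms with respect to the Gaussian centers
(central finite differences), since an unnormalized p-type primitive is
d/dA of an s-type primitive divided by 2*alpha.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf


def boys0(t: float) -> float:
    if t < 1e-12:
        return 1.0 - t / 3.0
    return 0.5 * np.sqrt(np.pi / t) * erf(np.sqrt(t)) / np.sqrt(1.0)


def overlap_ss(a, A, b, B) -> float:
    """<s_A | s_B> for unnormalized primitives exp(-a|r-A|^2)."""
    A, B = np.asarray(A, float), np.asarray(B, float)
    p = a + b
    ab2 = float(np.sum((A - B) ** 2))
    return (np.pi / p) ** 1.5 * np.exp(-a * b / p * ab2)


def kinetic_ss(a, A, b, B) -> float:
    A, B = np.asarray(A, float), np.asarray(B, float)
    p = a + b
    mu = a * b / p
    ab2 = float(np.sum((A - B) ** 2))
    return mu * (3.0 - 2.0 * mu * ab2) * (np.pi / p) ** 1.5 * np.exp(-mu * ab2)


def nuclear_ss(a, A, b, B, C) -> float:
    """<s_A | 1/|r-C| | s_B> (positive; multiply by -Z for attraction)."""
    A, B, C = (np.asarray(x, float) for x in (A, B, C))
    p = a + b
    ab2 = float(np.sum((A - B) ** 2))
    P = (a * A + b * B) / p
    pc2 = float(np.sum((P - C) ** 2))
    return 2.0 * np.pi / p * np.exp(-a * b / p * ab2) * boys0(p * pc2)


def eri_ssss(a, A, b, B, c, C, d, D) -> float:
    """(s_A s_B | s_C s_D), chemists' notation, unnormalized primitives."""
    A, B, C, D = (np.asarray(x, float) for x in (A, B, C, D))
    p = a + b
    q = c + d
    P = (a * A + b * B) / p
    Q = (c * C + d * D) / q
    ab2 = float(np.sum((A - B) ** 2))
    cd2 = float(np.sum((C - D) ** 2))
    pq2 = float(np.sum((P - Q) ** 2))
    pref = 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
    return pref * np.exp(-a * b / p * ab2 - c * d / q * cd2) * boys0(
        p * q / (p + q) * pq2
    )


def central_diff(f, x0: np.ndarray, direction: int, h: float = 1e-4) -> float:
    """d f / d x0[direction] by 4th-order central differences."""
    x0 = np.asarray(x0, float)

    def at(step):
        x = x0.copy()
        x[direction] += step
        return f(x)

    return (at(-2 * h) - 8 * at(-h) + 8 * at(h) - at(2 * h)) / (12 * h)
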