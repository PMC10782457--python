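"""Transition-moment and spectral-observable tests, including the
naive-loop oracle for every second-order term and the CPP/SOS closure."""

from types import SimpleNamespace

import numpy as np
import pytest

from adcfold import cpp
from adcfold.adc import AdcWorkspace
from adcfold.constants import UnitError, convert_units
from adcfold.models import generate
from adcfold.moints import RawSpinOrbitalIntegrals
from adcfold.mp import t2_amplitudes
from adcfold.properties import (
    SPEED_OF_LIGHT_AU,
    TransitionMomentBuilder,
    absorption_cross_section,
    lorentzian_broadening,
    oscillator_strength,
    rotatory_strength,
    transition_amplitude,
)
from adcfold.spectra import ecd_cpp, excited_states_table, uvvis_cpp

GAMMA = convert_units(1000.0, "cm-1", "hartree")


# -- naive-loop oracle for the 13 second-order terms ------------------------

def naive_second_order_terms(ws, d):
    """Plain nested-loop evaluation of every second-order p-h term."""
    no, nv = ws.n_occ, ws.n_virt
    t2 = ws.amps.t2
    eps_o, eps_v = ws.e_occ, ws.e_virt
    blk = ws.ints.block
    d_oo, d_ov = d[:no, :no], d[:no, no:]
    d_vo, d_vv = d[no:, :no], d[no:, no:]
    O, V = range(no), range(nv)

    rho_oo = np.zeros((no, no))
    for i in O:
        for j in O:
            rho_oo[i, j] = 0.5 * sum(
                t2[i, k, a, b] * t2[j, k, a, b]
                for k in O for a in V for b in V)
    rho_vv = np.zeros((nv, nv))
    for a in V:
        for b in V:
            rho_vv[a, b] = 0.5 * sum(
                t2[i, j, a, c] * t2[i, j, b, c]
                for i in O for j in O for c in V)

    def denom(i, j, a, b):
        return eps_o[i] + eps_o[j] - eps_v[a] - eps_v[b]

    vvvv, oooo, ovov = blk("vvvv"), blk("oooo"), blk("ovov")
    vovv, ooov = blk("vovv"), blk("ooov")

    def lvv(i, j, a, b):
        return 0.5 * sum(vvvv[a, b, c, dd] * t2[i, j, c, dd]
                         for c in V for dd in V) / denom(i, j, a, b)

    def loo(i, j, a, b):
        return 0.5 * sum(oooo[k, l, i, j] * t2[k, l, a, b]
                         for k in O for l in O) / denom(i, j, a, b)

    def ring(i, j, a, b):
        return sum(ovov[k, b, j, c] * t2[i, k, a, c]
                   for k in O for c in V)

    s2a = np.zeros((no, nv))
    s2b = np.zeros((no, nv))
    for i in O:
        for a in V:
            s2a[i, a] = 0.5 * sum(
                vovv[a, j, b, c] * t2[i, j, b, c]
                for j in O for b in V for c in V) / (eps_o[i] - eps_v[a])
            s2b[i, a] = -0.5 * sum(
                ooov[j, k, i, b] * t2[j, k, a, b]
                for j in O for k in O for b in V) / (eps_o[i] - eps_v[a])

    terms = {k: np.zeros((no, nv), dtype=complex) for k in (
        "rho_oo", "rho_vv", "tt_chain", "ladder_vv", "ladder_oo",
        "ring_1", "ring_2", "ring_3", "ring_4",
        "s2_vv_a", "s2_vv_b", "s2_oo_a", "s2_oo_b")}
    for i in O:
        for a in V:
            terms["rho_oo"][i, a] = -0.5 * sum(
                rho_oo[i, j] * d_vo[a, j] for j in O)
            terms["rho_vv"][i, a] = -0.5 * sum(
                d_vo[b, i] * rho_vv[b, a] for b in V)
            terms["tt_chain"][i, a] = 0.5 * sum(
                t2[i, j, a, b] * t2[j, k, b, c] * d_vo[c, k]
                for j in O for k in O for b in V for c in V)
            terms["ladder_vv"][i, a] = sum(
                lvv(i, j, a, b) * d_ov[j, b] for j in O for b in V)
            terms["ladder_oo"][i, a] = sum(
                loo(i, j, a, b) * d_ov[j, b] for j in O for b in V)
            for key, sgn, perm in (
                ("ring_1", -1.0, lambda i, j, a, b: ring(i, j, a, b)),
                ("ring_2", +1.0, lambda i, j, a, b: ring(j, i, a, b)),
                ("ring_3", +1.0, lambda i, j, a, b: ring(i, j, b, a)),
                ("ring_4", -1.0, lambda i, j, a, b: ring(j, i, b, a)),
            ):
                terms[key][i, a] = sgn * sum(
                    perm(i, j, a, b) / denom(i, j, a, b) * d_ov[j, b]
                    for j in O for b in V)
            terms["s2_vv_a"][i, a] = sum(d_vv[a, b] * s2a[i, b] for b in V)
            terms["s2_vv_b"][i, a] = sum(d_vv[a, b] * s2b[i, b] for b in V)
            terms["s2_oo_a"][i, a] = -sum(d_oo[j, i] * s2a[j, a] for j in O)
            terms["s2_oo_b"][i, a] = -sum(d_oo[j, i] * s2b[j, a] for j in O)
    return terms


def test_each_second_order_term_matches_naive_loops(h2o_ws):
    ws, builder = h2o_ws
    d = ws.ints.operator_so("dipole", "z").real
    fast = builder.second_order_terms(d)
    slow = naive_second_order_terms(ws, d)
    assert len(fast) == 13
    assert set(fast) == set(slow)
    for key in fast:
        assert np.max(np.abs(fast[key] - slow[key])) < 1e-10, key


def test_t2_zero_collapses_to_bare_operator_block():
    eps = np.concatenate([[-1.1, -1.1, -0.8, -0.8], [0.5, 0.5, 1.3, 1.3]])
    rng = np.random.default_rng(8)
    d_sym = rng.normal(size=(8, 8))
    d_sym = d_sym + d_sym.T
    d_im = rng.normal(size=(8, 8))
    d_im = 1j * (d_im - d_im.T)
    ints = RawSpinOrbitalIntegrals(
        eps, 4, np.zeros((8,) * 4), operators={"op": [d_sym, d_im, d_sym]}
    )
    ws = AdcWorkspace(ints, t2_amplitudes(ints))
    builder = TransitionMomentBuilder(ws)
    for comp, dm in ((0, d_sym), (1, d_im)):
        F = builder.build("op", comp)
        bare = np.conj(dm[:4, 4:])  # <a|D|i> arranged over (i,a)
        assert np.max(np.abs(F.F_s - bare.reshape(-1))) < 1e-14
        assert np.max(np.abs(F.F_d)) == 0.0


def test_component_batching_transparency(h2o_ws):
    _, builder = h2o_ws
    batch = builder.build_components("dipole")
    for comp, F in zip(("x", "y", "z"), batch):
        single = builder.build("dipole", comp)
        np.testing.assert_array_equal(F.F_s, single.F_s)
        np.testing.assert_array_equal(F.F_d, single.F_d)


# -- amplitudes and cross-module SOS closure --------------------------------

def dense_states(ws):
    evals, evecs = ws.assemble_dense().eigenstates()
    return evals, [
        SimpleNamespace(y_s=evecs[: ws.n_s, k], y_d=evecs[ws.n_s:, k],
                        converged=True)
        for k in range(len(evals))
    ]


def test_amplitude_contract_and_phase_freedom(h2o_ws):
    ws, builder = h2o_ws
    F = builder.build("dipole", "z")
    evals, states = dense_states(ws)
    st = states[4]
    x = transition_amplitude(F, st)
    flipped = SimpleNamespace(y_s=-st.y_s, y_d=-st.y_d, converged=True)
    assert transition_amplitude(F, flipped) == pytest.approx(-x)
    f0 = oscillator_strength(evals[4], [x])
    assert oscillator_strength(
        evals[4], [transition_amplitude(F, flipped)]) == pytest.approx(f0)
    assert f0 >= 0.0
    # orthogonal moment/state gives zero
    zero = SimpleNamespace(
        y_s=np.zeros(ws.n_s), y_d=np.zeros(ws.n_d), converged=True)
    assert transition_amplitude(F, zero) == 0.0


def test_sos_from_amplitudes_reproduces_cpp_response(h2_ws):
    """Cross-module closure: moments + dense eigenpairs + damped SOS equal
    the folded-solver response value."""
    ws, builder = h2_ws
    Fz = builder.build("dipole", "z")
    evals, states = dense_states(ws)
    amps = np.array([transition_amplitude(Fz, st) for st in states])
    omegas = np.array([0.15, 0.35])
    vals, _, _ = cpp.response_functions(
        ws, [(Fz, Fz)], omegas, GAMMA, threshold=1e-10
    )
    for iw, w in enumerate(omegas):
        sos = np.sum(np.abs(amps) ** 2 / (evals - w - 1j * GAMMA)) + np.conj(
            np.sum(np.abs(amps) ** 2 / (evals + w - 1j * GAMMA))
        )
        assert abs(vals[0, iw] - sos) < 1e-8


def test_trk_sum_is_finite_diagnostic(h2_ws):
    ws, builder = h2_ws
    dips = builder.build_components("dipole")
    evals, states = dense_states(ws)
    total = 0.0
    for w, st in zip(evals, states):
        xs = [transition_amplitude(F, st) for F in dips]
        total += oscillator_strength(w, xs)
    assert np.isfinite(total)
    assert total > 0.0


# -- strengths and symmetry -------------------------------------------------

def test_water_rotatory_strengths_vanish(h2o_ws):
    ws, builder = h2o_ws
    states, rows, _ = excited_states_table(ws, builder, 6)
    for row in rows:
        assert abs(row["rot_strength_velocity"]) < 1e-10
        assert abs(row["rot_strength_length"]) < 1e-10


def test_enantiomers_flip_cd_sign(h2o2_pair):
    (ws1, b1), (ws2, b2) = h2o2_pair
    grid = np.array([0.30, 0.34])
    e1 = ecd_cpp(ws1, b1, grid, GAMMA, threshold=1e-6)
    e2 = ecd_cpp(ws2, b2, grid, GAMMA, threshold=1e-6)
    assert np.max(np.abs(e1.delta_epsilon)) > 1e-3  # chiral signal exists
    np.testing.assert_allclose(
        e1.delta_epsilon, -e2.delta_epsilon, atol=1e-10
    )


def test_spectra_invariant_under_rigid_rotation(h2o_molecule):
    from conftest import make_workspace

    theta = 0.9
    R = np.array([
        [np.cos(theta), 0, np.sin(theta)],
        [0, 1, 0],
        [-np.sin(theta), 0, np.cos(theta)],
    ])
    grid = np.array([0.40, 0.48])
    ws0, b0 = make_workspace(h2o_molecule, "sto-3g")
    ws1, b1 = make_workspace(h2o_molecule.rotated(R), "sto-3g")
    s0 = uvvis_cpp(ws0, b0, grid, GAMMA, threshold=1e-8)
    s1 = uvvis_cpp(ws1, b1, grid, GAMMA, threshold=1e-8)
    np.testing.assert_allclose(s0.sigma_au, s1.sigma_au, atol=1e-8)


# -- sigma(omega) and sticks -------------------------------------------------

def test_isolated_state_cpp_peak_is_analytic_lorentzian():
    """On a decoupled two-level model the CPP cross section equals the
    one-term damped SOS closed form exactly."""
    model = generate(2, 4, coupling=0.0, seed=5, dos=0.2)
    rhs = np.zeros(2)
    rhs[0] = 0.7
    evals, evecs = np.linalg.eigh(model.M_ss)
    x = evecs.T @ rhs
    omega_n = evals[np.argmax(np.abs(x))]
    gamma = 0.01
    grid = np.linspace(omega_n - 0.05, omega_n + 0.05, 11)
    F = SimpleNamespace(
        operator="model", component="z",
        F_s=rhs.astype(complex), F_d=np.zeros(model.n_d, complex),
        phase=1.0 + 0j, real_parts=lambda: (rhs, np.zeros(model.n_d)),
    )
    vals, _, _ = cpp.response_functions(
        model, [(F, F)], grid, gamma, threshold=1e-12
    )
    sigma = absorption_cross_section(vals[0].imag, grid)
    analytic = np.zeros_like(grid)
    for xn, wn in zip(x, evals):
        analytic += 4 * np.pi * grid / SPEED_OF_LIGHT_AU * xn * xn * (
            gamma / ((wn - grid) ** 2 + gamma**2)
            - gamma / ((wn + grid) ** 2 + gamma**2)
        )
    np.testing.assert_allclose(sigma, analytic, atol=1e-6)


class TestLorentzianBroadening:
    def test_empty_sticks_warn_and_zero(self):
        grid = np.linspace(0.1, 0.5, 7)
        with pytest.warns(UserWarning, match="empty"):
            spec = lorentzian_broadening([], 0.01, grid)
        assert np.all(spec.sigma_au == 0.0)

    def test_single_stick_line_center_value(self):
        f, gamma, w0 = 0.8, 0.004, 0.35
        spec = lorentzian_broadening([(w0, f)], gamma, np.array([w0]))
        want = 2.0 * np.pi * f / (SPEED_OF_LIGHT_AU * gamma)
        assert spec.sigma_au[0] == pytest.approx(want, rel=1e-12)

    def test_integral_recovers_total_intensity(self):
        sticks = [(0.3, 0.5), (0.45, 1.2)]
        gamma = 0.003
        grid = np.linspace(0.0, 1.5, 40001)
        spec = lorentzian_broadening(sticks, gamma, grid)
        integral = np.trapezoid(spec.sigma_au, grid)
        want = 2.0 * np.pi**2 / SPEED_OF_LIGHT_AU * sum(f for _, f in sticks)
        assert integral == pytest.approx(want, rel=0.01)


# -- unit conversions --------------------------------------------------------

class TestConvertUnits:
    def test_damping_1000_cm1(self):
        assert convert_units(1000.0, "cm-1", "hartree") == pytest.approx(
            1000.0 / 219474.6313632, rel=1e-12)

    def test_zero_maps_to_zero(self):
        for a in ("hartree", "ev", "cm-1", "au"):
            for b in ("hartree", "ev", "cm-1", "au"):
                assert convert_units(0.0, a, b) == 0.0

    @pytest.mark.parametrize("value", [1.0, 27.3, 1e-4])
    def test_roundtrips(self, value):
        via = convert_units(convert_units(value, "ev", "cm-1"), "cm-1", "ev")
        assert via == pytest.approx(value, rel=1e-12)
        via2 = convert_units(
            convert_units(value, "hartree", "ev"), "ev", "hartree")
        assert via2 == pytest.approx(value, rel=1e-12)

    def test_unsupported_pair(self):
        with pytest.raises(UnitError, match="supported"):
            convert_units(1.0, "joule", "ev")


def test_rotatory_strength_gauge_validation():
    with pytest.raises(ValueError, match="gauge"):
        rotatory_strength(0.5, [1.0], [1.0], gauge="acceleration")
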