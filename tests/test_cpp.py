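"""CPP solver tests: folding algebra, reduced-space solves, full-solver
oracle equivalence and convergence instrumentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adcfold import cpp
from adcfold.constants import convert_units
from adcfold.models import generate
from adcfold.properties import TransitionMomentBuilder

GAMMA = convert_units(1000.0, "cm-1", "hartree")


# -- frequency grids --------------------------------------------------------

class TestFreqGrid:
    def test_paper_window_has_25_points(self):
        grid = cpp.freq_grid(0.1650, 0.2250, step=0.0025)
        assert len(grid) == 25
        assert grid[0] == pytest.approx(0.1650)
        assert grid[-1] == pytest.approx(0.2250)

    def test_101_points_over_4_to_11_ev(self):
        grid = cpp.freq_grid(4.0, 11.0, count=101)
        assert len(grid) == 101
        assert np.allclose(np.diff(grid), 0.07)

    def test_single_point(self):
        assert list(cpp.freq_grid(0.3, 0.9, count=1)) == [0.3]

    def test_inconsistent_spec_errors(self):
        with pytest.raises(cpp.ConfigurationError):
            cpp.freq_grid(0.1, 0.2)
        with pytest.raises(cpp.ConfigurationError):
            cpp.freq_grid(0.1, 0.2, count=5, step=0.01)
        with pytest.raises(cpp.ConfigurationError):
            cpp.freq_grid(0.2, 0.1, count=5)


# -- fold weights -----------------------------------------------------------

class TestFoldWeights:
    def test_undamped_limit(self):
        d = np.array([1.0, 2.0, 3.0])
        wr, wi = cpp.fold_weights(d, 0.5, 0.0)
        np.testing.assert_allclose(wr, 1.0 / (d - 0.5), atol=1e-15)
        assert np.all(wi == 0.0)

    def test_undamped_resonance_raises(self):
        with pytest.raises(cpp.DegeneracyError):
            cpp.fold_weights(np.array([1.0, 2.0]), 2.0, 0.0)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.5, 5.0), st.floats(-1.0, 1.0), st.floats(1e-4, 0.5))
    def test_matches_complex_reciprocal(self, d, omega, gamma):
        wr, wi = cpp.fold_weights(np.array([d]), omega, gamma)
        ref = 1.0 / (d - omega - 1j * gamma)
        assert wr[0] == pytest.approx(ref.real, abs=1e-14)
        assert wi[0] == pytest.approx(ref.imag, abs=1e-14)
        assert wi[0] > 0.0


# -- sigma pairs and RHS folding -------------------------------------------

def dense_folded_parts(ws, omega, gamma):
    dense = ws.assemble_dense()
    wr, wi = cpp.fold_weights(ws.doubles_diagonal(), omega, gamma)
    Mp = dense.M_ss - dense.M_sd @ (wr[:, None] * dense.M_ds)
    Mpp = dense.M_sd @ (wi[:, None] * dense.M_ds)
    return Mp, Mpp


class TestSigmaPair:
    def test_dense_equivalence_on_water(self, h2o_ws):
        ws, _ = h2o_ws
        rng = np.random.default_rng(3)
        b = rng.normal(size=ws.n_s)
        b /= np.linalg.norm(b)
        for omega in (0.2, 0.45):
            Mp, Mpp = dense_folded_parts(ws, omega, GAMMA)
            sp, spp = cpp.build_sigma_pair(ws, b, omega, GAMMA)
            np.testing.assert_allclose(sp, Mp @ b, atol=1e-10)
            np.testing.assert_allclose(spp, Mpp @ b, atol=1e-10)

    def test_large_gamma_kills_sigma_pp(self, h2o_ws):
        ws, _ = h2o_ws
        b = np.ones(ws.n_s) / np.sqrt(ws.n_s)
        norms = []
        for gamma in (1e2, 1e3, 1e4):
            _, spp = cpp.build_sigma_pair(ws, b, 0.3, gamma)
            norms.append(np.linalg.norm(spp))
        # resolvent decay O(1/gamma)
        assert norms[1] < 0.15 * norms[0]
        assert norms[2] < 0.15 * norms[1]

    def test_zero_coupling_reduces_to_bare_sigma(self):
        model = generate(6, 10, coupling=0.0, seed=4, dos=1.0)
        b = np.linspace(-1, 1, 6)
        sp, spp = cpp.build_sigma_pair(model, b, 0.5, 0.01)
        np.testing.assert_allclose(sp, model.M_ss @ b, atol=1e-14)
        assert np.max(np.abs(spp)) == 0.0


class TestFoldRhs:
    def test_zero_doubles_rhs_passthrough(self, h2o_ws):
        ws, _ = h2o_ws
        b_s = np.arange(1.0, ws.n_s + 1)
        out = cpp.fold_rhs(ws, b_s, np.zeros(ws.n_d), 0.3, GAMMA)
        np.testing.assert_allclose(out, b_s.astype(complex), atol=1e-15)

    def test_dense_block_elimination(self, h2o_ws):
        ws, _ = h2o_ws
        dense = ws.assemble_dense()
        rng = np.random.default_rng(5)
        b_s = rng.normal(size=ws.n_s)
        b_d = rng.normal(size=ws.n_d)
        for branch in (+1, -1):
            z = branch * 0.33 + 1j * GAMMA
            w = 1.0 / (ws.doubles_diagonal() - z)
            want = b_s - dense.M_sd @ (w * b_d)
            got = cpp.fold_rhs(ws, b_s, b_d, 0.33, GAMMA, branch)
            np.testing.assert_allclose(got, want, atol=1e-12)


class TestSolveReduced:
    def test_subspace_containing_solution_is_exact(self, h2o_ws):
        ws, _ = h2o_ws
        dense = ws.assemble_dense()
        omega = 0.3
        rng = np.random.default_rng(6)
        b = rng.normal(size=ws.n_s) + 0j
        Mp, Mpp = dense_folded_parts(ws, omega, GAMMA)
        A = Mp - 1j * Mpp - (omega + 1j * GAMMA) * np.eye(ws.n_s)
        x = np.linalg.solve(A, b)
        V, _ = np.linalg.qr(np.column_stack([x.real, x.imag]))
        sp = Mp @ V
        spp = Mpp @ V
        c = cpp.solve_reduced(V, sp, spp, omega, GAMMA, b)
        res = A @ (V @ c) - b
        assert np.linalg.norm(res) / np.linalg.norm(b) < 1e-12

    def test_one_vector_diagonal_model_closed_form(self):
        # scalar folded equation: ((a - w) - i(m + g)) x = beta
        a, m, g, w, beta = 1.3, 0.2, 0.05, 0.9, 0.7
        V = np.array([[1.0]])
        c = cpp.solve_reduced(
            V, np.array([[a]]), np.array([[m]]), w, g,
            np.array([beta + 0j]),
        )
        want = beta / ((a - w) - 1j * (m + g))
        assert c[0] == pytest.approx(want, rel=1e-12)

    def test_invariance_under_orthogonal_remixing(self, h2o_ws):
        ws, _ = h2o_ws
        omega = 0.25
        rng = np.random.default_rng(7)
        V, _ = np.linalg.qr(rng.normal(size=(ws.n_s, 4)))
        Mp, Mpp = dense_folded_parts(ws, omega, GAMMA)
        b = rng.normal(size=ws.n_s) + 1j * rng.normal(size=ws.n_s)
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        x1 = V @ cpp.solve_reduced(V, Mp @ V, Mpp @ V, omega, GAMMA, b)
        W = V @ Q
        x2 = W @ cpp.solve_reduced(W, Mp @ W, Mpp @ W, omega, GAMMA, b)
        np.testing.assert_allclose(x1, x2, atol=1e-12)


# -- full solver ------------------------------------------------------------

def _dipole_rhs(builder):
    return builder.build_components("dipole")


@pytest.mark.parametrize("strategy", ["separate", "common"])
def test_solver_matches_dense_complex_solve(h2o_ws, strategy):
    ws, builder = h2o_ws
    Fz = builder.build("dipole", "z")
    omegas = np.array([0.2, 0.4])
    systems = cpp.make_cpp_systems([Fz], omegas, GAMMA, threshold=1e-9)
    sols, diag = cpp.cpp_solve(ws, systems, strategy=strategy)
    dense = ws.assemble_dense()
    Ffull = np.concatenate([Fz.F_s, Fz.F_d])
    for s, sol in zip(systems, sols):
        assert sol.converged
        z = s.omega_signed + 1j * s.gamma
        X = np.linalg.solve(
            dense.matrix - z * np.eye(dense.matrix.shape[0]), Ffull
        )
        rel_s = np.linalg.norm(sol.x_s - X[: ws.n_s]) / np.linalg.norm(
            X[: ws.n_s])
        rel_d = np.linalg.norm(sol.x_d - X[ws.n_s:]) / np.linalg.norm(
            X[ws.n_s:])
        assert rel_s < 1e-8
        assert rel_d < 1e-8


def test_zero_rhs_converges_to_zero_in_one_iteration(h2o_ws):
    ws, builder = h2o_ws
    system = cpp.FoldedSystem(
        label="zero@0.3", omega=0.3, gamma=GAMMA,
        rhs_s=np.zeros(ws.n_s), rhs_d=np.zeros(ws.n_d),
    )
    sols, _ = cpp.cpp_solve(ws, [system])
    assert sols[0].converged
    assert sols[0].n_iterations == 1
    assert np.max(np.abs(sols[0].x_s)) == 0.0


def test_separate_strategy_sigma_pairs_equal_trial_vectors(h2o_ws):
    ws, builder = h2o_ws
    systems = cpp.make_cpp_systems(
        _dipole_rhs(builder), np.array([0.2, 0.3, 0.4]), GAMMA
    )
    _, diag = cpp.cpp_solve(ws, systems, strategy="separate")
    assert diag.sigma_pairs_computed == diag.trial_vectors


def test_common_strategy_product_accounting(lih_ws):
    """sigma-pair accounting for a pooled subspace: new trial vectors times
    unconverged response functions, summed over iterations."""
    ws, builder = lih_ws
    systems = cpp.make_cpp_systems(
        _dipole_rhs(builder), np.array([0.1, 0.15]), GAMMA,
        threshold=1e-6,
    )
    sols, diag = cpp.cpp_solve(ws, systems, strategy="common")
    assert all(s.converged for s in sols)
    # reconstruct the product accounting from the per-iteration records
    per_iter = {}
    for rec in diag.records:
        new, unconv = per_iter.get(rec.iteration, (0, 0))
        per_iter[rec.iteration] = (rec.new_vectors, unconv + 1)
    expected = sum(new * n for new, n in per_iter.values())
    assert diag.sigma_pairs_accounted == expected
    # pooled subspaces never build more pairs than the product accounting
    assert diag.sigma_pairs_computed <= diag.sigma_pairs_accounted


def test_monotone_projected_residual(h2o_ws):
    ws, builder = h2o_ws
    Fz = builder.build("dipole", "z")
    systems = cpp.make_cpp_systems([Fz], np.array([0.45]), GAMMA,
                                   threshold=1e-12)
    sols, _ = cpp.cpp_solve(ws, systems, max_iter=30)
    for sol in sols:
        hist = np.array(sol.residual_history)
        assert np.all(np.diff(hist) < 1e-10)  # non-increasing


def test_response_value_matches_damped_sos(h2_ws):
    ws, builder = h2_ws
    Fz = builder.build("dipole", "z")
    omegas = np.array([0.1, 0.3])
    vals, _, _ = cpp.response_functions(
        ws, [(Fz, Fz)], omegas, GAMMA, threshold=1e-10
    )
    evals, evecs = ws.assemble_dense().eigenstates()
    x = evecs.T @ np.concatenate([Fz.F_s, Fz.F_d])
    for iw, w in enumerate(omegas):
        sos = np.sum(np.abs(x) ** 2 / (evals - w - 1j * GAMMA)) + np.conj(
            np.sum(np.abs(x) ** 2 / (evals + w - 1j * GAMMA))
        )
        assert abs(vals[0, iw] - sos) < 1e-8


def test_absorptive_positivity_and_small_gamma_limit(h2_ws):
    ws, builder = h2_ws
    Fz = builder.build("dipole", "z")
    omegas = np.array([0.1, 0.25])  # off resonance (first root ~0.39)
    ims = []
    for gamma in (1e-2, 1e-3, 1e-4):
        vals, _, _ = cpp.response_functions(
            ws, [(Fz, Fz)], omegas, gamma, threshold=1e-10
        )
        assert np.all(vals.imag >= 0.0)
        ims.append(np.max(vals.imag))
    # Im part vanishes linearly in gamma off resonance
    assert ims[1] < 0.15 * ims[0]
    assert ims[2] < 0.15 * ims[1]


def test_unconverged_systems_are_flagged_not_silent():
    model = generate(40, 60, dos=8.0, coupling=0.4, seed=9)
    systems = [cpp.FoldedSystem(
        label="m@w", omega=2.0, gamma=1e-3, rhs_s=model.rhs[0],
        rhs_d=np.zeros(model.n_d), threshold=1e-14,
    )]
    sols, _ = cpp.cpp_solve(model, systems, max_iter=2)
    assert not sols[0].converged
    assert sols[0].x_s is not None  # partial result available
    with pytest.raises(RuntimeError, match="not converged"):
        cpp.response_value(
            type("F", (), {"F_s": np.zeros(model.n_s, complex),
                           "F_d": np.zeros(model.n_d, complex)})(),
            sols[0],
        )
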