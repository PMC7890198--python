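"""ANM Hessians, finite differences, switched pair energies, minimization."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nmakit import energetics as en
from nmakit import synthetic as syn
from nmakit.constants import COULOMB_KCAL_A
from nmakit.structure import select


class TestANMHessian:
    def test_symmetric_and_translation_invariant(self, folded100):
        _, _, _, _ = folded100
        s = syn.folded_chain_structure(30, seed=1)
        sel = select(s, "name CA")
        H = en.anm_hessian(s, sel, en.ANMParameters(cutoff=9.0))
        A = H.array
        assert np.abs(A - A.T).max() < 1e-12
        # row sums of super-elements vanish: H @ (uniform translation) = 0
        for axis in range(3):
            t = np.zeros(H.order)
            t[axis::3] = 1.0
            assert np.abs(A @ t).max() < 1e-10

    def test_rotation_in_null_space(self):
        s = syn.folded_chain_structure(25, seed=2)
        sel = select(s, "name CA")
        H = en.anm_hessian(s, sel, en.ANMParameters(cutoff=9.0))
        xyz = H.coords - H.coords.mean(axis=0)
        # infinitesimal rotation about z
        r = np.zeros((len(xyz), 3))
        r[:, 0] = -xyz[:, 1]
        r[:, 1] = xyz[:, 0]
        assert np.abs(H.array @ r.ravel()).max() < 1e-10

    def test_positive_semidefinite(self):
        s = syn.folded_chain_structure(25, seed=3)
        sel = select(s, "name CA")
        H = en.anm_hessian(s, sel, en.ANMParameters(cutoff=9.0))
        w = np.linalg.eigvalsh(H.array)
        assert w.min() > -1e-10

    def test_gamma_scales_linearly(self):
        s = syn.folded_chain_structure(20, seed=4)
        sel = select(s, "name CA")
        H1 = en.anm_hessian(s, sel, en.ANMParameters(cutoff=9.0, gamma=1.0))
        H2 = en.anm_hessian(s, sel, en.ANMParameters(cutoff=9.0, gamma=2.5))
        np.testing.assert_allclose(H2.array, 2.5 * H1.array, atol=1e-12)

    def test_matches_finite_difference_of_anm_potential(self):
        s = syn.folded_chain_structure(15, seed=5)
        sel = select(s, "name CA")
        xyz = s.coords[list(sel.indices)]
        p = en.ANMParameters(cutoff=9.0)
        analytic = en.anm_hessian(s, sel, p).array
        pot = en.anm_potential(xyz, p)
        numeric = en.numerical_hessian(pot, xyz).array
        assert np.abs(analytic - numeric).max() < 1e-5

    def test_isolated_node_warns(self):
        s = syn.folded_chain_structure(20, seed=6)
        sel = select(s, "name CA")
        with pytest.warns(RuntimeWarning, match="no neighbor"):
            en.anm_hessian(s, sel, en.ANMParameters(cutoff=0.5))

    def test_two_atoms_single_spring(self):
        """2 nodes along x: the only nonzero eigenvalue is 2γ (stretch)."""
        import nmakit.structure as stx

        atoms = [
            stx.Atom(1, "CA", "C", "GLY", 1, "A", "", np.array([0.0, 0.0, 0.0]), mass=1.0),
            stx.Atom(2, "CA", "C", "GLY", 2, "A", "", np.array([3.0, 0.0, 0.0]), mass=1.0),
        ]
        s = stx.Structure(atoms)
        H = en.anm_hessian(s, select(s, "all"), en.ANMParameters(cutoff=5.0, gamma=1.0))
        w = np.sort(np.linalg.eigvalsh(H.array))
        np.testing.assert_allclose(w[:5], 0.0, atol=1e-12)
        assert w[5] == pytest.approx(2.0, abs=1e-12)


class TestNumericalHessian:
    def test_exact_on_quadratic(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(9, 9))
        K = M @ M.T  # SPD

        pot = en.PotentialModel(
            energy=lambda x: 0.5 * x @ K @ x,
            gradient=lambda x: K @ x,
            n_atoms=3,
        )
        H = en.numerical_hessian(pot, np.zeros(9))
        assert np.abs(H.array - K).max() < 1e-6

    def test_fixed_atoms_removed(self):
        K = np.eye(9) * 2.0
        pot = en.PotentialModel(
            energy=lambda x: 0.5 * x @ K @ x,
            gradient=lambda x: K @ x,
            n_atoms=3,
            fixed_mask=np.array([False, True, False]),
        )
        H = en.numerical_hessian(pot, np.zeros(9))
        assert H.order == 6

    def test_symmetrized(self, chain10):
        pot, coords, _ = chain10
        H = en.numerical_hessian(pot, coords)
        assert np.abs(H.array - H.array.T).max() == 0.0


class TestSwitchingFunction:
    def test_boundary_values(self):
        assert en.switching_function(6.0) == 1.0
        assert en.switching_function(10.0) == 0.0
        assert en.switching_function(2.0) == 1.0
        assert en.switching_function(50.0) == 0.0

    def test_exact_midwindow_value(self):
        # closed form at r=8, r_on=6, r_off=10:
        # (100-64)² (100+128-108) / (100-36)³ = 1296·120/262144 = 0.59326171875
        assert en.switching_function(8.0) == pytest.approx(0.59326171875, abs=1e-15)

    def test_monotone_decreasing_in_window(self):
        r = np.linspace(6.0, 10.0, 200)
        vals = [en.switching_function(x) for x in r]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_c1_continuity_at_edges(self):
        h = 1e-6
        for edge in (6.0, 10.0):
            left = (en.switching_function(edge) - en.switching_function(edge - h)) / h
            right = (en.switching_function(edge + h) - en.switching_function(edge)) / h
            assert abs(left - right) < 1e-4

    def test_symbolic_oracle(self):
        """Exact-arithmetic check of the switching polynomial and its C¹
        continuity, independent of the float implementation."""
        import sympy as sp

        r, ron, roff = sp.symbols("r ron roff", positive=True)
        S = (
            (roff**2 - r**2) ** 2
            * (roff**2 + 2 * r**2 - 3 * ron**2)
            / (roff**2 - ron**2) ** 3
        )
        assert sp.simplify(S.subs(r, ron) - 1) == 0
        assert sp.simplify(S.subs(r, roff)) == 0
        dS = sp.diff(S, r)
        assert sp.simplify(dS.subs(r, ron)) == 0
        assert sp.simplify(dS.subs(r, roff)) == 0
        for rv in (sp.Rational(13, 2), sp.Integer(7), sp.Rational(17, 2), sp.Integer(9)):
            exact = float(S.subs({r: rv, ron: 6, roff: 10}))
            assert en.switching_function(float(rv)) == pytest.approx(exact, abs=1e-15)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            en.switching_function(5.0, cut_on=10.0, cut_off=6.0)

    @given(r=st.floats(0.1, 20.0))
    def test_bounded(self, r):
        v = en.switching_function(r)
        assert 0.0 <= v <= 1.0


class TestSwitchedPairPotential:
    def test_zero_beyond_cutoff(self):
        assert en.switched_pair_potential(1.0, -1.0, (0.1, 3.5), 12.0) == 0.0

    def test_lj_minimum_depth(self):
        # neutral pair at r_min: energy is exactly −ε (switch = 1 inside cut_on)
        eps, rmin = 0.2, 3.5
        e = en.switched_pair_potential(0.0, 0.0, (eps, rmin), rmin)
        assert e == pytest.approx(-eps, abs=1e-12)

    def test_coulomb_term_with_dielectric(self):
        # large r_min pushed out so LJ ≈ 0? instead subtract the neutral value
        r = 5.0
        e_charged = en.switched_pair_potential(1.0, 1.0, (0.1, 3.0), r)
        e_neutral = en.switched_pair_potential(0.0, 0.0, (0.1, 3.0), r)
        expected = COULOMB_KCAL_A * 1.0 * 1.0 / (3.0 * r)
        assert e_charged - e_neutral == pytest.approx(expected, rel=1e-12)

    def test_opposite_charges_attract(self):
        e = en.switched_pair_potential(1.0, -1.0, (0.05, 3.0), 4.0)
        e0 = en.switched_pair_potential(0.0, 0.0, (0.05, 3.0), 4.0)
        assert e < e0


class TestMinimize:
    def test_quadratic_bowl_reaches_tolerance(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(12, 12))
        K = M @ M.T + 0.1 * np.eye(12)
        pot = en.PotentialModel(
            energy=lambda x: 0.5 * x @ K @ x,
            gradient=lambda x: K @ x,
            n_atoms=4,
        )
        x0 = rng.normal(size=12)
        x, trace = en.minimize(pot, x0, sd_steps=50)
        assert en.grms(pot.gradient(x)) < 1e-4
        assert np.abs(x).max() < 1e-3  # true minimum is the origin

    def test_perturbed_chain_relaxes(self, chain10):
        pot, coords, _ = chain10
        rng = np.random.default_rng(2)
        x0 = coords.ravel() + rng.normal(scale=0.05, size=coords.size)
        x, trace = en.minimize(pot, x0, sd_steps=200)
        assert en.grms(pot.gradient(x)) < 1e-4
        assert pot.energy(x) <= pot.energy(x0.ravel())

    def test_energy_never_increases_in_trace(self, chain10):
        pot, coords, _ = chain10
        rng = np.random.default_rng(3)
        x0 = coords.ravel() + rng.normal(scale=0.05, size=coords.size)
        _, trace = en.minimize(pot, x0, sd_steps=100)
        e = trace.energies
        assert all(b <= a + 1e-10 for a, b in zip(e, e[1:]))

    def test_fixed_atoms_do_not_move(self):
        K = np.eye(9) * 3.0
        pot = en.PotentialModel(
            energy=lambda x: 0.5 * x @ K @ x,
            gradient=lambda x: K @ x,
            n_atoms=3,
            fixed_mask=np.array([True, False, False]),
        )
        x0 = np.arange(9, dtype=float)
        x, _ = en.minimize(pot, x0, sd_steps=50)
        np.testing.assert_allclose(x[:3], x0[:3], atol=0.0)
        assert np.abs(x[3:]).max() < 1e-3


class TestMassWeight:
    def test_double_weighting_rejected(self, chain10):
        pot, coords, _ = chain10
        H = en.numerical_hessian(pot, coords)
        Hw = en.mass_weight(H)
        with pytest.raises(ValueError):
            en.mass_weight(Hw)

    def test_uniform_masses_scale(self, chain10):
        pot, coords, _ = chain10
        H = en.numerical_hessian(pot, coords)
        Hw = en.mass_weight(H, masses=np.full(10, 4.0))
        np.testing.assert_allclose(Hw.array, H.array / 4.0, atol=1e-14)

    def test_nonpositive_mass_rejected(self, chain10):
        pot, coords, _ = chain10
        H = en.numerical_hessian(pot, coords)
        with pytest.raises(ValueError):
            en.mass_weight(H, masses=np.zeros(10))


class TestHessianIO:
    def test_roundtrip(self, tmp_path, chain10):
        pot, coords, _ = chain10
        H = en.mass_weight(en.numerical_hessian(pot, coords))
        p = str(tmp_path / "h.txt")
        en.save_hessian(H, p)
        H2 = en.load_hessian(p)
        assert H2.mass_weighted == H.mass_weighted
        assert np.abs(H2.array - H.array).max() < 1e-12
        np.testing.assert_allclose(H2.masses, H.masses)
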