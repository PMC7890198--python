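"""Structure parsing, selection grammar, superposition and editing."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nmakit import synthetic as syn
from nmakit.structure import (
    Atom,
    AtomSelection,
    PairingError,
    SelectionError,
    Structure,
    StructureError,
    difference_vector,
    kabsch_superpose,
    pair_by_residue,
    radius_of_gyration,
    read_pdb,
    rmsd,
    select,
    solvent_shell,
    transplant_ligand,
    write_pdb,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 12.00           C
ATOM      3  C   ALA A   1      12.697   7.147  -4.943  1.00 14.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60 10.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.40 10.00           C
ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00 10.00           C
END
"""


@pytest.fixture
def minimal(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINIMAL_PDB)
    return read_pdb(str(p))


class TestReadPDB:
    def test_file_order_and_fields(self, minimal):
        assert len(minimal) == 3
        assert [a.name for a in minimal.atoms] == ["N", "CA", "C"]
        assert minimal.atoms[0].resname == "ALA"
        assert minimal.atoms[1].bfactor == 12.0
        np.testing.assert_allclose(minimal.atoms[0].coord, [11.104, 6.134, -6.504])

    def test_masses_from_element(self, minimal):
        assert minimal.atoms[0].mass == pytest.approx(14.007, abs=0.01)
        assert minimal.atoms[1].mass == pytest.approx(12.011, abs=0.01)

    def test_altloc_keep_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        s = read_pdb(str(p))
        cas = [a for a in s.atoms if a.resid == 1]
        assert len(cas) == 1
        assert cas[0].altloc == "A"
        assert cas[0].occupancy == pytest.approx(0.6)

    def test_altloc_keep_first(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        s = read_pdb(str(p), altloc_policy="keep-first")
        assert [a for a in s.atoms if a.resid == 1][0].altloc == "A"

    def test_empty_after_chain_filter(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        with pytest.raises(StructureError):
            read_pdb(str(p), chains={"Z"})

    def test_write_read_roundtrip(self, tmp_path):
        s = syn.ideal_helix(8, build_H=True)
        path = str(tmp_path / "helix.pdb")
        write_pdb(s, path)
        s2 = read_pdb(path)
        assert len(s2) == len(s)
        assert np.abs(s.coords - s2.coords).max() < 1e-3
        assert all(a.name == b.name and a.resid == b.resid for a, b in zip(s.atoms, s2.atoms))


class TestSelect:
    def test_name_ca(self):
        s = syn.ideal_helix(6)
        assert len(select(s, "name CA")) == 6

    def test_compound_expression(self):
        s = syn.ideal_helix(12)
        sel = select(s, "chain A and resid 3-7 and name CA")
        assert len(sel) == 5
        assert all(s.atoms[i].resid in range(3, 8) for i in sel.indices)

    def test_or_and_not(self):
        s = syn.ideal_helix(6, build_H=True)
        heavy = select(s, "heavy")
        not_h = select(s, "not element H")
        assert heavy.indices == not_h.indices
        no = select(s, "name CA or name C")
        assert len(no) == 12

    def test_empty_selection_allowed(self):
        s = syn.ideal_helix(6)
        sel = select(s, "resname TRP")
        assert sel.empty

    def test_malformed_expression(self):
        s = syn.ideal_helix(6)
        with pytest.raises(SelectionError):
            select(s, "resid abc")
        with pytest.raises(SelectionError):
            select(s, "name")
        with pytest.raises(SelectionError):
            select(s, "(name CA")

    def test_order_preserved(self):
        s = syn.ideal_helix(6)
        sel = select(s, "name CA or name N")
        assert list(sel.indices) == sorted(sel.indices)


class TestSuperposition:
    def test_self_superposition_identity(self):
        s = syn.folded_chain_structure(20, seed=1)
        sel = select(s, "name CA")
        assert rmsd(s, s, sel, sel) == pytest.approx(0.0, abs=1e-10)
        R, t, v = kabsch_superpose(s.coords, s.coords)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_rigid_transform_removed(self):
        s = syn.folded_chain_structure(20, seed=2)
        sel = select(s, "name CA")
        s2 = s.copy()
        theta = math.pi / 2
        Rz = np.array(
            [[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]
        )
        s2.coords = s.coords @ Rz.T + np.array([5.0, -3.0, 2.0])
        assert rmsd(s, s2, sel, sel) == pytest.approx(0.0, abs=1e-8)

    def test_proper_rotation(self):
        s = syn.folded_chain_structure(15, seed=4)
        s2 = syn.perturbed_copy(s, 0.5, seed=5)
        R, _, _ = kabsch_superpose(s2.coords, s.coords)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self):
        a = syn.folded_chain_structure(20, seed=6)
        b = syn.perturbed_copy(a, 1.0, seed=7)
        sel = select(a, "name CA")
        assert rmsd(a, b, sel, sel) == pytest.approx(rmsd(b, a, sel, sel), abs=1e-8)

    def test_too_few_pairs(self):
        s = syn.folded_chain_structure(20, seed=1)
        two = AtomSelection((0, 1))
        with pytest.raises(PairingError):
            rmsd(s, s, two, two)

    def test_mismatched_counts(self):
        s = syn.folded_chain_structure(20, seed=1)
        with pytest.raises(PairingError):
            rmsd(s, s, AtomSelection((0, 1, 2)), AtomSelection((0, 1, 2, 3)))

    @given(seed=st.integers(0, 50))
    def test_rigid_invariance_property(self, seed):
        rng = np.random.default_rng(seed)
        s = syn.folded_chain_structure(12, seed=seed)
        b = syn.perturbed_copy(s, 0.4, seed=seed + 1)
        sel = select(s, "name CA")
        base = rmsd(s, b, sel, sel)
        # random proper rotation + translation of the mobile structure
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        b2 = b.copy()
        b2.coords = b.coords @ q.T + rng.normal(size=3) * 10
        assert rmsd(s, b2, sel, sel) == pytest.approx(base, abs=1e-8)


class TestDifferenceVector:
    def test_identical_structures_zero(self):
        s = syn.folded_chain_structure(20, seed=1)
        sel = select(s, "name CA")
        dv = difference_vector(s, s, sel, sel)
        assert np.abs(dv.components).max() == pytest.approx(0.0, abs=1e-10)

    def test_translation_removed(self):
        s = syn.folded_chain_structure(20, seed=1)
        sel = select(s, "name CA")
        s2 = s.copy()
        s2.coords = s.coords + np.array([1.0, 0.0, 0.0])
        dv = difference_vector(s, s2, sel, sel)
        assert np.abs(dv.components).max() == pytest.approx(0.0, abs=1e-8)

    def test_hinge_motion_localized(self):
        open_s, closed_s = syn.hinge_pair(seed=0)
        n_dom = 20
        dom_a = AtomSelection(tuple(range(n_dom)))
        # fit on the static domain only: the moving domain then carries
        # essentially all of the displacement
        dv = difference_vector(open_s, closed_s, dom_a, dom_a)
        assert np.linalg.norm(dv.components, axis=1).max() < 0.5
        R, t, _ = kabsch_superpose(
            closed_s.coords[:n_dom], open_s.coords[:n_dom]
        )
        fitted = closed_s.coords @ R.T + t
        norms = np.linalg.norm(fitted - open_s.coords, axis=1)
        assert norms[-n_dom:].mean() > 3 * norms[:n_dom].mean()


class TestPairByResidue:
    def test_intersection_of_shared_residues(self):
        a = syn.ideal_helix(12)
        b = syn.ideal_helix(12)
        # drop residues 3 and 9 from b
        b = Structure([at for at in b.atoms if at.resid not in (3, 9)])
        selA, selB = pair_by_residue(a, b)
        assert len(selA) == len(selB) == 10
        residsA = [a.atoms[i].resid for i in selA.indices]
        assert 3 not in residsA and 9 not in residsA


class TestTransplantLigand:
    def _pocket(self):
        """Two 'residues' of 2 atoms flanking a 1-atom ligand."""
        def atom(serial, name, resname, resid, xyz, het=False, element="C"):
            return Atom(serial, name, element, resname, resid, "A", "", np.array(xyz), het=het)

        atoms = [
            atom(1, "CA", "GLY", 1, [-3.0, 0.0, 0.0]),
            atom(2, "CB", "GLY", 1, [-2.0, 0.5, 0.0]),
            atom(3, "CA", "GLY", 2, [3.0, 0.0, 0.0]),
            atom(4, "CB", "GLY", 2, [2.0, -0.5, 0.0]),
            atom(5, "CA", "GLY", 3, [0.0, 5.3, 0.0]),  # decoy at 5.1 Å from ligand
            atom(6, "C1", "LIG", 10, [0.0, 0.2, 0.0], het=True),
        ]
        return Structure(atoms)

    def test_identity_transplant(self):
        s = self._pocket()
        lig = select(s, "resname LIG")
        out = transplant_ligand(s, s, lig, fit_atoms="heavy")
        new_lig = select(out, "resname LIG")
        np.testing.assert_allclose(
            out.coords[list(new_lig.indices)], s.coords[list(lig.indices)], atol=1e-9
        )

    def test_rigidly_displaced_donor(self):
        s = self._pocket()
        donor = s.copy()
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        donor.coords = s.coords @ Rz.T + np.array([10.0, 0.0, 0.0])
        lig = select(donor, "resname LIG")
        out = transplant_ligand(s, donor, lig, fit_atoms="heavy")
        new_lig = select(out, "resname LIG")
        np.testing.assert_allclose(
            out.coords[list(new_lig.indices)],
            s.coords[list(select(s, "resname LIG").indices)],
            atol=1e-8,
        )

    def test_contact_shell_excludes_distant_residue(self):
        s = self._pocket()
        lig_xyz = np.array([0.0, 0.2, 0.0])
        d_decoy = np.linalg.norm(np.array([0.0, 5.3, 0.0]) - lig_xyz)
        assert d_decoy > 5.0  # fixture sanity: decoy beyond the cutoff
        # transplant must succeed from residues 1-2 alone (3 shared atoms incl. ligand shell)
        donor = s.copy()
        lig = select(donor, "resname LIG")
        out = transplant_ligand(s, donor, lig, fit_atoms="heavy")
        assert len(out) == len(s)

    def test_idempotent(self):
        s = self._pocket()
        donor = syn.perturbed_copy(s, 0.0, seed=0)
        lig = select(donor, "resname LIG")
        once = transplant_ligand(s, donor, lig, fit_atoms="heavy")
        twice = transplant_ligand(once, donor, lig, fit_atoms="heavy")
        np.testing.assert_allclose(once.coords, twice.coords, atol=1e-9)


class TestSolventShell:
    def _solvated(self, water_positions):
        atoms = [Atom(1, "CA", "C", "GLY", 1, "A", "", np.zeros(3))]
        serial = 2
        for i, pos in enumerate(water_positions):
            atoms.append(
                Atom(serial, "O", "O", "HOH", 100 + i, "W", "", np.array(pos), het=True)
            )
            serial += 1
        return Structure(atoms)

    def test_near_water_kept_far_removed(self):
        s = self._solvated([[2.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        sel = solvent_shell(s, select(s, "name CA"), cutoff=2.8)
        resids = {s.atoms[i].resid for i in sel.indices}
        assert resids == {100}

    def test_cubic_lattice_face_neighbors(self):
        # 27 waters on a 3x3x3 lattice of spacing 3 Å around a point solute:
        # exactly the 6 face-adjacent (d=3) survive a cutoff between 3 and 3*sqrt(2)
        waters = [
            [3 * i, 3 * j, 3 * k]
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
        s = self._solvated(waters)
        sel = solvent_shell(s, select(s, "name CA"), cutoff=3.5)
        # brute-force oracle
        expected = {
            s.atoms[i].resid
            for i in range(1, len(s.atoms))
            if np.linalg.norm(s.atoms[i].coord) <= 3.5
        }
        assert {s.atoms[i].resid for i in sel.indices} == expected
        assert len(expected) == 6

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(0)
        s = self._solvated(rng.uniform(-6, 6, (30, 3)))
        solute = select(s, "name CA")
        prev: set = set()
        for cutoff in (1.0, 2.0, 4.0, 8.0):
            cur = set(solvent_shell(s, solute, cutoff=cutoff).indices)
            assert prev <= cur
            prev = cur

    def test_molecules_never_split(self):
        atoms = [Atom(1, "CA", "C", "GLY", 1, "A", "", np.zeros(3))]
        # 3-atom water with only one atom in range
        for k, (name, el, pos) in enumerate(
            [("O", "O", [2.5, 0, 0]), ("H1", "H", [3.3, 0.6, 0]), ("H2", "H", [3.3, -0.6, 0])]
        ):
            atoms.append(Atom(2 + k, name, el, "HOH", 100, "W", "", np.array(pos), het=True))
        s = Structure(atoms)
        sel = solvent_shell(s, select(s, "name CA"), cutoff=2.8)
        assert len(sel) == 3  # whole molecule kept


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        s = Structure([Atom(1, "CA", "C", "GLY", 1, "A", "", np.zeros(3), mass=12.0)])
        assert radius_of_gyration(s, AtomSelection((0,))) == 0.0

    def test_two_unit_masses(self):
        atoms = [
            Atom(1, "CA", "C", "GLY", 1, "A", "", np.array([0.0, 0.0, 0.0]), mass=1.0),
            Atom(2, "CA", "C", "GLY", 2, "A", "", np.array([2.0, 0.0, 0.0]), mass=1.0),
        ]
        s = Structure(atoms)
        assert radius_of_gyration(s, AtomSelection((0, 1))) == pytest.approx(1.0)

    def test_against_double_loop_oracle(self):
        s = syn.random_cloud_structure(100, seed=9)
        sel = select(s, "all")
        got = radius_of_gyration(s, sel, mass_weighted=False)
        xyz = s.coords
        n = len(s)
        # Rg² = (1/2N²) ΣΣ |r_i - r_j|²  (uniform masses)
        acc = 0.0
        for i in range(n):
            for j in range(n):
                acc += np.sum((xyz[i] - xyz[j]) ** 2)
        oracle = math.sqrt(acc / (2 * n * n))
        assert got == pytest.approx(oracle, abs=1e-10)
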