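"""Structure model, PDB round trips, selections, correspondence and superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import mk_atom, mk_peptide, mk_target, mk_water
from peprefine.structmodel import (
    AtomSelection,
    ComplexModel,
    CorrespondenceError,
    MolecularStructure,
    PDBFormatError,
    RigidTransform,
    Role,
    RoleMappingError,
    SuperpositionError,
    correspond,
    read_pdb,
    read_pdb_models,
    resolve_selection,
    superpose_kabsch,
    write_pdb,
    write_pdb_models,
)

MINIMAL_WATER_PDB = """\
HETATM    1  O   HOH W   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  H1  HOH W   1       0.760   0.590   0.000  1.00  0.00           H
HETATM    3  H2  HOH W   1      -0.760   0.590   0.000  1.00  0.00           H
END
"""


class TestReadPDB:
    def test_minimal_water(self, tmp_path):
        p = tmp_path / "w.pdb"
        p.write_text(MINIMAL_WATER_PDB)
        model = read_pdb(p, {})
        assert len(model.waters.residues()) == 1
        assert len(model.waters.atoms) == 3
        heavy = [a for a in model.waters.atoms if a.is_heavy]
        assert len(heavy) == 1 and heavy[0].element == "O"

    def test_unknown_chain_raises(self, tmp_path):
        p = tmp_path / "x.pdb"
        p.write_text(
            "ATOM      1  CA  ALA Q   1       0.000   0.000   0.000  1.00  0.00           C\nEND\n"
        )
        with pytest.raises(RoleMappingError):
            read_pdb(p, {"A": "target"})

    def test_unparseable_record_reports_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       0.000   xxx     0.000  1.00  0.00           C\n"
        )
        with pytest.raises(PDBFormatError, match=":1"):
            read_pdb(p, {"A": "target"})

    def test_altloc_keeps_highest_occupancy_first_on_tie(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      3  CB AALA A   1       3.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      4  CB BALA A   1       4.000   0.000   0.000  0.50  0.00           C\n"
            "END\n"
        )
        model = read_pdb(p, {"A": "target"})
        by_name = {a.name: a for a in model.target.atoms}
        assert by_name["CA"].position[0] == pytest.approx(2.0)  # higher occupancy
        assert by_name["CB"].position[0] == pytest.approx(3.0)  # first on tie


class TestRoundTrip:
    def test_coordinates_preserved(self, toy_complex, tmp_path):
        path = tmp_path / "c.pdb"
        write_pdb(toy_complex, path)
        back = read_pdb(path, {"A": "target", "B": "ligand"})
        assert len(back.target.atoms) == len(toy_complex.target.atoms)
        assert len(back.ligand.atoms) == len(toy_complex.ligand.atoms)
        np.testing.assert_allclose(back.target.coords(), toy_complex.target.coords(), atol=5e-4)
        np.testing.assert_allclose(back.ligand.coords(), toy_complex.ligand.coords(), atol=5e-4)

    def test_empty_complex(self, tmp_path):
        empty = ComplexModel(MolecularStructure([], "t"), MolecularStructure([], "l"))
        path = tmp_path / "e.pdb"
        write_pdb(empty, path)
        body = [l for l in path.read_text().splitlines() if l.startswith(("ATOM", "HETATM"))]
        assert body == []

    def test_zn_ion_preserved(self, tmp_path):
        tgt = mk_target()
        zn = MolecularStructure(
            [mk_atom(999, "ZN", "Zn", "ZN", 200, "A", (1.0, 2.0, 3.0), Role.ION)], "ions"
        )
        model = ComplexModel(tgt, mk_peptide(), ions=zn)
        path = tmp_path / "zn.pdb"
        write_pdb(model, path)
        text = path.read_text()
        assert any(l.startswith("HETATM") and " ZN " in l for l in text.splitlines())
        back = read_pdb(path, {"A": "target", "B": "ligand"})
        assert len(back.ions.atoms) == 1
        np.testing.assert_allclose(back.ions.atoms[0].position, [1.0, 2.0, 3.0], atol=5e-4)

    def test_multi_model_round_trip(self, toy_complex, tmp_path):
        shifted = toy_complex.transformed(RigidTransform(np.eye(3), np.array([1.0, 0, 0])))
        path = tmp_path / "mm.pdb"
        write_pdb_models([toy_complex, shifted], path)
        models = read_pdb_models(path, {"A": "target", "B": "ligand"})
        assert len(models) == 2
        delta = models[1].ligand.coords() - models[0].ligand.coords()
        np.testing.assert_allclose(delta, np.tile([1.0, 0.0, 0.0], (len(delta), 1)), atol=1e-3)


class TestSelections:
    def test_all_heavy_on_lone_water(self, tmp_path):
        p = tmp_path / "w.pdb"
        p.write_text(MINIMAL_WATER_PDB)
        model = read_pdb(p, {})
        sel = resolve_selection(model, AtomSelection.all_heavy(), Role.WATER)
        assert len(sel.indices) == 1

    def test_calpha_counts_residues(self, toy_complex):
        sel = resolve_selection(toy_complex, AtomSelection.calpha(), Role.LIGAND)
        assert len(sel.indices) == len(toy_complex.ligand.residues())

    def test_n_terminal_k_restricts_residues(self):
        pep = mk_peptide(n_res=10)
        model = ComplexModel(mk_target(), pep)
        sel = resolve_selection(model, AtomSelection.n_terminal(5), Role.LIGAND)
        picked = {pep.atoms[i].residue_index for i in sel.indices}
        assert picked == {1, 2, 3, 4, 5}
        # all heavy atoms of those residues, nothing more
        expected = sum(1 for a in pep.atoms if a.residue_index <= 5 and a.is_heavy)
        assert len(sel.indices) == expected

    def test_indices_strictly_increasing(self, toy_complex):
        sel = resolve_selection(toy_complex, AtomSelection.all_heavy(), Role.TARGET)
        assert list(sel.indices) == sorted(set(sel.indices))


class TestCorrespond:
    def test_identity_pairing(self, toy_complex):
        sel = resolve_selection(toy_complex, AtomSelection.all_heavy(), Role.LIGAND)
        ia, ib = correspond(toy_complex.ligand, toy_complex.ligand, sel)
        assert ia == ib == list(sel.indices)

    def test_symmetry_up_to_order(self, toy_complex):
        lig = toy_complex.ligand
        sel = resolve_selection(toy_complex, AtomSelection.all_heavy(), Role.LIGAND)
        ia, ib = correspond(lig, lig, sel)
        ia2, ib2 = correspond(lig, lig, sel)
        assert set(zip(ia, ib)) == set(zip(ib2, ia2))

    def test_truncated_copy_pairs_shared_residues(self):
        full = mk_peptide(n_res=10)
        model = ComplexModel(mk_target(), full)
        trunc_atoms = [a for a in full.atoms if a.residue_index <= 5]
        trunc = MolecularStructure(trunc_atoms, "trunc")
        sel = resolve_selection(model, AtomSelection.n_terminal(5), Role.LIGAND)
        ia, ib = correspond(full, trunc, sel)
        assert len(ia) == len(sel.indices)

    def test_missing_atom_named_in_error(self):
        from dataclasses import replace

        a = mk_peptide(n_res=2)
        renamed = MolecularStructure(
            [atom if atom.name != "CB" else replace(atom, name="XX") for atom in a.atoms],
            "b",
        )
        model = ComplexModel(mk_target(), a)
        sel = resolve_selection(model, AtomSelection.all_heavy(), Role.LIGAND)
        with pytest.raises(CorrespondenceError, match="CB"):
            correspond(a, renamed, sel)


def _quaternion_superpose_rmsd(mob, ref):
    """Independent oracle: Horn's closed-form quaternion solution."""
    mc = mob - mob.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    M = mc.T @ rc
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    vals, vecs = np.linalg.eigh(N)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = Rotation.from_quat([x, y, z, w]).as_matrix()
    d = mc @ R.T - rc
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


class TestSuperpose:
    def test_identity(self, toy_complex):
        tr = superpose_kabsch(toy_complex, toy_complex, AtomSelection.calpha())
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tr.translation, 0.0, atol=1e-9)

    def test_exact_recovery_of_rigid_motion(self, toy_complex):
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        moved = toy_complex.transformed(RigidTransform(R, t))
        tr = superpose_kabsch(moved, toy_complex, AtomSelection.calpha())
        fitted = moved.transformed(tr)
        np.testing.assert_allclose(
            fitted.target.coords(), toy_complex.target.coords(), atol=1e-9
        )

    def test_matches_quaternion_oracle_under_noise(self, toy_complex):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(10, 3)) * 5.0
        R = Rotation.random(random_state=rng).as_matrix()
        mob = ref @ R.T + rng.normal(scale=0.1, size=(10, 3)) + np.array([4.0, -2.0, 1.0])
        atoms_ref = [mk_atom(i, "CA", "C", "ALA", i + 1, "A", p, Role.TARGET) for i, p in enumerate(ref)]
        atoms_mob = [mk_atom(i, "CA", "C", "ALA", i + 1, "A", p, Role.TARGET) for i, p in enumerate(mob)]
        lig = mk_peptide()
        cm_ref = ComplexModel(MolecularStructure(atoms_ref, "r"), lig)
        cm_mob = ComplexModel(MolecularStructure(atoms_mob, "m"), lig)
        tr = superpose_kabsch(cm_mob, cm_ref, AtomSelection.calpha())
        fitted = tr.apply(mob)
        d = fitted - ref
        ours = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
        oracle = _quaternion_superpose_rmsd(mob, ref)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_optimality_under_perturbation(self, toy_complex):
        rng = np.random.default_rng(5)
        R = Rotation.random(random_state=rng).as_matrix()
        moved = toy_complex.transformed(RigidTransform(R, np.array([2.0, 1.0, -3.0])))
        # distort so the optimum is not exactly zero
        noisy = ComplexModel(
            MolecularStructure(
                [
                    mk_atom(a.serial, a.name, a.element, a.residue_name, a.residue_index,
                            a.chain_id, a.position + rng.normal(scale=0.2, size=3), a.role)
                    for a in moved.target.atoms
                ],
                "noisy",
            ),
            moved.ligand,
        )
        tr = superpose_kabsch(noisy, toy_complex, AtomSelection.calpha())
        ca = [i for i, a in enumerate(noisy.target.atoms) if a.name == "CA"]
        ref = toy_complex.target.coords(ca)
        best = np.sqrt(np.mean(np.sum((tr.apply(noisy.target.coords(ca)) - ref) ** 2, axis=1)))
        for _ in range(20):
            pert = Rotation.from_rotvec(rng.normal(scale=0.02, size=3)).as_matrix()
            worse_tr = RigidTransform(pert @ tr.rotation, tr.translation)
            worse = np.sqrt(
                np.mean(np.sum((worse_tr.apply(noisy.target.coords(ca)) - ref) ** 2, axis=1))
            )
            assert worse >= best - 1e-12

    def test_too_few_pairs_raises(self):
        atoms = [mk_atom(i, "CA", "C", "ALA", i + 1, "A", (i, 0, 0), Role.TARGET) for i in range(2)]
        cm = ComplexModel(MolecularStructure(atoms, "a"), mk_peptide())
        with pytest.raises(SuperpositionError):
            superpose_kabsch(cm, cm, AtomSelection.calpha())

    def test_collinear_raises(self):
        atoms = [mk_atom(i, "CA", "C", "ALA", i + 1, "A", (i * 3.8, 0, 0), Role.TARGET) for i in range(5)]
        cm = ComplexModel(MolecularStructure(atoms, "a"), mk_peptide())
        with pytest.raises(SuperpositionError):
            superpose_kabsch(cm, cm, AtomSelection.calpha())


class TestRigidTransform:
    def test_apply_then_invert_recovers(self):
        rng = np.random.default_rng(8)
        R = Rotation.random(random_state=rng).as_matrix()
        tr = RigidTransform(R, rng.normal(size=3))
        pts = rng.normal(size=(20, 3))
        np.testing.assert_allclose(tr.inverse().apply(tr.apply(pts)), pts, atol=1e-9)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
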