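import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fragdecomp import (
    FixtureSpec,
    build_complex,
    build_peptide,
    extend_protofibril,
    kabsch_superpose,
    read_pdb,
    write_pdb,
)
from fragdecomp.structure_io import PDBParseError, assign_parameters, load_parameter_table


class TestReadPdb:
    def test_tripeptide_parses_one_chain_three_protein_residues(self, tripeptide, tmp_path):
        path = tmp_path / "tri.pdb"
        write_pdb(tripeptide, path)
        model = read_pdb(path)
        assert list(model.chains) == ["A"]
        assert [r.molecule_class for r in model.residues] == ["protein"] * 3

    def test_empty_structure_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(PDBParseError):
            read_pdb(path)

    def test_ligand_classification(self, small_complex, tmp_path):
        path = tmp_path / "cplx.pdb"
        write_pdb(small_complex, path)
        model = read_pdb(path, ligand_resnames={"LIG"})
        assert len(model.ligand_residues()) == 1
        assert len(model.water_residues()) == 3

    def test_malformed_atom_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.pdb"
        good = "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N"
        bad = "ATOM      2  CA  GLY A   1       x.xxx   0.000   0.000  1.00  0.00           C"
        path.write_text(good + "\n" + bad + "\nEND\n")
        with pytest.raises(PDBParseError, match="line 2"):
            read_pdb(path)

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        lines = [
            "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N",
            "ATOM      2  CA AGLY A   1       1.000   0.000   0.000  0.30  0.00           C",
            "ATOM      3  CA BGLY A   1       2.000   0.000   0.000  0.70  0.00           C",
            "ATOM      4  C   GLY A   1       3.000   0.000   0.000  1.00  0.00           C",
            "END",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_pdb(path)
        ca = model.residues[0].atom("CA")
        assert ca.coords[0] == pytest.approx(2.0)
        assert len(model.residues[0].atoms) == 3

    def test_roundtrip_preserves_coords_and_assignments(self, small_complex, tmp_path):
        path = tmp_path / "rt.pdb"
        write_pdb(small_complex, path)
        model = read_pdb(path, ligand_resnames={"LIG"})
        assert len(model) == len(small_complex)
        for a, b in zip(small_complex.atoms, model.atoms):
            assert np.allclose(a.coords, b.coords, atol=1e-3)
            assert (a.name, a.res_name, a.chain_id, a.res_seq) == (
                b.name,
                b.res_name,
                b.chain_id,
                b.res_seq,
            )
        for r, r2 in zip(small_complex.residues, model.residues):
            assert r.molecule_class == r2.molecule_class


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        t = kabsch_superpose(pts, pts)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(t.translation, 0.0, atol=1e-10)
        assert t.fit_rmsd == pytest.approx(0.0, abs=1e-10)

    def test_pure_translation(self):
        pts = np.random.default_rng(1).normal(size=(5, 3))
        t = kabsch_superpose(pts, pts + np.array([0.0, 0.0, 4.8]))
        assert np.allclose(t.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(t.translation, [0.0, 0.0, 4.8], atol=1e-10)
        assert t.fit_rmsd < 1e-10

    def test_recovers_planted_30deg_z_rotation(self):
        theta = math.radians(30.0)
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0.0],
                [math.sin(theta), math.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        pts = np.random.default_rng(2).normal(size=(5, 3))
        t = kabsch_superpose(pts, pts @ rot.T)
        assert np.allclose(t.rotation, rot, atol=1e-8)
        assert t.fit_rmsd < 1e-8

    @pytest.mark.parametrize(
        "mobile",
        [
            np.zeros((2, 3)),  # too few points
            np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0])),  # collinear
        ],
    )
    def test_degenerate_inputs_raise(self, mobile):
        with pytest.raises(ValueError):
            kabsch_superpose(mobile, mobile + 1.0)

    def test_optimality_beats_random_transforms(self):
        rng = np.random.default_rng(3)
        mobile = rng.normal(size=(8, 3))
        target = rng.normal(size=(8, 3))
        best = kabsch_superpose(mobile, target).fit_rmsd
        for _ in range(100):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = rng.uniform(0, 2 * math.pi)
            k = np.array(
                [
                    [0, -axis[2], axis[1]],
                    [axis[2], 0, -axis[0]],
                    [-axis[1], axis[0], 0],
                ]
            )
            rot = np.eye(3) + math.sin(ang) * k + (1 - math.cos(ang)) * (k @ k)
            moved = mobile @ rot.T + rng.normal(size=3)
            rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
            assert best <= rmsd + 1e-12

    @settings(derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 2**31 - 1),
        angle=st.floats(-math.pi, math.pi),
    )
    def test_recovers_arbitrary_planted_rigid_motion(self, seed, angle):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(7, 3)) * 5.0
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        k = np.array(
            [
                [0, -axis[2], axis[1]],
                [axis[2], 0, -axis[0]],
                [-axis[1], axis[0], 0],
            ]
        )
        rot = np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)
        shift = rng.normal(size=3) * 10.0
        t = kabsch_superpose(pts, pts @ rot.T + shift)
        assert np.allclose(t.rotation, rot, atol=1e-7)
        assert t.fit_rmsd < 1e-7


class TestExtendProtofibril:
    def test_translational_trimer_to_pentamer_offsets(self):
        model = build_peptide(
            FixtureSpec(sequence=("GLY", "ALA", "GLY"), n_chains=3, chain_rise=4.8)
        )
        grown = extend_protofibril(model, 5)
        chains = grown.protein_chains()
        assert len(chains) == 5
        first = np.array([a.coords for r in chains["A"] for a in r.atoms])
        for cid, expected_z in zip(list(chains)[3:], (14.4, 19.2)):
            coords = np.array([a.coords for r in chains[cid] for a in r.atoms])
            assert np.allclose(coords - first, [0.0, 0.0, expected_z], atol=1e-6)

    def test_same_count_returns_unchanged(self):
        model = build_peptide(FixtureSpec(sequence=("GLY", "GLY"), n_chains=3))
        out = extend_protofibril(model, 3)
        assert np.allclose(
            [a.coords for a in out.atoms], [a.coords for a in model.atoms]
        )

    def test_screw_dimer_to_trimer_matches_analytic_operator(self):
        twist, rise = 10.0, 4.8
        model = build_peptide(
            FixtureSpec(
                sequence=("GLY", "ALA"), n_chains=2, chain_twist=twist, chain_rise=rise
            )
        )
        grown = extend_protofibril(model, 3)
        chains = grown.protein_chains()
        third = list(chains)[-1]
        first = np.array([a.coords for r in chains["A"] for a in r.atoms])
        t = math.radians(2 * twist)
        rot = np.array(
            [
                [math.cos(t), -math.sin(t), 0.0],
                [math.sin(t), math.cos(t), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        expected = first @ rot.T + np.array([0.0, 0.0, 2 * rise])
        got = np.array([a.coords for r in chains[third] for a in r.atoms])
        assert np.allclose(got, expected, atol=1e-6)

    def test_replicated_chains_conserve_atom_count(self):
        model = build_peptide(FixtureSpec(sequence=("ALA", "GLY", "SER"), n_chains=2))
        grown = extend_protofibril(model, 6)
        counts = {
            cid: sum(len(r.atoms) for r in residues)
            for cid, residues in grown.protein_chains().items()
        }
        assert len(set(counts.values())) == 1
        assert len(counts) == 6

    def test_mismatched_sequences_raise(self):
        a = build_peptide(FixtureSpec(sequence=("GLY", "GLY"), n_chains=1))
        b = build_peptide(FixtureSpec(sequence=("ALA", "GLY"), n_chains=1))
        for res in b.residues:
            res.chain_id = "B"
            for at in res.atoms:
                at.chain_id = "B"
        a.residues.extend(b.residues)
        with pytest.raises(ValueError, match="sequence"):
            extend_protofibril(a, 4)

    def test_shrinking_raises(self):
        model = build_peptide(FixtureSpec(sequence=("GLY", "GLY"), n_chains=3))
        with pytest.raises(ValueError):
            extend_protofibril(model, 2)


class TestParameterTable:
    def test_table_overrides_defaults(self, tripeptide, tmp_path):
        path = tmp_path / "params.csv"
        path.write_text(
            "res_name,atom_name,charge,lj_sigma,lj_epsilon\n"
            "GLY,CA,0.25,3.5,0.11\n"
        )
        table = load_parameter_table(path)
        assign_parameters(tripeptide, table)
        ca = tripeptide.residues[0].atom("CA")
        n = tripeptide.residues[0].atom("N")
        assert (ca.partial_charge, ca.lj_sigma, ca.lj_epsilon) == (0.25, 3.5, 0.11)
        assert n.partial_charge == 0.0
        assert n.lj_sigma > 0  # built-in per-element default

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("res_name,atom_name,charge\nGLY,CA,0.1\n")
        with pytest.raises(ValueError, match="lj_sigma"):
            load_parameter_table(path)
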