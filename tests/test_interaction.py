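import math

import numpy as np
import pytest

from fragdecomp import (
    ClassicalBackend,
    FixtureSpec,
    build_complex,
    classical_cross_energy,
    fragment_chain,
    fragment_interaction,
    fragment_waters,
    solvent_interaction,
    three_body_correction,
    total_fibril_interaction,
)
from fragdecomp.backends import EnergyBackend
from fragdecomp.constants import COULOMB_CONSTANT
from fragdecomp.fragmentation import Fragment
from fragdecomp.interaction import InteractionRecord, analyze_complex, average_summaries
from conftest import make_atom, random_complex_spec


class TotalOnlyBackend(EnergyBackend):
    """Classical backend restricted to the supramolecular route."""

    method_label = "classical-total-only"
    supports_total_energy = True

    def total_energy(self, atoms):
        return ClassicalBackend().total_energy(atoms)


class StubBackend(EnergyBackend):
    """Returns preset per-fragment energies through the cross route."""

    method_label = "stub"
    supports_cross_interaction = True

    def __init__(self, table):
        self.table = table
        self.calls = 0

    def cross_energy(self, atoms_a, atoms_b):
        self.calls += 1
        key = (atoms_a[0].chain_id, atoms_a[0].res_seq)
        return self.table[key]


def simple_fragment(fid, chain, seq, charge=0.0, coords=(0.0, 0.0, 0.0)):
    return Fragment(
        fragment_id=fid,
        core_atoms=[
            make_atom("X", coords=coords, charge=charge, chain_id=chain, res_seq=seq)
        ],
        source_residues=[(chain, seq, "GLY")],
    )


class TestFragmentInteraction:
    def test_zero_parameter_fragment_gives_zero(self):
        frag = simple_fragment("A:1", "A", 1)
        lig = [make_atom("L1", coords=(5, 0, 0), charge=1.0)]
        rec = fragment_interaction(frag, lig, ClassicalBackend())
        assert rec.delta_e == 0.0

    def test_point_charge_pair_closed_form(self):
        frag = simple_fragment("A:1", "A", 1, charge=0.5)
        lig = [make_atom("L1", coords=(4.0, 0, 0), charge=-0.5)]
        rec = fragment_interaction(frag, lig, ClassicalBackend())
        assert rec.delta_e == pytest.approx(
            COULOMB_CONSTANT * 0.5 * -0.5 / 4.0, abs=1e-12
        )
        assert rec.components is not None
        assert sum(rec.components) == pytest.approx(rec.delta_e, abs=1e-12)

    def test_supramolecular_route_matches_cross_route(self, small_complex):
        lig = small_complex.ligand_atoms()
        frags = fragment_chain(small_complex, "A", cap_params="zero")
        for frag in frags:
            direct = fragment_interaction(frag, lig, ClassicalBackend()).delta_e
            supra = fragment_interaction(frag, lig, TotalOnlyBackend()).delta_e
            assert supra == pytest.approx(direct, abs=1e-10)

    def test_backend_failure_carries_fragment_context(self):
        frag = simple_fragment("A:7", "A", 7, charge=1.0)
        lig = [make_atom("L1", coords=(0, 0, 0), charge=1.0)]  # overlap
        with pytest.raises(ValueError, match="A:7"):
            fragment_interaction(frag, lig, ClassicalBackend())


class TestAggregation:
    def test_empty_fragment_list_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="no fragments"):
            summary = total_fibril_interaction([], [make_atom("L")], ClassicalBackend())
        assert summary.delta_e_fibril == 0.0

    def test_stub_energies_sum(self):
        frags = [simple_fragment("A:1", "A", 1), simple_fragment("A:2", "A", 2)]
        backend = StubBackend({("A", 1): -1.5, ("A", 2): -2.5})
        summary = total_fibril_interaction(frags, [make_atom("L")], backend)
        assert summary.delta_e_fibril == pytest.approx(-4.0)

    def test_fragment_sum_reproduces_direct_cross_energy(self, small_complex):
        lig = small_complex.ligand_atoms()
        frags = []
        for cid in small_complex.protein_chains():
            frags.extend(fragment_chain(small_complex, cid, cap_params="zero"))
        summary = total_fibril_interaction(frags, lig, ClassicalBackend())
        protein_atoms = [
            a
            for r in small_complex.residues
            if r.molecule_class == "protein"
            for a in r.atoms
        ]
        direct = classical_cross_energy(protein_atoms, lig)[0]
        assert summary.delta_e_fibril == pytest.approx(direct, abs=1e-9)

    def test_tip3p_water_against_unit_charge_closed_form(self):
        half = math.radians(104.52 / 2.0)
        o = np.array([3.0, 0.0, 0.0])
        h1 = o + 0.9572 * np.array([math.cos(half), math.sin(half), 0.0])
        h2 = o + 0.9572 * np.array([math.cos(half), -math.sin(half), 0.0])
        water = Fragment(
            fragment_id="W:1",
            core_atoms=[
                make_atom("O", "O", o, charge=-0.834, res_name="HOH", chain_id="W"),
                make_atom("H1", "H", h1, charge=0.417, res_name="HOH", chain_id="W"),
                make_atom("H2", "H", h2, charge=0.417, res_name="HOH", chain_id="W"),
            ],
            source_residues=[("W", 1, "HOH")],
        )
        probe = [make_atom("Q", coords=(0, 0, 0), charge=1.0)]
        expected = COULOMB_CONSTANT * (
            -0.834 / np.linalg.norm(o)
            + 0.417 / np.linalg.norm(h1)
            + 0.417 / np.linalg.norm(h2)
        )
        de, records = solvent_interaction([water], probe, ClassicalBackend())
        assert de == pytest.approx(expected, abs=1e-10)
        assert len(records) == 1

    def test_doubling_identical_waters_doubles_solvent_term(self):
        model = build_complex(
            FixtureSpec(
                sequence=("GLY", "GLY"),
                ligand="two_atom_probe",
                n_waters=2,
                water_radii=(4.0, 4.5),
                seed=3,
                planted_charges={("L", 1, "L1"): 1.0, ("W", 1, "O"): -0.5},
            )
        )
        waters, _ = fragment_waters(model, math.inf)
        lig = model.ligand_atoms()
        de_one, _ = solvent_interaction(waters[:1], lig, ClassicalBackend())
        de_two, _ = solvent_interaction(waters[:1] * 2, lig, ClassicalBackend())
        assert de_two == pytest.approx(2 * de_one, rel=1e-12)


class TestThreeBodyCorrection:
    def rec(self, fid, residues, de):
        return InteractionRecord(fid, residues, de)

    def test_stub_arithmetic(self):
        mono = [
            self.rec("A:1", [("A", 1, "GLY")], -2.0),
            self.rec("A:2", [("A", 2, "GLY")], -2.0),
        ]
        di = [self.rec("A:1-2", [("A", 1, "GLY"), ("A", 2, "GLY")], -5.0)]
        assert three_body_correction(mono, di) == pytest.approx(-1.0)

    def test_additive_backend_with_inert_caps_gives_zero(self, small_complex):
        lig = small_complex.ligand_atoms()
        backend = ClassicalBackend()
        for cid in small_complex.protein_chains():
            mono = fragment_chain(small_complex, cid, cap_params="zero")
            di = fragment_chain(
                small_complex, cid, order="dipeptide", cap_params="zero"
            )
            mono_r = [fragment_interaction(f, lig, backend) for f in mono]
            di_r = [fragment_interaction(f, lig, backend) for f in di]
            assert abs(three_body_correction(mono_r, di_r)) < 1e-9

    def test_invariant_to_enumeration_order(self):
        rng = np.random.default_rng(4)
        mono = [self.rec(f"A:{i}", [("A", i, "GLY")], rng.normal()) for i in range(1, 6)]
        di = [
            self.rec(
                f"A:{i}-{i + 1}",
                [("A", i, "GLY"), ("A", i + 1, "GLY")],
                rng.normal(),
            )
            for i in range(1, 5)
        ]
        base = three_body_correction(mono, di)
        perm = three_body_correction(mono[::-1], di[::-1])
        assert perm == pytest.approx(base, abs=1e-12)

    def test_misaligned_windows_raise(self):
        mono = [self.rec("A:1", [("A", 1, "GLY")], -1.0)]
        di = [self.rec("A:5-6", [("A", 5, "GLY"), ("A", 6, "GLY")], -3.0)]
        with pytest.raises(ValueError, match="no matching"):
            three_body_correction(mono, di)


class TestSummary:
    def test_total_is_sum_of_parts(self, small_complex):
        lig = small_complex.ligand_atoms()
        frags = []
        di = []
        for cid in small_complex.protein_chains():
            frags.extend(fragment_chain(small_complex, cid, cap_params="zero"))
            di.extend(
                fragment_chain(small_complex, cid, order="dipeptide", cap_params="zero")
            )
        waters, _ = fragment_waters(small_complex, math.inf)
        summary = analyze_complex(
            frags, lig, ClassicalBackend(), water_fragments=waters,
            dipeptide_fragments=di,
        )
        assert summary.delta_e_total == pytest.approx(
            summary.delta_e_fibril
            + summary.delta_e_solvent
            + summary.three_body_correction,
            abs=1e-12,
        )
        summary.validate()

    def test_exports_are_deterministic(self, small_complex, tmp_path):
        lig = small_complex.ligand_atoms()
        frags = fragment_chain(small_complex, "A")
        outputs = []
        for i in range(2):
            summary = total_fibril_interaction(frags, lig, ClassicalBackend())
            p = tmp_path / f"out{i}.tsv"
            summary.to_tsv(p)
            outputs.append(p.read_bytes())
        assert outputs[0] == outputs[1]
        payload = summary.to_json(tmp_path / "out.json")
        assert payload["delta_e_fibril"] == pytest.approx(summary.delta_e_fibril)

    def test_average_summaries_mean_and_sd(self):
        lig = [make_atom("L")]
        summaries = []
        for de in (-1.0, -3.0):
            frag = simple_fragment("A:1", "A", 1)
            s = total_fibril_interaction([frag], lig, StubBackend({("A", 1): de}))
            summaries.append(s)
        stats = average_summaries(summaries)
        mean, sd = stats["A:1"]
        assert mean == pytest.approx(-2.0)
        assert sd == pytest.approx(math.sqrt(2.0))
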