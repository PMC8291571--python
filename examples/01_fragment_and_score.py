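"""Fragment a synthetic fibril–ligand complex and decompose the energy.

Builds a two-filament peptide with a charged probe ligand and explicit
waters, cleaves it into hydrogen-capped amino-acid fragments, and sums
the per-fragment ligand interaction energies into fibril, solvent and
total terms.  The final check shows the scheme's defining property: with
inert caps and the exact pairwise backend, the fragment sum equals the
direct protein–ligand interaction energy to machine precision.
"""

import math

from fragdecomp import (
    ClassicalBackend,
    FixtureSpec,
    build_complex,
    classical_cross_energy,
    fragment_chain,
    fragment_waters,
    residue_decomposition,
)
from fragdecomp.interaction import analyze_complex

spec = FixtureSpec(
    sequence=("GLY", "ALA", "SER", "ASP", "LYS"),
    n_chains=2,
    chain_rise=4.8,
    ligand="ring_probe",
    n_waters=6,
    seed=42,
    planted_charges={
        ("A", 3, "O"): -0.4,
        ("A", 4, "CA"): 0.3,
        ("B", 5, "N"): -0.2,
        ("L", 1, "L1"): 0.6,
        ("W", 2, "O"): -0.3,
    },
    planted_lj={("L", 1, "L2"): (3.2, 0.15), ("A", 4, "CB"): (3.4, 0.1)},
)
model = build_complex(spec)
ligand = model.ligand_atoms()
backend = ClassicalBackend()

fragments, dipeptides = [], []
for chain_id in model.protein_chains():
    fragments.extend(fragment_chain(model, chain_id, scheme="hydrogen", cap_params="zero"))
    dipeptides.extend(
        fragment_chain(model, chain_id, order="dipeptide", cap_params="zero")
    )
waters, _ = fragment_waters(model, cutoff=math.inf)

summary = analyze_complex(
    fragments, ligand, backend, water_fragments=waters, dipeptide_fragments=dipeptides
)

print(f"fragments: {len(fragments)} peptide + {len(waters)} water")
print(f"ΔE_fibril  = {summary.delta_e_fibril:10.4f} kcal/mol")
print(f"ΔE_solvent = {summary.delta_e_solvent:10.4f} kcal/mol")
print(f"ΔE_total   = {summary.delta_e_total:10.4f} kcal/mol")
print(f"3-body     = {summary.three_body_correction:10.2e} kcal/mol (pairwise backend: ~0)")

print("\nmost stabilizing residues (ΔE per residue, kcal/mol):")
for row in residue_decomposition(summary, top_n=3)[:3]:
    print(f"  {row.rank}. {row.res_name}{row.res_seq} filament {row.filament_id}: "
          f"{row.energy:8.4f}")

protein_atoms = [
    a for r in model.residues if r.molecule_class == "protein" for a in r.atoms
]
direct = classical_cross_energy(protein_atoms, ligand)[0]
print(f"\nfragment sum vs direct supramolecular energy: "
      f"gap = {abs(summary.delta_e_fibril - direct):.2e} kcal/mol")
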