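"""Write QM input decks for fragments and parse engine results back.

The electronic-structure step runs outside this package: per fragment F
the deck writer emits F+ligand, F, and (once) ligand-alone geometries
with additive charge bookkeeping at the default M06-2X/6-31+G** level.
Here a mock engine stamps each deck with a final energy so the parser's
hartree → kcal/mol aggregation can be shown end to end.
"""

import tempfile
from pathlib import Path

from fragdecomp import (
    FixtureSpec,
    QmJobSpec,
    build_complex,
    fragment_chain,
    parse_qm_results,
    write_qm_decks,
)
from fragdecomp.backends import QmDeckBackend
from fragdecomp.interaction import total_fibril_interaction

model = build_complex(
    FixtureSpec(sequence=("ASP", "GLY", "LYS"), ligand="two_atom_probe", seed=1)
)
fragments = fragment_chain(model, "A", scheme="methylamide")

workdir = Path(tempfile.mkdtemp())
manifest = write_qm_decks(
    fragments, model.ligand_atoms(), QmJobSpec(), workdir / "decks"
)
print(f"{len(manifest)} fragments -> {len(list((workdir / 'decks').glob('*.qmin')))} decks")
for fid, decks in manifest.items():
    print(f"  {fid}: {decks['complex']}")

# mock engine: E_complex slightly below E_frag + E_ligand -> attraction
results = workdir / "results"
results.mkdir()
for i, decks in enumerate(manifest.values()):
    for role, e_hartree in (
        ("complex", -200.010 - i * 0.001),
        ("fragment", -150.0),
        ("ligand", -50.0),
    ):
        stem = decks[role].rsplit(".", 1)[0]
        (results / f"{stem}.out").write_text(f"FINAL ENERGY: {e_hartree} hartree\n")

energies, gaps = parse_qm_results(manifest, results)
backend = QmDeckBackend(energies)
summary = total_fibril_interaction(fragments, model.ligand_atoms(), backend)
print(f"\nmissing results: {gaps or 'none'}")
for rec in summary.records:
    print(f"  ΔE({rec.fragment_id}) = {rec.delta_e:8.3f} kcal/mol")
print(f"ΔE_fibril = {summary.delta_e_fibril:.3f} kcal/mol "
      "(supramolecular differences, hartree-converted)")
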