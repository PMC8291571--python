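# fragdecomp

Fragment-based decomposition of protein–ligand interaction energies for
amyloid fibrils.

## The problem

Binding free energies of small molecules (PET tracers, inhibitors) to
amyloid fibrils such as tau filaments are usually estimated with
force-field methods (MM-GBSA). Validating those numbers at a quantum
mechanical level is intractable for a whole fibril — but not for its
pieces. `fragdecomp` implements a fragmentation scheme for exactly this:
the fibril is cut along its peptide bonds, each amino acid (or
overlapping dipeptide) is closed into a small molecule by synthetic
caps, and the fibril–ligand interaction energy is assembled as the sum
of fragment–ligand supramolecular energies

```
ΔE_fibril  = Σ_i [ E(frag_i ∪ L) − E(frag_i) − E(L) ]
ΔE_solvent = Σ_w [ E(w ∪ L) − E(w) − E(L) ]        (explicit waters)
ΔE_total   = ΔE_fibril + ΔE_solvent (+ three-body correction)
```

evaluated on the fixed complex geometry. Each fragment is small enough
for DFT (default level M06-2X/6-31+G\*\*), and the per-fragment terms
double as a residue-wise decomposition of the binding energy.

The package covers the workflow around that scheme:

- **structure handling** — PDB I/O (via gemmi), molecule classification,
  Kabsch superposition, and protofibril extension by replicating
  filaments along the fibril growth axis (trimer → pentamer);
- **fragmentation** — peptide-bond detection, hydrogen (link-atom) or
  N-methylamide/acetyl capping, explicit-water fragments with a
  ligand-distance cutoff, formal-charge bookkeeping;
- **energy backends** — an exact classical Coulomb + Lennard-Jones
  backend (the desk-scale oracle), and a QM deck writer / result parser
  for external electronic-structure engines;
- **aggregation & reporting** — fibril/solvent/total sums, dipeptide
  three-body corrections, residue-wise decomposition tables, MM-GBSA
  component bookkeeping (ΔG_binding = ΔE_vdw + ΔE_elec + ΔG_GB + ΔG_SA)
  and the ΔG = RT·ln(Ki) conversion;
- **fixtures** — seeded ideal-geometry peptides, probe ligands and
  waters with planted parameters, so every property is testable with
  closed-form expectations and no downloads.

Because the classical backend is strictly pairwise additive, monopeptide
fragmentation with inert caps must reproduce the direct protein–ligand
cross energy *exactly*; this identity is the package's central
correctness guarantee and is enforced to ≤1e-9 kcal/mol in the tests.

Units are Å and kcal/mol throughout.

## Worked example

`examples/01_fragment_and_score.py` builds a two-filament pentapeptide
complex with a charged ring probe and six waters, fragments it with
hydrogen caps, and aggregates the interaction energy:

```
fragments: 10 peptide + 6 water
ΔE_fibril  =    -8.3541 kcal/mol
ΔE_solvent =    -6.8653 kcal/mol
ΔE_total   =   -15.2193 kcal/mol
3-body     =   0.00e+00 kcal/mol (pairwise backend: ~0)

most stabilizing residues (ΔE per residue, kcal/mol):
  1. SER3 filament A: -11.1425
  2. HOH2 filament W:  -6.8653
  3. LYS5 filament B:  -6.3257

fragment sum vs direct supramolecular energy: gap = 0.00e+00 kcal/mol
```

ΔE_fibril is the sum of the ten fragment–ligand terms, ΔE_solvent the
sum over the waters, and the final line verifies the fragmentation
identity against the unfragmented complex. The other examples cover
protofibril extension (`02`), QM deck generation and result parsing
(`03`), and component-table auditing with Ki conversion (`04`).

A thin CLI wraps the same library calls:

```sh
fragdecomp run --complex complex.pdb --ligand-resname LIG \
    --scheme hcap --order di --backend classical --out results/
fragdecomp extend --pdb trimer.pdb --copies 5 --out pentamer.pdb
fragdecomp check-table --table components.csv
```

## QM deck format

Decks are plain text: a `# fragdecomp qm deck v1` header, `method`,
`basis`, `charge`, `multiplicity` lines, then `geometry` … `end` with
one `element x y z` row per atom (Å). The result parser expects one
`<deck stem>.out` file per deck containing a line
`FINAL ENERGY: <float> hartree`; energies are converted at
627.509474 kcal/mol per hartree. Counterpoise/BSSE correction is not
applied and reports say so.

## Reference data

`fragdecomp.datasets` bundles published binding free-energy component
tables and fragment-scheme interaction totals for the AV-1451 tau
tracer in fibrils from Alzheimer's, CTE and Pick's disease patients
(main binding sites and the AD cryptic sites C1/C3). These are inputs
for the bookkeeping layer — re-aggregation, sum auditing, Ki
conversion — not outputs of this package.

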