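# Methods

## The fragmentation scheme

A fibril–ligand complex on a fixed geometry (typically a single MD
snapshot) is decomposed by cutting every peptide bond C_i–N_{i+1} and
closing each piece into a neutral-shell molecule with synthetic caps.
The fibril–ligand interaction energy is then the sum of per-fragment
supramolecular energies ΔE_i = E(frag_i ∪ L) − E(frag_i) − E(L), all in
kcal/mol on coordinates in Å. The same construction applied to explicit
waters near the ligand yields ΔE_solvent, and

    ΔE_total = ΔE_fibril + ΔE_solvent (+ three-body correction).

The scheme's value is that each fragment is small enough for DFT-level
evaluation while the sum remains interpretable residue by residue.
Geometries are never relaxed: every energy refers to the complex
snapshot as given. Multi-snapshot averaging is supported as a thin loop
(`average_summaries`, mean ± sd per fragment); the default is a single
snapshot.

### Peptide-bond detection

A bond is declared between consecutive residues when d(C_i, N_{i+1}) ≤
1.8 Å. This covers the standard amide range (1.32–1.35 Å) with a wide
safety margin and treats anything longer as a chain break, which is
warned about and splits the fragmentation windows. A residue missing
its backbone C or N is an error, not a silent skip.

### Capping

Two modes close the cut bonds:

- **hydrogen** (link-atom): the atom across the cut is replaced by H
  along the original bond vector, at 1.09 Å from C (when it replaces N)
  and 1.01 Å from N (when it replaces C). These lengths are the
  standard link-atom convention; the placement rule is exact and
  deterministic.
- **methylamide**: residue i receives an N-methylamide cap (N and
  methyl C reuse the original N_{i+1} / CA_{i+1} positions; the amide H
  is synthesized in-plane trans to the carbonyl; three methyl H are
  placed tetrahedrally at 1.09 Å in a fixed reference frame), and
  residue i+1 receives the symmetric acetyl cap built on C_i/O_i/CA_i.
  Reusing the neighbour heavy-atom positions keeps the cap geometry
  faithful to the complex snapshot; only atoms that did not exist are
  synthesized.

Cap sanity is validated per fragment: every cap atom must lie within
2.0 Å of at least one heavy atom of the fragment and no closer than
0.5 Å to any other atom. In hydrogen mode the stricter form — exactly
one *core* heavy-atom anchor — is also enforced; in methylamide mode
cap atoms legitimately bond to other cap heavies (methyl H to the cap
methyl carbon), so only the attachment/clash form applies there.

Fragment net charge is the sum of standard pH-7 formal side-chain
charges of the core residues (ASP/GLU −1, LYS/ARG +1, HIS neutral as
the HIE-like default), overridable per call through `charge_rules`, for
example `{"HIS": 1}` for a protonated histidine or entries for
non-standard residues. Caps are charge-neutral by construction, so
fragment charges always re-sum to the chain's formal charge. Terminal
residues keep whatever termini the input has — fibril cores are
mid-sequence excerpts, so no zwitterion is forced. Multiplicity is 1
(closed-shell fragments).

In production runs cap atoms carry nonbonded parameters like any other
atom (they are part of the fragment's electronic structure in QM
decks): zero charge and per-element Lennard-Jones defaults. The
`cap_params="zero"` switch makes caps fully inert and exists for the
exactness oracle below; it is not a production setting.

### Dipeptide windows and the three-body correction

Dipeptide fragmentation uses overlapping windows (i, i+1). The
correction Σ_i [ΔE(di_i) − ΔE(frag_i) − ΔE(frag_{i+1})] measures
non-additivity of the fragment decomposition. For any strictly pairwise
backend with inert caps it is identically zero (the test suite asserts
≤ 1e-9 kcal/mol); with a QM backend it captures genuine three-body
polarization. Windows that span a chain break are skipped.

### Explicit solvent

Waters (HOH/WAT/TIP3 residue codes) become 3-atom neutral fragments
when their oxygen lies within a ligand-distance cutoff, default 6 Å.
No selection radius is canonical for this term; the cutoff is
configurable, excluded waters are counted, and the value used is
recorded in the output metadata. `math.inf` selects all waters.

## Energy backends

The backend contract exposes `cross_energy(A, B)` and/or
`total_energy(atoms)` in kcal/mol; the interaction layer prefers the
direct cross route and falls back to the supramolecular difference of
three totals.

**Classical backend.** Exact pairwise Coulomb + Lennard-Jones with
Lorentz–Berthelot combining (arithmetic σ, geometric ε), Coulomb
constant 332.0636 kcal·Å/(mol·e²), no cutoff, no switching, no
periodicity. Pair terms are summed in sorted order so cross(A, B) ==
cross(B, A) bitwise. Atoms closer than 1e-6 Å or missing parameters
are errors. This backend is a desk-scale oracle, not a force-field
reproduction: because it is strictly pairwise additive, monopeptide
fragmentation with inert caps must reproduce the direct protein–ligand
cross energy exactly — the headline identity the acceptance tests
enforce at ≤ 1e-9 kcal/mol. With default (LJ-carrying) caps the
fragment sum deviates from the direct energy by the cap contribution;
that gap is a reportable diagnostic, never silently dropped.

**QM deck backend.** Writes per-fragment supramolecular deck triples
(complex, fragment, ligand-once) in a stable plain-text layout with
additive charge bookkeeping, default level M06-2X/6-31+G\*\* (method and
basis are free strings). Results are parsed from `FINAL ENERGY: <float>
hartree` lines and converted at 627.509474 kcal/mol per hartree; missing
files are reported as gaps rather than raised, so partially completed
batches can be aggregated. No counterpoise/BSSE correction is applied;
reports state this. No engine runs in-process.

Default per-element LJ parameters are a deliberately small generic
table used only to give caps and unparameterized atoms something
physically shaped; any per-(residue, atom) table supplied by the user
overrides it.

## Structure handling

PDB reading goes through gemmi. Residues are classified water / ligand
(caller-supplied codes) / protein (standard amino acid with N, CA, C
backbone) / other. Alternate locations are resolved by highest
occupancy, ties to the first conformer encountered — wild PDB files
demand a rule and none is canonical. Only the first model of a
multi-model file is used (with a warning). Missing hydrogens are
tolerated at parse time; hydrogen capping synthesizes what it needs.
Residue numbering is used as given (possibly non-contiguous); internal
indices are positional and never appear in reports.

Superposition is the Kabsch algorithm (SVD with determinant sign
correction, reflections excluded). Collinear or <3-point inputs are
rejected because the rotation is under-determined there; the
degeneracy test is on the second singular value of the centered point
sets (≤ 1e-9 relative to the point-cloud norm).

Protofibril extension estimates the inter-filament operator by one
backbone-atom (N, CA, C) superposition over all consecutive chain pairs
stacked into a single correspondence — equivalent to a pair-averaged
fit and robust to side-chain disorder — then applies it repeatedly to
the terminal chain until the target filament count is reached. The
operator generalizes a screw transform (twist + rise), so both purely
translational stacks and twisted fibrils replicate correctly. Original
atoms are never moved and new chains receive fresh single-character
identifiers. The alternative — reading deposited helical parameters —
is deliberately not implemented; superposition works from coordinates
alone.

## Free-energy bookkeeping

ΔG_binding = ΔE_vdw + ΔE_elec + ΔG_GB + ΔG_SA is an exact sum in this
package; the GB/SA numerics that produce the components live in
external MM-GBSA tools and are out of scope. When auditing printed
tables, each addend was rounded to one decimal independently, so the
printed total may differ from the exact component sum by up to 0.05 per
addend plus 0.05 on the total — 0.25 kcal/mol for a four-component row.
That bound is the table-check tolerance; several bundled rows indeed
differ by exactly 0.1.

The Ki relation is implemented as ΔG = RT·ln(Ki) with Ki in mol/L at a
1 M standard state and R = 1.98720425864083e-3 kcal/(mol·K). The
round-trip with its inverse is exact to ~1e-16 relative error.

Residue-wise decomposition assigns each fragment record to its source
residue; dipeptide records are split 50/50 between their two residues
(no canonical attribution exists for overlapping windows, and the even
split conserves the total by construction). Water records land on their
own residues, so row energies always re-sum to ΔE_fibril + ΔE_solvent.
Rows are ranked ascending in energy (most stabilizing first), ties
broken by (filament, residue number) for run-to-run determinism.

## Synthetic fixtures

The fixture generator builds extended peptides with exact ideal bond
lengths (N–CA 1.46, CA–C 1.52, C–N 1.33, C=O 1.23 Å) on a planar
zig-zag with standard backbone angles, a CB for non-glycine residues,
multi-filament stacks via an explicit screw operator, rigid two-atom or
six-ring probe ligands, and TIP3P-geometry waters placed either on a
seeded jittered grid or at exact ligand distances (for cutoff tests),
always ≥ 2.5 Å from solutes and each other, with bounded placement
attempts. All randomness flows from the spec's seed; identical specs
produce bitwise-identical PDB files.

Most atoms carry zero charge and zero ε; tests plant a few explicit
carriers so every expected energy has a closed form. This
planted-parameter design is what the test suite's guarantees rest on.
What the fixtures deliberately do not emulate: realistic side-chain
rotamers, actual tau fibril geometry, conformational disorder, or
force-field-quality parameters. Passing tests therefore demonstrate
the correctness of the decomposition machinery — cleavage, capping,
bookkeeping, aggregation — not the physical accuracy of any particular
energy model on real fibrils.

## Problem sizes and numerical choices

The test and acceptance workloads use 3–8 residue chains, 1–2
filaments, 0–10 waters and 20 seeded fixture complexes — sizes at which
the exact (no-cutoff) classical backend is instantaneous and all
identities can be checked to tight absolute tolerances (1e-9 kcal/mol
for energy identities, 1e-6 Å for cap geometry, 1e-8 for rotation
recovery). Constants are pinned for bit-reproducibility: Coulomb
332.0636, hartree→kcal/mol 627.509474, R as above.

## Known limitations

- The classical backend is an oracle, not FF99SB/GAFF; production-grade
  interaction energies require the QM route.
- No BSSE/counterpoise correction; no entropy or deformation terms.
- Proline N-caps follow the standard rule (no ring-opening special
  case); disulfides are not fragmentation-aware.
- mmCIF, crystallographic symmetry and NMR ensembles beyond model 1 are
  out of scope.
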