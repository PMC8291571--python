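"""Physical constants and small lookup tables, fixed for bit-reproducibility."""

# Coulomb constant in kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0636

# Hartree → kcal/mol
HARTREE_TO_KCAL = 627.509474

# Gas constant in kcal/(mol·K)
GAS_CONSTANT_KCAL = 1.98720425864083e-3

# Residue codes treated as water on input
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3"})

STANDARD_AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL",
        # common protonation-state variants
        "HID", "HIE", "HIP", "ASH", "GLH", "LYN", "CYX",
    }
)

# Formal side-chain charges at pH 7 (HIS neutral / HIE tautomer by default).
# Overridable per call via a user charge table.
FORMAL_CHARGES = {
    "ALA": 0, "ARG": +1, "ASN": 0, "ASP": -1, "CYS": 0, "GLN": 0,
    "GLU": -1, "GLY": 0, "HIS": 0, "ILE": 0, "LEU": 0, "LYS": +1,
    "MET": 0, "PHE": 0, "PRO": 0, "SER": 0, "THR": 0, "TRP": 0,
    "TYR": 0, "VAL": 0,
    "HID": 0, "HIE": 0, "HIP": +1, "ASH": 0, "GLH": 0, "LYN": 0,
    "CYX": 0,
}

# Default per-element Lennard-Jones parameters (sigma in Å, epsilon in
# kcal/mol), a deliberately small generic table: user-supplied
# per-(residue, atom) parameter files override it.
DEFAULT_LJ = {
    "H": (2.50, 0.0157),
    "C": (3.40, 0.0860),
    "N": (3.25, 0.1700),
    "O": (3.00, 0.2100),
    "S": (3.60, 0.2500),
    "P": (3.74, 0.2000),
    "F": (3.12, 0.0610),
    "CL": (3.47, 0.2650),
    "BR": (3.60, 0.3200),
}

# Cap construction geometry (link-atom convention)
CH_BOND = 1.09  # Å, hydrogen cap replacing N across a cut C–N bond
NH_BOND = 1.01  # Å, hydrogen cap replacing C across a cut C–N bond
TETRAHEDRAL_ANGLE = 109.471220634  # degrees

# Peptide-bond detection cutoff; covers the 1.32–1.35 Å standard range
# and rejects chain breaks.
PEPTIDE_BOND_CUTOFF = 1.8  # Å
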