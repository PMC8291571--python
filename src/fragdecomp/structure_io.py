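"""PDB structure handling: parsing, writing, superposition, fibril extension.

A :class:`ProtofibrilModel` is the coordinate substrate for every other
module: atoms grouped into residues, residues into chains (filaments),
each residue classified as protein / ligand / water / other.  Reading
goes through gemmi; writing emits fixed-column PDB so that coordinates
round-trip at the format's 1e-3 Å precision.
"""

from __future__ import annotations

import copy as _copy
import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .constants import DEFAULT_LJ, STANDARD_AMINO_ACIDS, WATER_RESNAMES


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass
class AtomRecord:
    """One atom with coordinates in Å and optional nonbonded parameters.

    ``partial_charge`` (e), ``lj_sigma`` (Å) and ``lj_epsilon`` (kcal/mol)
    stay ``None`` until :func:`assign_parameters` is called.
    """

    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    insertion_code: str
    coords: np.ndarray
    occupancy: float = 1.0
    partial_charge: float | None = None
    lj_sigma: float | None = None
    lj_epsilon: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name!r}")
        if self.occupancy is not None and not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    def copy(self) -> "AtomRecord":
        new = _copy.copy(self)
        new.coords = self.coords.copy()
        return new


@dataclass
class Residue:
    chain_id: str
    res_seq: int
    insertion_code: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    molecule_class: str = "other"  # protein | ligand | water | other

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_ATOMS)

    def copy(self) -> "Residue":
        return Residue(
            self.chain_id,
            self.res_seq,
            self.insertion_code,
            self.res_name,
            [a.copy() for a in self.atoms],
            self.molecule_class,
        )


class ProtofibrilModel:
    """Atoms grouped into residues and chains, with molecule classes.

    Chains preserve file order; residue order within a chain follows the
    input and must be monotone in ``res_seq`` for protein chains.
    """

    def __init__(self, residues: Sequence[Residue]):
        self.residues: list[Residue] = list(residues)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for res in self.residues:
            out.setdefault(res.chain_id, []).append(res)
        return out

    def protein_chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for res in self.residues:
            if res.molecule_class == "protein":
                out.setdefault(res.chain_id, []).append(res)
        return out

    def ligand_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.molecule_class == "ligand"]

    def ligand_atoms(self) -> list[AtomRecord]:
        return [a for r in self.ligand_residues() for a in r.atoms]

    def water_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.molecule_class == "water"]

    def copy(self) -> "ProtofibrilModel":
        return ProtofibrilModel([r.copy() for r in self.residues])

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class RigidTransform:
    """Proper rigid-body transform ``x ↦ R·x + t`` with its fit RMSD in Å."""

    rotation: np.ndarray
    translation: np.ndarray
    fit_rmsd: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3×3")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")
        if self.fit_rmsd < 0:
            raise ValueError("fit_rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            0.0,
        )


def _classify(res_name: str, has_backbone: bool, ligand_resnames: frozenset) -> str:
    if res_name in WATER_RESNAMES:
        return "water"
    if res_name in ligand_resnames:
        return "ligand"
    if res_name in STANDARD_AMINO_ACIDS:
        return "protein" if has_backbone else "other"
    return "other"


def _prevalidate_pdb(path: Path) -> int:
    """Check coordinate columns of ATOM/HETATM lines; return record count."""
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            n_records += 1
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"line {lineno}: truncated ATOM/HETATM record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(
                    f"line {lineno}: unparseable coordinates in ATOM/HETATM record"
                ) from exc
    return n_records


def read_pdb(
    path: str | Path,
    ligand_resnames: Iterable[str] = (),
) -> ProtofibrilModel:
    """Read a PDB file into a :class:`ProtofibrilModel`.

    Residues are classified as water (HOH/WAT/TIP3), ligand (codes in
    ``ligand_resnames``), protein (standard amino acid with N/CA/C
    backbone) or other.  Alternate locations are resolved by keeping the
    highest-occupancy conformer (ties: first encountered).  Only the
    first model of a multi-model file is used, with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _prevalidate_pdb(path) == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    ligset = frozenset(ligand_resnames)

    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    if len(st) > 1:
        warnings.warn(
            f"{path}: {len(st)} models present, using the first only", stacklevel=2
        )
    model = st[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            # alt-loc resolution: per atom name keep highest occupancy,
            # first occurrence winning ties
            chosen: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = chosen.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    chosen[atom.name] = atom
            records = []
            for atom in res:  # preserve file order
                if chosen.get(atom.name) is not atom:
                    continue
                element = atom.element.name.strip()
                if not element:
                    element = "".join(c for c in atom.name if c.isalpha())[:1] or "X"
                records.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=element,
                        alt_loc=atom.altloc if atom.altloc != "\x00" else "",
                        res_name=res.name,
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        insertion_code=res.seqid.icode.strip(),
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                    )
                )
            r = Residue(
                chain_id=chain.name,
                res_seq=res.seqid.num,
                insertion_code=res.seqid.icode.strip(),
                res_name=res.name,
                atoms=records,
            )
            r.molecule_class = _classify(res.name, r.has_backbone(), ligset)
            residues.append(r)

    if not residues:
        raise PDBParseError(f"{path}: empty structure")
    return ProtofibrilModel(residues)


def write_pdb(model: ProtofibrilModel, path: str | Path) -> None:
    """Write fixed-column PDB (ATOM/HETATM/TER/END); serials renumbered."""
    path = Path(path)
    lines: list[str] = []
    serial = 0
    chains = model.chains
    for chain_id, residues in chains.items():
        for res in residues:
            record = "ATOM  " if res.molecule_class == "protein" else "HETATM"
            for a in res.atoms:
                serial += 1
                name = a.name
                # standard PDB atom-name justification
                if len(name) < 4 and len(a.element) == 1:
                    name = f" {name}"
                lines.append(
                    f"{record}{serial:5d} {name:<4s}{a.alt_loc or ' ':1s}"
                    f"{res.res_name:>3s} {chain_id[:1]:1s}{res.res_seq:4d}"
                    f"{res.insertion_code or ' ':1s}   "
                    f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          "
                    f"{a.element.upper():>2s}"
                )
        if residues and residues[-1].molecule_class == "protein":
            serial += 1
            last = residues[-1]
            lines.append(
                f"TER   {serial:5d}      {last.res_name:>3s} "
                f"{chain_id[:1]:1s}{last.res_seq:4d}"
            )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping ``mobile`` onto ``target``.

    Point correspondence is positional (i-th to i-th); reflections are
    excluded by the usual determinant sign correction.  Raises for fewer
    than three points or collinear/degenerate sets, where the rotation
    about the common axis is undetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching N×3 arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required")

    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    x = mobile - cm
    y = target - ct

    # collinear point sets leave the rotation under-determined
    span = max(np.linalg.norm(x), np.linalg.norm(y), 1.0)
    for pts in (x, y):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-9 * span:
            raise ValueError("degenerate (collinear) point set")

    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ct - rot @ cm
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - target) ** 2, axis=1))))
    return RigidTransform(rot, trans, rmsd)


def _fresh_chain_ids(existing: set[str], count: int) -> list[str]:
    pool = string.ascii_uppercase + string.digits + string.ascii_lowercase
    out = []
    for c in pool:
        if c not in existing:
            out.append(c)
        if len(out) == count:
            return out
    raise ValueError("ran out of single-character chain identifiers")


def extend_protofibril(model: ProtofibrilModel, target_copies: int) -> ProtofibrilModel:
    """Grow a fibril to ``target_copies`` filaments along its growth axis.

    The inter-filament operator (a screw transform for real fibrils) is
    estimated by backbone-atom superposition of every consecutive chain
    pair simultaneously, then applied repeatedly to the terminal chain.
    Original atoms are never moved; new chains get fresh identifiers.
    """
    chains = model.protein_chains()
    ids = list(chains)
    if len(ids) < 2:
        raise ValueError("need at least 2 protein chains to estimate the operator")
    ref_seq = [r.res_name for r in chains[ids[0]]]
    ref_counts = [len(r.atoms) for r in chains[ids[0]]]
    for cid in ids[1:]:
        if [r.res_name for r in chains[cid]] != ref_seq:
            raise ValueError(f"chain {cid!r} sequence differs from chain {ids[0]!r}")
        if [len(r.atoms) for r in chains[cid]] != ref_counts:
            raise ValueError(f"chain {cid!r} atom counts differ from chain {ids[0]!r}")
    if target_copies < len(ids):
        raise ValueError(
            f"target_copies={target_copies} below current chain count {len(ids)}"
        )
    if target_copies == len(ids):
        return model.copy()

    def backbone_coords(residues: list[Residue]) -> np.ndarray:
        pts = []
        for res in residues:
            for name in BACKBONE_ATOMS:
                atom = res.atom(name)
                if atom is None:
                    raise ValueError(
                        f"residue {res.res_name}{res.res_seq} in chain "
                        f"{res.chain_id!r} lacks backbone atom {name}"
                    )
                pts.append(atom.coords)
        return np.array(pts)

    # one superposition over all consecutive pairs = pair-averaged operator
    mobile = np.vstack([backbone_coords(chains[c]) for c in ids[:-1]])
    target = np.vstack([backbone_coords(chains[c]) for c in ids[1:]])
    op = kabsch_superpose(mobile, target)

    new_model = model.copy()
    new_ids = _fresh_chain_ids(set(model.chains), target_copies - len(ids))
    template = [r.copy() for r in chains[ids[-1]]]
    current = template
    for new_id in new_ids:
        grown = []
        for res in current:
            res2 = res.copy()
            res2.chain_id = new_id
            for a in res2.atoms:
                a.chain_id = new_id
                a.coords = op.apply(a.coords)
            grown.append(res2)
        new_model.residues.extend(grown)
        current = grown
    return new_model


def load_parameter_table(path: str | Path) -> pd.DataFrame:
    """Load a per-(res_name, atom_name) parameter table.

    Plain delimited text (comma or whitespace) with a header row and
    columns ``res_name atom_name charge lj_sigma lj_epsilon``.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"res_name", "atom_name", "charge", "lj_sigma", "lj_epsilon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    return df


def assign_parameters(
    model: ProtofibrilModel,
    table: pd.DataFrame | None = None,
    default_charge: float = 0.0,
    default_lj: Mapping[str, tuple[float, float]] = DEFAULT_LJ,
) -> ProtofibrilModel:
    """Assign partial charges and LJ parameters to every atom, in place.

    Atoms absent from ``table`` get ``default_charge`` and the built-in
    per-element LJ defaults; unknown elements get zeroed LJ terms.
    Returns the model for chaining.
    """
    lookup: dict[tuple[str, str], tuple[float, float, float]] = {}
    if table is not None:
        for row in table.itertuples(index=False):
            lookup[(row.res_name, row.atom_name)] = (
                float(row.charge),
                float(row.lj_sigma),
                float(row.lj_epsilon),
            )
    for atom in model.atoms:
        entry = lookup.get((atom.res_name, atom.name))
        if entry is not None:
            atom.partial_charge, atom.lj_sigma, atom.lj_epsilon = entry
        else:
            atom.partial_charge = default_charge
            sigma, eps = default_lj.get(atom.element.upper(), (0.0, 0.0))
            atom.lj_sigma, atom.lj_epsilon = sigma, eps
    return model
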