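"""Deterministic synthetic structures for desk-scale testing.

Generates ideal-geometry extended peptides (optionally stacked into
multi-filament fibrils by a screw operator), small rigid probe ligands,
and explicit waters — all seeded, so every test input is reproducible
bit-for-bit without downloads.  The planted-parameter design (all atoms
inert except a few explicit charge/LJ carriers) gives closed-form
expected energies and is the backbone of the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .constants import STANDARD_AMINO_ACIDS
from .structure_io import AtomRecord, ProtofibrilModel, Residue, write_pdb

# ideal backbone geometry, Å / degrees
N_CA = 1.46
CA_C = 1.52
C_N = 1.33
C_O = 1.23
CA_CB = 1.52
ANGLE_N_CA_C = 110.0
ANGLE_CA_C_N = 116.0
ANGLE_C_N_CA = 122.0
ANGLE_O_C_N = 123.0

# TIP3P-like water geometry
OH_BOND = 0.9572
HOH_ANGLE = 104.52


@dataclass
class FixtureSpec:
    """Recipe for a synthetic peptide / fibril / complex.

    ``planted_charges`` and ``planted_lj`` map ``(chain_id, res_seq,
    atom_name)`` to a partial charge (e) resp. ``(sigma, epsilon)``; all
    other atoms are inert (zero charge, zero epsilon).  ``water_radii``
    pins each water oxygen at an exact minimum distance from the ligand;
    without it waters go on a seeded jittered grid.
    """

    sequence: Sequence[str] = ("GLY", "GLY", "GLY")
    n_chains: int = 1
    chain_rise: float = 4.8
    chain_twist: float = 0.0
    ligand: str = "none"  # none | two_atom_probe | ring_probe
    ligand_offset: tuple[float, float, float] = (0.0, 8.0, 0.0)
    n_waters: int = 0
    water_radii: Sequence[float] | None = None
    seed: int = 0
    planted_charges: Mapping[tuple[str, int, str], float] = field(
        default_factory=dict
    )
    planted_lj: Mapping[tuple[str, int, str], tuple[float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("sequence must have at least one residue")
        if self.n_chains > 1 and self.chain_rise <= 0:
            raise ValueError("chain_rise must be positive for multi-chain fixtures")
        for code in self.sequence:
            if code not in STANDARD_AMINO_ACIDS:
                raise ValueError(f"unsupported residue code {code!r}")
        if self.ligand not in ("none", "two_atom_probe", "ring_probe"):
            raise ValueError(f"unknown ligand kind {self.ligand!r}")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


def _rot2d(v: np.ndarray, degrees: float) -> np.ndarray:
    t = math.radians(degrees)
    c, s = math.cos(t), math.sin(t)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], 0.0])


def _atom(
    name: str,
    element: str,
    coords: np.ndarray,
    res: Residue,
) -> AtomRecord:
    a = AtomRecord(
        serial=0,
        name=name,
        element=element,
        alt_loc="",
        res_name=res.res_name,
        chain_id=res.chain_id,
        res_seq=res.res_seq,
        insertion_code="",
        coords=coords,
        occupancy=1.0,
        partial_charge=0.0,
        lj_sigma=0.0,
        lj_epsilon=0.0,
    )
    res.atoms.append(a)
    return a


def _build_chain(sequence: Sequence[str], chain_id: str) -> list[Residue]:
    """Extended planar backbone via a 2D turtle with ideal bond geometry."""
    residues: list[Residue] = []
    pos = np.zeros(3)
    heading = np.array([1.0, 0.0, 0.0])
    # turn angles are supplements of the backbone bond angles, with
    # alternating sign so the chain stays extended along x
    bond_cycle = [
        (N_CA, 180.0 - ANGLE_N_CA_C),
        (CA_C, 180.0 - ANGLE_CA_C_N),
        (C_N, 180.0 - ANGLE_C_N_CA),
    ]
    sign = 1.0
    positions: list[dict[str, np.ndarray]] = []
    n_pos = pos.copy()
    for i in range(len(sequence) + 1):  # one virtual extra residue for O/caps
        entry = {"N": n_pos.copy()}
        p = n_pos.copy()
        h = heading.copy()
        for j, (length, turn) in enumerate(bond_cycle):
            p = p + length * h
            if j == 0:
                entry["CA"] = p.copy()
            elif j == 1:
                entry["C"] = p.copy()
            h = _rot2d(h, sign * turn)
            sign = -sign
        positions.append(entry)
        n_pos = p
        heading = h
        # note: sign already flipped three times per residue (odd), so
        # successive residues alternate handedness, giving a zig-zag

    for i, code in enumerate(sequence):
        res = Residue(
            chain_id=chain_id,
            res_seq=i + 1,
            insertion_code="",
            res_name=code,
            molecule_class="protein",
        )
        pn, pca, pc = positions[i]["N"], positions[i]["CA"], positions[i]["C"]
        next_n = positions[i + 1]["N"]
        _atom("N", "N", pn, res)
        _atom("CA", "C", pca, res)
        _atom("C", "C", pc, res)
        # carbonyl O in-plane at the standard O–C–N angle from the C→N bond
        d_cn = (next_n - pc) / np.linalg.norm(next_n - pc)
        d_cca = (pca - pc) / np.linalg.norm(pca - pc)
        normal_sign = 1.0 if np.cross(d_cca, d_cn)[2] >= 0 else -1.0
        o_dir = _rot2d(d_cn, normal_sign * ANGLE_O_C_N)
        _atom("O", "O", pc + C_O * o_dir, res)
        if code != "GLY":
            # CB out of plane, tetrahedral-ish and deterministic
            u_n = (pn - pca) / np.linalg.norm(pn - pca)
            u_c = (pc - pca) / np.linalg.norm(pc - pca)
            t = -(u_n + u_c)  # opposes the N/C bisector
            t /= np.linalg.norm(t)
            up = np.array([0.0, 0.0, 1.0])
            cb_dir = 0.578 * t + 0.816 * up
            cb_dir /= np.linalg.norm(cb_dir)
            _atom("CB", "C", pca + CA_CB * cb_dir, res)
        residues.append(res)
    return residues


def _screw(coords: np.ndarray, twist_deg: float, rise: float) -> np.ndarray:
    t = math.radians(twist_deg)
    c, s = math.cos(t), math.sin(t)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return coords @ rot.T + np.array([0.0, 0.0, rise])


def build_peptide(spec: FixtureSpec) -> ProtofibrilModel:
    """Ideal-geometry peptide, replicated into ``n_chains`` filaments.

    Filament k is the first chain transformed by the screw operator
    (``chain_twist``·k about z, ``chain_rise``·k along z); with zero
    twist this is a pure translational stack, the canonical cross-β
    arrangement at the ~4.8 Å inter-strand rise.
    """
    chain_ids = [chr(ord("A") + k) for k in range(spec.n_chains)]
    residues: list[Residue] = []
    template = _build_chain(spec.sequence, "A")
    for k, cid in enumerate(chain_ids):
        for res in template:
            r = res.copy()
            r.chain_id = cid
            for a in r.atoms:
                a.chain_id = cid
                if k:
                    a.coords = _screw(
                        a.coords[None, :], spec.chain_twist * k, spec.chain_rise * k
                    )[0]
            residues.append(r)
    model = ProtofibrilModel(residues)
    _apply_planted(model, spec)
    return model


def _ligand_residue(spec: FixtureSpec, centroid: np.ndarray) -> Residue:
    res = Residue(
        chain_id="L",
        res_seq=1,
        insertion_code="",
        res_name="LIG",
        molecule_class="ligand",
    )
    origin = centroid + np.asarray(spec.ligand_offset, dtype=float)
    if spec.ligand == "two_atom_probe":
        _atom("L1", "C", origin, res)
        _atom("L2", "C", origin + np.array([1.5, 0.0, 0.0]), res)
    elif spec.ligand == "ring_probe":
        for i in range(6):
            t = math.radians(60.0 * i)
            _atom(
                f"L{i + 1}",
                "C",
                origin + 1.39 * np.array([math.cos(t), math.sin(t), 0.0]),
                res,
            )
    else:
        raise ValueError("build_complex requires a ligand kind other than 'none'")
    return res


def _water_residue(
    index: int, o_pos: np.ndarray, rng: np.random.Generator
) -> Residue:
    res = Residue(
        chain_id="W",
        res_seq=index,
        insertion_code="",
        res_name="HOH",
        molecule_class="water",
    )
    # deterministic orientation drawn from the seeded generator
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    half = math.radians(HOH_ANGLE / 2.0)
    _atom("O", "O", o_pos, res)
    for k, s in enumerate((1.0, -1.0)):
        d = math.cos(half) * axis + s * math.sin(half) * e1
        _atom(f"H{k + 1}", "H", o_pos + OH_BOND * d, res)
    return res


def _apply_planted(model: ProtofibrilModel, spec: FixtureSpec) -> None:
    for atom in model.atoms:
        key = (atom.chain_id, atom.res_seq, atom.name)
        if key in spec.planted_charges:
            atom.partial_charge = float(spec.planted_charges[key])
        if key in spec.planted_lj:
            atom.lj_sigma, atom.lj_epsilon = map(float, spec.planted_lj[key])


def build_complex(spec: FixtureSpec) -> ProtofibrilModel:
    """Peptide + probe ligand (+ explicit waters), fully parameterized.

    The ligand sits at ``ligand_offset`` from the peptide centroid.
    Waters are packed on a seeded jittered grid around the ligand (or at
    the exact ligand distances in ``water_radii``) with a 2.5 Å minimum
    separation from all solute atoms and each other; infeasible packing
    raises after bounded attempts.
    """
    model = build_peptide(
        FixtureSpec(
            sequence=spec.sequence,
            n_chains=spec.n_chains,
            chain_rise=spec.chain_rise,
            chain_twist=spec.chain_twist,
            seed=spec.seed,
        )
    )
    centroid = np.mean([a.coords for a in model.atoms], axis=0)
    lig = _ligand_residue(spec, centroid)
    model.residues.append(lig)

    rng = np.random.default_rng(spec.seed)
    solute = np.array([a.coords for a in model.atoms])
    lig_coords = np.array([a.coords for a in lig.atoms])
    lig_centroid = lig_coords.mean(axis=0)
    placed: list[np.ndarray] = []

    def far_enough(p: np.ndarray) -> bool:
        if np.min(np.linalg.norm(solute - p, axis=1)) < 2.5:
            return False
        return all(np.linalg.norm(q - p) >= 2.5 for q in placed)

    if spec.water_radii is not None:
        if len(spec.water_radii) != spec.n_waters:
            raise ValueError("water_radii length must equal n_waters")
        # anchor: the ligand atom farthest from the peptide, so a shell
        # placed on the away side has its exact distance to the ligand
        away = lig_centroid - centroid
        away /= np.linalg.norm(away)
        anchor = lig_coords[np.argmax(lig_coords @ away)]
        for i, radius in enumerate(spec.water_radii):
            for _ in range(500):
                tangent = rng.normal(size=3)
                tangent -= np.dot(tangent, away) * away
                tangent /= np.linalg.norm(tangent)
                u = away + 0.35 * tangent
                u /= np.linalg.norm(u)
                p = anchor + radius * u
                if far_enough(p) and np.min(
                    np.linalg.norm(lig_coords - p, axis=1)
                ) >= radius - 1e-9:
                    break
            else:
                raise ValueError(f"could not place water {i + 1} at r={radius}")
            placed.append(p)
    else:
        for i in range(spec.n_waters):
            for _ in range(500):
                cell = rng.integers(-3, 4, size=3).astype(float)
                p = lig_centroid + 3.0 * cell + rng.uniform(-0.5, 0.5, size=3)
                if far_enough(p):
                    break
            else:
                raise ValueError(f"could not place water {i + 1} on the grid")
            placed.append(p)

    for i, p in enumerate(placed):
        model.residues.append(_water_residue(i + 1, p, rng))
    _apply_planted(model, spec)
    return model


def write_fixture_files(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[Path, Path]:
    """Emit a PDB and matching parameter table for a fixture complex."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = build_complex(spec) if spec.ligand != "none" else build_peptide(spec)
    pdb_path = out_dir / "fixture.pdb"
    write_pdb(model, pdb_path)
    rows = ["res_name,atom_name,charge,lj_sigma,lj_epsilon"]
    seen = set()
    for a in model.atoms:
        key = (a.res_name, a.name)
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            f"{a.res_name},{a.name},{a.partial_charge:.10g},"
            f"{a.lj_sigma:.10g},{a.lj_epsilon:.10g}"
        )
    param_path = out_dir / "params.csv"
    param_path.write_text("\n".join(rows) + "\n")
    return pdb_path, param_path
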