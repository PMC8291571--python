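"""Energy backends: the evaluation contract plus two implementations.

* :class:`ClassicalBackend` — exact pairwise Coulomb + Lennard-Jones with
  Lorentz–Berthelot combining, no cutoff, no periodicity.  It is the
  desk-scale oracle: because it is strictly pairwise additive, the
  fragment-sum interaction energy must reproduce the direct supramolecular
  cross energy exactly, which the test suite exploits.
* :class:`QmDeckBackend` — writes plain-text input decks for an external
  electronic-structure engine (default M06-2X/6-31+G**) and parses the
  resulting final energies back, converting hartree → kcal/mol.  The
  electronic-structure computation itself never runs in-process.

All energies are in kcal/mol.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import COULOMB_CONSTANT, HARTREE_TO_KCAL
from .fragmentation import Fragment
from .structure_io import AtomRecord


class EnergyBackend:
    """Contract for energy evaluation.

    Implementations advertise capabilities through
    ``supports_cross_interaction`` / ``supports_total_energy`` and return
    energies in kcal/mol via ``cross_energy(atoms_a, atoms_b)`` and/or
    ``total_energy(atoms)``.
    """

    method_label: str = "abstract"
    supports_cross_interaction: bool = False
    supports_total_energy: bool = False

    def cross_energy(
        self, atoms_a: Sequence[AtomRecord], atoms_b: Sequence[AtomRecord]
    ) -> float:
        raise NotImplementedError

    def total_energy(self, atoms: Sequence[AtomRecord]) -> float:
        raise NotImplementedError


def _gather_params(atoms: Sequence[AtomRecord]):
    coords = np.empty((len(atoms), 3))
    q = np.empty(len(atoms))
    sigma = np.empty(len(atoms))
    eps = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        if a.partial_charge is None or a.lj_sigma is None or a.lj_epsilon is None:
            raise ValueError(
                f"atom {a.name} ({a.res_name} {a.chain_id}:{a.res_seq}) "
                "has no nonbonded parameters assigned"
            )
        coords[i] = a.coords
        q[i] = a.partial_charge
        sigma[i] = a.lj_sigma
        eps[i] = a.lj_epsilon
    return coords, q, sigma, eps


def _pair_energy(ra, qa, sa, ea, rb, qb, sb, eb) -> tuple[float, float]:
    """(electrostatic, van der Waals) sums over all A×B pairs."""
    d = ra[:, None, :] - rb[None, :, :]
    r = np.sqrt(np.sum(d * d, axis=-1))
    if np.any(r < 1e-6):
        raise ValueError("overlapping atoms (r < 1e-6 Å)")
    elec_terms = COULOMB_CONSTANT * np.outer(qa, qb) / r
    sig = 0.5 * (sa[:, None] + sb[None, :])  # Lorentz
    epsm = np.sqrt(np.outer(ea, eb))  # Berthelot
    sr6 = (sig / r) ** 6
    vdw_terms = 4.0 * epsm * (sr6 * sr6 - sr6)
    # summing in sorted order makes cross(A, B) == cross(B, A) exact
    elec = np.sum(np.sort(elec_terms, axis=None))
    vdw = np.sum(np.sort(vdw_terms, axis=None))
    return float(elec), float(vdw)


def classical_cross_energy(
    atoms_a: Sequence[AtomRecord], atoms_b: Sequence[AtomRecord]
) -> tuple[float, float, float]:
    """Exact A–B nonbonded interaction energy.

    Returns ``(total, electrostatic, van_der_waals)`` where the Coulomb
    term uses k_e = 332.0636 kcal·Å/(mol·e²) and LJ uses
    Lorentz–Berthelot combining; no cutoff, no periodicity.
    """
    ca, qa, sa, ea = _gather_params(atoms_a)
    cb, qb, sb, eb = _gather_params(atoms_b)
    elec, vdw = _pair_energy(ca, qa, sa, ea, cb, qb, sb, eb)
    return elec + vdw, elec, vdw


def classical_total_energy(atoms: Sequence[AtomRecord]) -> float:
    """Pairwise nonbonded sum over all distinct pairs of one atom set.

    No bonded terms: this exists solely to realize the supramolecular
    difference E(A∪B) − E(A) − E(B), which for a pairwise-additive form
    equals the A–B cross energy identically.
    """
    if len(atoms) < 2:
        # still validate parameters on the lone atom
        if atoms:
            _gather_params(atoms)
        return 0.0
    coords, q, sigma, eps = _gather_params(atoms)
    iu, ju = np.triu_indices(len(atoms), k=1)
    d = coords[iu] - coords[ju]
    r = np.sqrt(np.sum(d * d, axis=-1))
    if np.any(r < 1e-6):
        raise ValueError("overlapping atoms (r < 1e-6 Å)")
    elec = COULOMB_CONSTANT * np.sum(q[iu] * q[ju] / r)
    sig = 0.5 * (sigma[iu] + sigma[ju])
    epsm = np.sqrt(eps[iu] * eps[ju])
    sr6 = (sig / r) ** 6
    vdw = np.sum(4.0 * epsm * (sr6 * sr6 - sr6))
    return float(elec + vdw)


class ClassicalBackend(EnergyBackend):
    """Exact classical nonbonded backend (Coulomb + LJ)."""

    method_label = "classical-nonbonded"
    supports_cross_interaction = True
    supports_total_energy = True

    def cross_energy(self, atoms_a, atoms_b) -> float:
        return classical_cross_energy(atoms_a, atoms_b)[0]

    def cross_energy_components(self, atoms_a, atoms_b) -> tuple[float, float, float]:
        return classical_cross_energy(atoms_a, atoms_b)

    def total_energy(self, atoms) -> float:
        return classical_total_energy(atoms)


@dataclass
class QmJobSpec:
    """Level-of-theory header for a QM input deck."""

    method: str = "M06-2X"
    basis: str = "6-31+G**"
    charge: int = 0
    multiplicity: int = 1
    geometry: list[tuple[str, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be ≥ 1")


DECK_HEADER = "# fragdecomp qm deck v1"


def _write_deck(
    path: Path,
    method: str,
    basis: str,
    charge: int,
    multiplicity: int,
    atoms: Sequence[AtomRecord],
) -> None:
    lines = [
        DECK_HEADER,
        f"method {method}",
        f"basis {basis}",
        f"charge {charge}",
        f"multiplicity {multiplicity}",
        "geometry",
    ]
    for a in atoms:
        x, y, z = a.coords
        lines.append(f"{a.element:<2s} {x: .10f} {y: .10f} {z: .10f}")
    lines.append("end")
    path.write_text("\n".join(lines) + "\n")


def write_qm_decks(
    fragments: Iterable[Fragment],
    ligand: Sequence[AtomRecord],
    spec: QmJobSpec,
    out_dir: str | Path,
    ligand_charge: int = 0,
) -> dict:
    """Write supramolecular input decks for every fragment.

    Per fragment F: a F+ligand complex deck (charge q_F + q_L) and a
    F-alone deck; the ligand deck is written once.  Returns a manifest
    mapping ``fragment_id`` to its three deck paths, also saved as
    ``manifest.json`` in ``out_dir``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to {out_dir}: {exc}") from exc

    ligand_path = out_dir / "ligand.qmin"
    _write_deck(
        ligand_path, spec.method, spec.basis, ligand_charge, spec.multiplicity, ligand
    )
    manifest: dict[str, dict[str, str]] = {}
    for frag in fragments:
        safe = frag.fragment_id.replace(":", "_")
        frag_path = out_dir / f"{safe}.fragment.qmin"
        complex_path = out_dir / f"{safe}.complex.qmin"
        _write_deck(
            frag_path,
            spec.method,
            spec.basis,
            frag.net_charge,
            frag.multiplicity,
            frag.atoms,
        )
        _write_deck(
            complex_path,
            spec.method,
            spec.basis,
            frag.net_charge + ligand_charge,
            frag.multiplicity,
            list(frag.atoms) + list(ligand),
        )
        manifest[frag.fragment_id] = {
            "complex": complex_path.name,
            "fragment": frag_path.name,
            "ligand": ligand_path.name,
        }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


_ENERGY_RE = re.compile(r"FINAL ENERGY:\s*(-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s*hartree")


def _read_result(path: Path) -> float:
    text = path.read_text()
    m = _ENERGY_RE.search(text)
    if m is None:
        raise ValueError(f"{path}: no parseable 'FINAL ENERGY: <float> hartree' line")
    return float(m.group(1)) * HARTREE_TO_KCAL


def parse_qm_results(
    manifest: dict, results_dir: str | Path
) -> tuple[dict[str, tuple[float, float, float]], list[str]]:
    """Collect (E_complex, E_fragment, E_ligand) per fragment, in kcal/mol.

    A result file ``<deck stem>.out`` must exist for each deck and carry a
    ``FINAL ENERGY: <float> hartree`` line.  Fragments with missing files
    land in the returned gap list instead of raising, so partial result
    sets can be aggregated.
    """
    results_dir = Path(results_dir)
    energies: dict[str, tuple[float, float, float]] = {}
    gaps: list[str] = []
    for frag_id, decks in manifest.items():
        vals = []
        missing = False
        for role in ("complex", "fragment", "ligand"):
            out_path = results_dir / (Path(decks[role]).stem + ".out")
            if not out_path.exists():
                missing = True
                break
            vals.append(_read_result(out_path))
        if missing:
            gaps.append(frag_id)
        else:
            energies[frag_id] = (vals[0], vals[1], vals[2])
    return energies, gaps


class QmDeckBackend(EnergyBackend):
    """Backend facade over externally computed supramolecular QM energies.

    Construct it from the output of :func:`parse_qm_results`; the
    interaction layer then consumes ΔE = E_complex − E_fragment −
    E_ligand per fragment id.
    """

    supports_cross_interaction = False
    supports_total_energy = False

    def __init__(
        self,
        energies: dict[str, tuple[float, float, float]],
        method_label: str = "M06-2X/6-31+G**",
    ):
        self.energies = dict(energies)
        self.method_label = method_label

    def interaction_energy(self, fragment_id: str) -> float:
        if fragment_id not in self.energies:
            raise KeyError(f"no QM result for fragment {fragment_id}")
        e_complex, e_frag, e_lig = self.energies[fragment_id]
        return e_complex - e_frag - e_lig
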