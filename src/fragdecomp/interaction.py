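"""Per-fragment ligand interaction energies and their aggregation.

The fibril–ligand interaction energy is computed as the sum over capped
fragment contributions, the solvent term as the sum over explicit
water–ligand interactions, and the total as

    ΔE_total = ΔE_fibril + ΔE_solvent (+ three-body correction).

Each per-fragment ΔE is the supramolecular difference
E(fragment∪ligand) − E(fragment) − E(ligand) evaluated on the fixed
complex-snapshot geometry (no relaxation); backends that expose a direct
cross-interaction evaluate it in one call.  The dipeptide three-body
correction compares overlapping two-residue windows against the sum of
their single-residue constituents.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .backends import EnergyBackend, QmDeckBackend
from .fragmentation import Fragment
from .structure_io import AtomRecord


@dataclass
class InteractionRecord:
    """Interaction energy of one fragment with the ligand, kcal/mol."""

    fragment_id: str
    source_residues: list[tuple[str, int, str]]
    delta_e: float
    components: tuple[float, float] | None = None  # (elec, vdw)
    filament_id: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_e):
            raise ValueError(f"non-finite ΔE for {self.fragment_id}")
        if self.components is not None:
            if abs(sum(self.components) - self.delta_e) > 1e-9:
                raise ValueError(
                    f"components of {self.fragment_id} do not sum to ΔE"
                )


@dataclass
class InteractionSummary:
    """Fragment records plus fibril / solvent / total aggregates."""

    records: list[InteractionRecord] = field(default_factory=list)
    solvent_records: list[InteractionRecord] = field(default_factory=list)
    delta_e_fibril: float = 0.0
    delta_e_solvent: float = 0.0
    three_body_correction: float = 0.0
    metadata: dict = field(default_factory=dict)

    @property
    def delta_e_total(self) -> float:
        return self.delta_e_fibril + self.delta_e_solvent + self.three_body_correction

    def validate(self) -> None:
        frag_sum = sum(r.delta_e for r in self.records)
        if abs(frag_sum - self.delta_e_fibril) > 1e-9:
            raise ValueError("ΔE_fibril does not equal the fragment-record sum")
        solv_sum = sum(r.delta_e for r in self.solvent_records)
        if abs(solv_sum - self.delta_e_solvent) > 1e-9:
            raise ValueError("ΔE_solvent does not equal the water-record sum")

    def to_tsv(self, path: str | Path) -> None:
        """Deterministic TSV export: one row per record plus summary rows."""
        lines = ["kind\tfragment_id\tfilament_id\tresidues\tdelta_e_kcal_mol"]
        for kind, recs in (
            ("fragment", self.records),
            ("water", self.solvent_records),
        ):
            for r in recs:
                resstr = ",".join(
                    f"{c}:{s}:{n}" for c, s, n in r.source_residues
                )
                lines.append(
                    f"{kind}\t{r.fragment_id}\t{r.filament_id}\t{resstr}"
                    f"\t{r.delta_e:.9f}"
                )
        lines.append(f"total\tdelta_e_fibril\t\t\t{self.delta_e_fibril:.9f}")
        lines.append(f"total\tdelta_e_solvent\t\t\t{self.delta_e_solvent:.9f}")
        lines.append(
            f"total\tthree_body_correction\t\t\t{self.three_body_correction:.9f}"
        )
        lines.append(f"total\tdelta_e_total\t\t\t{self.delta_e_total:.9f}")
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "delta_e_fibril": self.delta_e_fibril,
            "delta_e_solvent": self.delta_e_solvent,
            "three_body_correction": self.three_body_correction,
            "delta_e_total": self.delta_e_total,
            "records": [
                {
                    "fragment_id": r.fragment_id,
                    "filament_id": r.filament_id,
                    "source_residues": [list(t) for t in r.source_residues],
                    "delta_e": r.delta_e,
                    "components": list(r.components) if r.components else None,
                }
                for r in self.records + self.solvent_records
            ],
            "metadata": self.metadata,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=1) + "\n")
        return payload


def fragment_interaction(
    fragment: Fragment,
    ligand: Sequence[AtomRecord],
    backend: EnergyBackend,
) -> InteractionRecord:
    """ΔE between one capped fragment and the ligand.

    Uses the backend's direct cross-interaction when available, otherwise
    the supramolecular difference of three total energies; for a
    pairwise-additive backend both routes agree identically.
    """
    filament = fragment.source_residues[0][0] if fragment.source_residues else ""
    try:
        if isinstance(backend, QmDeckBackend):
            delta_e = backend.interaction_energy(fragment.fragment_id)
            components = None
        elif backend.supports_cross_interaction:
            if hasattr(backend, "cross_energy_components"):
                total, elec, vdw = backend.cross_energy_components(
                    fragment.atoms, list(ligand)
                )
                delta_e, components = total, (elec, vdw)
            else:
                delta_e = backend.cross_energy(fragment.atoms, list(ligand))
                components = None
        elif backend.supports_total_energy:
            e_ab = backend.total_energy(list(fragment.atoms) + list(ligand))
            e_a = backend.total_energy(fragment.atoms)
            e_b = backend.total_energy(list(ligand))
            delta_e = e_ab - e_a - e_b
            components = None
        else:
            raise ValueError(
                f"backend {backend.method_label!r} supports neither "
                "cross_interaction nor total_energy"
            )
    except Exception as exc:
        raise type(exc)(f"[fragment {fragment.fragment_id}] {exc}") from exc
    return InteractionRecord(
        fragment_id=fragment.fragment_id,
        source_residues=list(fragment.source_residues),
        delta_e=delta_e,
        components=components,
        filament_id=filament,
    )


def total_fibril_interaction(
    fragments: Sequence[Fragment],
    ligand: Sequence[AtomRecord],
    backend: EnergyBackend,
) -> InteractionSummary:
    """ΔE_fibril = Σ fragment–ligand ΔE (solvent term zero)."""
    if not fragments:
        warnings.warn("no fragments supplied; ΔE_fibril = 0", stacklevel=2)
    records = [fragment_interaction(f, ligand, backend) for f in fragments]
    summary = InteractionSummary(
        records=records,
        delta_e_fibril=float(sum(r.delta_e for r in records)),
        metadata={"backend": backend.method_label},
    )
    summary.validate()
    return summary


def solvent_interaction(
    water_fragments: Sequence[Fragment],
    ligand: Sequence[AtomRecord],
    backend: EnergyBackend,
) -> tuple[float, list[InteractionRecord]]:
    """ΔE_solvent = Σ water–ligand ΔE over explicit water fragments."""
    records = [fragment_interaction(w, ligand, backend) for w in water_fragments]
    return float(sum(r.delta_e for r in records)), records


def three_body_correction(
    monopeptide_records: Sequence[InteractionRecord],
    dipeptide_records: Sequence[InteractionRecord],
) -> float:
    """Non-additivity captured by overlapping dipeptide windows.

    correction = Σ_i [ΔE(dipeptide_i) − ΔE(frag_i) − ΔE(frag_{i+1})].
    Zero (to additive-arithmetic precision) for any strictly pairwise
    backend with inert caps.
    """
    mono_by_res: dict[tuple[str, int], InteractionRecord] = {}
    for rec in monopeptide_records:
        if len(rec.source_residues) != 1:
            raise ValueError(
                f"record {rec.fragment_id} is not a single-residue fragment"
            )
        c, s, _ = rec.source_residues[0]
        mono_by_res[(c, s)] = rec
    correction = 0.0
    for di in dipeptide_records:
        if len(di.source_residues) != 2:
            raise ValueError(f"record {di.fragment_id} is not a dipeptide window")
        (c1, s1, _), (c2, s2, _) = di.source_residues
        try:
            m1 = mono_by_res[(c1, s1)]
            m2 = mono_by_res[(c2, s2)]
        except KeyError as exc:
            raise ValueError(
                f"dipeptide window {di.fragment_id} has no matching "
                "monopeptide fragments"
            ) from exc
        correction += di.delta_e - m1.delta_e - m2.delta_e
    return correction


def analyze_complex(
    protein_fragments: Sequence[Fragment],
    ligand: Sequence[AtomRecord],
    backend: EnergyBackend,
    water_fragments: Sequence[Fragment] = (),
    dipeptide_fragments: Sequence[Fragment] | None = None,
    metadata: dict | None = None,
) -> InteractionSummary:
    """One-stop aggregation into a full :class:`InteractionSummary`."""
    summary = total_fibril_interaction(protein_fragments, ligand, backend)
    if water_fragments:
        de_solv, solv_records = solvent_interaction(water_fragments, ligand, backend)
        summary.delta_e_solvent = de_solv
        summary.solvent_records = solv_records
    if dipeptide_fragments is not None:
        di_records = [
            fragment_interaction(f, ligand, backend) for f in dipeptide_fragments
        ]
        summary.three_body_correction = three_body_correction(
            summary.records, di_records
        )
    if metadata:
        summary.metadata.update(metadata)
    summary.validate()
    return summary


def average_summaries(
    summaries: Sequence[InteractionSummary],
) -> dict[str, tuple[float, float]]:
    """Multi-snapshot mean ± sd per fragment and for the aggregates.

    Thin convenience over repeated single-snapshot analyses; keys are
    fragment ids plus ``delta_e_fibril`` / ``delta_e_solvent`` /
    ``delta_e_total``.
    """
    if not summaries:
        raise ValueError("no summaries to average")
    per_key: dict[str, list[float]] = {}
    for s in summaries:
        for r in s.records + s.solvent_records:
            per_key.setdefault(r.fragment_id, []).append(r.delta_e)
        per_key.setdefault("delta_e_fibril", []).append(s.delta_e_fibril)
        per_key.setdefault("delta_e_solvent", []).append(s.delta_e_solvent)
        per_key.setdefault("delta_e_total", []).append(s.delta_e_total)
    return {
        k: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        for k, v in per_key.items()
    }
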