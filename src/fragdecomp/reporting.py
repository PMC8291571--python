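"""Free-energy bookkeeping, ΔG↔Ki conversion, and decomposition tables.

MM-GBSA-style binding free energies are the sum of four components —
van der Waals, electrostatics, polar (generalized-Born) solvation, and
nonpolar (surface-area) solvation:

    ΔG_binding = ΔE_vdw + ΔE_elec + ΔG_GB + ΔG_SA

and relate to inhibition constants via ΔG = RT·ln(Ki) (Ki in mol/L,
1 M standard state).  This module only aggregates, checks and reports
such components; it never solves the GB equation itself.  Residue-wise
decomposition rows are derived from fragment interaction records, most
stabilizing first.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .constants import GAS_CONSTANT_KCAL
from .interaction import InteractionSummary

# Printed tables round each addend to one decimal independently, so the
# printed total can drift from the exact component sum by up to 0.05 per
# addend plus 0.05 on the total itself: 0.25 for a four-component row.
TABLE_CHECK_TOLERANCE = 0.25


@dataclass
class FreeEnergyComponents:
    """Additive binding free-energy components, kcal/mol."""

    e_vdw: float
    e_elec: float
    g_gb: float
    g_sa: float
    g_binding: float

    @classmethod
    def from_components(
        cls, e_vdw: float, e_elec: float, g_gb: float, g_sa: float
    ) -> "FreeEnergyComponents":
        return cls(e_vdw, e_elec, g_gb, g_sa, e_vdw + e_elec + g_gb + g_sa)

    @property
    def component_sum(self) -> float:
        return self.e_vdw + self.e_elec + self.g_gb + self.g_sa

    @property
    def is_consistent(self) -> bool:
        return abs(self.g_binding - self.component_sum) <= TABLE_CHECK_TOLERANCE


@dataclass
class DecompositionRow:
    """Per-residue contribution to the total interaction energy."""

    filament_id: str
    res_seq: int
    res_name: str
    energy: float
    rank: int
    top: bool = False


def sum_free_energy_components(
    e_vdw: float, e_elec: float, g_gb: float, g_sa: float
) -> float:
    """ΔG_binding as the exact sum of its four components."""
    for name, v in (
        ("e_vdw", e_vdw),
        ("e_elec", e_elec),
        ("g_gb", g_gb),
        ("g_sa", g_sa),
    ):
        if not math.isfinite(v):
            raise ValueError(f"{name} is not finite")
    return e_vdw + e_elec + g_gb + g_sa


def sum_interaction_totals(delta_e_fibril: float, delta_e_solvent: float) -> float:
    """ΔE_total = ΔE_fibril + ΔE_solvent."""
    if not (math.isfinite(delta_e_fibril) and math.isfinite(delta_e_solvent)):
        raise ValueError("interaction totals must be finite")
    return delta_e_fibril + delta_e_solvent


def ki_from_free_energy(g_binding: float, temperature: float = 298.15) -> float:
    """Inhibition constant Ki (mol/L) from ΔG_binding via ΔG = RT·ln(Ki).

    Assumes a 1 M standard state; R = 1.98720425864083e-3 kcal/(mol·K).
    More negative ΔG ⇒ smaller Ki ⇒ tighter binding.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(g_binding / (GAS_CONSTANT_KCAL * temperature))


def free_energy_from_ki(ki: float, temperature: float = 298.15) -> float:
    """Inverse of :func:`ki_from_free_energy`: ΔG = RT·ln(Ki)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if ki <= 0:
        raise ValueError("Ki must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(ki)


def residue_decomposition(
    summary: InteractionSummary, top_n: int = 5
) -> list[DecompositionRow]:
    """Residue-wise contributions, most stabilizing (lowest energy) first.

    Dipeptide records are split equally between their two residues.
    Water records land on their own (water) residues so the row energies
    always sum to ΔE_fibril + ΔE_solvent.  Ranks are 1..n ascending in
    energy, ties broken by (filament_id, res_seq); the ``top_n`` most
    stabilizing rows are flagged.
    """
    if top_n < 1:
        raise ValueError("top_n must be ≥ 1")
    records = list(summary.records) + list(summary.solvent_records)
    if not records:
        raise ValueError("summary contains no records to decompose")
    per_res: dict[tuple[str, int, str], float] = {}
    for rec in records:
        share = rec.delta_e / len(rec.source_residues)
        for chain_id, res_seq, res_name in rec.source_residues:
            key = (chain_id, res_seq, res_name)
            per_res[key] = per_res.get(key, 0.0) + share
    ordered = sorted(per_res.items(), key=lambda kv: (kv[1], kv[0][0], kv[0][1]))
    rows = [
        DecompositionRow(
            filament_id=chain_id,
            res_seq=res_seq,
            res_name=res_name,
            energy=energy,
            rank=i + 1,
            top=i < top_n,
        )
        for i, ((chain_id, res_seq, res_name), energy) in enumerate(ordered)
    ]
    return rows


def decomposition_by_filament(
    rows: Sequence[DecompositionRow],
) -> dict[str, list[DecompositionRow]]:
    """Group decomposition rows per filament, preserving rank order."""
    out: dict[str, list[DecompositionRow]] = {}
    for row in rows:
        out.setdefault(row.filament_id, []).append(row)
    return out


def decomposition_to_tsv(rows: Sequence[DecompositionRow], path: str | Path) -> None:
    lines = ["rank\tfilament_id\tres_seq\tres_name\tenergy_kcal_mol\ttop"]
    for r in rows:
        lines.append(
            f"{r.rank}\t{r.filament_id}\t{r.res_seq}\t{r.res_name}"
            f"\t{r.energy:.9f}\t{int(r.top)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ComponentTableRow:
    label: str
    components: FreeEnergyComponents
    flagged: bool


def load_component_table(path: str | Path) -> list[ComponentTableRow]:
    """Load an externally computed component table and audit its sums.

    Expects delimited text with columns ``site e_vdw e_elec g_gb g_sa
    g_binding``; each printed ΔG_binding is checked against the
    recomputed component sum within 0.05 kcal/mol (one-decimal rounding)
    and flagged on discrepancy.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"site", "e_vdw", "e_elec", "g_gb", "g_sa", "g_binding"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"component table missing columns: {sorted(missing)}")
    if df.empty:
        warnings.warn(f"{path}: component table has no data rows", stacklevel=2)
        return []
    rows: list[ComponentTableRow] = []
    for rec in df.itertuples(index=False):
        comps = FreeEnergyComponents(
            float(rec.e_vdw),
            float(rec.e_elec),
            float(rec.g_gb),
            float(rec.g_sa),
            float(rec.g_binding),
        )
        rows.append(
            ComponentTableRow(
                label=str(rec.site),
                components=comps,
                flagged=not comps.is_consistent,
            )
        )
    return rows
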