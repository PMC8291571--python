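"""Bundled reference tables.

Published MM-GBSA binding free-energy components and QM-fragmentation
interaction totals for the AV-1451 tau-tracer bound to fibrils from
Alzheimer's disease (AD), chronic traumatic encephalopathy (CTE) and
Pick's disease (PiD) patients, at the docking-identified binding sites
(and, for AD, the cryptic sites C1/C3 exposed by organic-solvent
profiling).  Values are in kcal/mol as printed (one decimal).  These
tables are inputs for the bookkeeping layer — re-aggregation, sum
auditing and ΔG→Ki conversion — not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = resources.files(__package__) / "data"

MMGBSA_MAIN = "mmgbsa_components_main_sites.csv"
MMGBSA_CRYPTIC = "mmgbsa_components_cryptic_sites.csv"
INTERACTION_MAIN = "fragment_interaction_totals_main.csv"
INTERACTION_CRYPTIC = "fragment_interaction_totals_cryptic.csv"


def dataset_path(name: str):
    """Filesystem path of a bundled CSV (usable with the table loaders)."""
    path = _DATA / name
    if not path.is_file():
        raise FileNotFoundError(name)
    return path


def load_mmgbsa_components(cryptic: bool = False) -> pd.DataFrame:
    """Binding free-energy component table (site, four components, total)."""
    return pd.read_csv(dataset_path(MMGBSA_CRYPTIC if cryptic else MMGBSA_MAIN))


def load_interaction_totals(cryptic: bool = False) -> pd.DataFrame:
    """Fragment-scheme interaction totals (ΔE_fibril, ΔE_solvent, ΔE_total)."""
    return pd.read_csv(
        dataset_path(INTERACTION_CRYPTIC if cryptic else INTERACTION_MAIN)
    )
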