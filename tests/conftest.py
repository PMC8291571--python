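import numpy as np
import pytest

from fragdecomp import FixtureSpec, build_complex, build_peptide
from fragdecomp.structure_io import AtomRecord


def make_atom(
    name="X",
    element="C",
    coords=(0.0, 0.0, 0.0),
    charge=0.0,
    sigma=0.0,
    epsilon=0.0,
    res_name="LIG",
    chain_id="L",
    res_seq=1,
):
    return AtomRecord(
        serial=0,
        name=name,
        element=element,
        alt_loc="",
        res_name=res_name,
        chain_id=chain_id,
        res_seq=res_seq,
        insertion_code="",
        coords=np.asarray(coords, dtype=float),
        occupancy=1.0,
        partial_charge=charge,
        lj_sigma=sigma,
        lj_epsilon=epsilon,
    )


@pytest.fixture
def tripeptide():
    return build_peptide(FixtureSpec(sequence=("GLY", "GLY", "GLY")))


@pytest.fixture
def small_complex():
    """Two-filament tetrapeptide with probe ligand, planted parameters."""
    spec = FixtureSpec(
        sequence=("GLY", "ALA", "GLY", "SER"),
        n_chains=2,
        ligand="two_atom_probe",
        n_waters=3,
        seed=11,
        planted_charges={
            ("A", 1, "CA"): 0.4,
            ("A", 3, "O"): -0.3,
            ("B", 2, "N"): 0.25,
            ("L", 1, "L1"): -1.0,
            ("L", 1, "L2"): 0.5,
        },
        planted_lj={
            ("A", 2, "CB"): (3.4, 0.12),
            ("L", 1, "L1"): (3.1, 0.2),
        },
    )
    return build_complex(spec)


def random_complex_spec(rng: np.random.Generator) -> FixtureSpec:
    """Seeded random fixture in the desk-scale study range."""
    n_res = int(rng.integers(3, 9))
    seq = [str(rng.choice(["GLY", "ALA", "SER", "ASP", "LYS"])) for _ in range(n_res)]
    n_chains = int(rng.integers(1, 3))
    n_waters = int(rng.integers(0, 11))
    charges = {}
    for _ in range(int(rng.integers(1, 5))):
        res_i = int(rng.integers(1, n_res + 1))
        chain = chr(ord("A") + int(rng.integers(0, n_chains)))
        atom = str(rng.choice(["N", "CA", "C", "O"]))
        charges[(chain, res_i, atom)] = float(rng.uniform(-1, 1))
    charges[("L", 1, "L1")] = float(rng.uniform(-1, 1))
    lj = {("L", 1, "L2"): (3.2, 0.15), (chr(ord("A")), 1, "CA"): (3.4, 0.1)}
    return FixtureSpec(
        sequence=tuple(seq),
        n_chains=n_chains,
        ligand=str(rng.choice(["two_atom_probe", "ring_probe"])),
        n_waters=n_waters,
        seed=int(rng.integers(0, 2**31 - 1)),
        planted_charges=charges,
        planted_lj=lj,
    )
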