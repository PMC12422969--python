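import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ampardyn.structio import Atom, Structure

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# hand-written 3-atom PDB fixture (fixed-width records)
THREE_ATOM_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00 10.00           C\n"
    "ATOM      2  CA  GLY A   2       4.500  -1.250   0.000  1.00 10.00           C\n"
    "ATOM      3  CZ  ARG A   3       0.125   8.000  -2.750  1.00 10.00           C\n"
    "END\n"
)

# same residue with two altloc conformers: B has the higher occupancy
ALTLOC_PDB = (
    "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C\n"
    "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60 10.00           C\n"
    "ATOM      3  CA  GLY A   2       1.000   1.000   1.000  1.00 10.00           C\n"
    "END\n"
)


@pytest.fixture
def three_atom_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_ATOM_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


def make_chain(chain_id, coords, first_residue=1, atom_name="CA", residue_name="ALA"):
    """Structure helper: one named atom per residue along a coordinate list."""
    return [
        Atom(chain_id, first_residue + k, residue_name, atom_name, "C", xyz)
        for k, xyz in enumerate(np.atleast_2d(np.asarray(coords, dtype=float)))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def make_structure(atom_lists):
    atoms = []
    for lst in atom_lists:
        atoms.extend(lst)
    return Structure(atoms)
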