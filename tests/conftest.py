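import numpy as np
import pytest

from foldphylo.structure_io import Structure
from foldphylo.synthetic import make_fold, make_supplementary_twin

PDB_3RES = """\
HEADER    TEST PROTEIN
REMARK   2 RESOLUTION.    2.00 ANGSTROMS.
ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00  0.00           C
ATOM      2  CA  GLY A   2      12.560   8.920  -5.010  1.00  0.00           C
ATOM      3  CA  SER A   3      14.021  10.355  -1.900  1.00  0.00           C
END
"""

CIF_3RES = """\
data_test
_cell.length_a 1.0
_struct.title 'test'
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 C CA . ALA A 1 1 ? 11.104 6.134 -6.504 1.00 0.00 1 A 1
ATOM 2 C CA . GLY A 1 2 ? 12.560 8.920 -5.010 1.00 0.00 2 A 1
ATOM 3 C CA . SER A 1 3 ? 14.021 10.355 -1.900 1.00 0.00 3 A 1
"""

COORDS_3RES = np.array(
    [
        [11.104, 6.134, -6.504],
        [12.560, 8.920, -5.010],
        [14.021, 10.355, -1.900],
    ]
)


@pytest.fixture
def pdb_3res(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(PDB_3RES)
    return p


@pytest.fixture
def cif_3res(tmp_path):
    p = tmp_path / "tiny.cif"
    p.write_text(CIF_3RES)
    return p


@pytest.fixture(scope="session")
def fold60():
    """A ~60-residue mixed α/β idealized fold."""
    return make_fold(
        [
            ("helix", 12), ("loop", 4), ("strand", 8), ("loop", 4),
            ("strand", 8), ("loop", 4), ("helix", 12), ("loop", 4),
            ("strand", 8),
        ],
        seed=42,
        id="fold60",
    )


@pytest.fixture(scope="session")
def twin():
    """Synthetic supplementary-shaped pairwise table (61 structures, 7 clades)."""
    table, clade_map, expected = make_supplementary_twin(seed=7)
    return table, clade_map, expected


def mk_structure(coords, id="s", start=1):
    coords = np.asarray(coords, dtype=float)
    return Structure(
        id=id,
        residues=[(start + i, "A") for i in range(len(coords))],
        coords=coords,
        resolution=None,
    )
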