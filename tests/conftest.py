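"""Shared fixtures: tiny structures and image bundles built in code."""

from __future__ import annotations

import numpy as np
import pytest

from epibind.epitope import DEFAULT_RADIUS, VDW_RADII, Structure

# Minimal hand-written PDB: two chains, three residues, with one water and
# one HETATM that readers must skip by default.
MINI_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.321   7.369  -4.749  1.00 10.00           C
ATOM      4  O   ALA A   1      12.240   8.380  -5.455  1.00 10.00           O
ATOM      5  CB  ALA A   1      12.621   4.906  -5.042  1.00 10.00           C
ATOM      6  N   GLY A   2      13.004   7.346  -3.606  1.00 12.00           N
ATOM      7  CA  GLY A   2      13.713   8.520  -3.108  1.00 12.00           C
ATOM      8  C   GLY A   2      14.670   8.127  -1.994  1.00 12.00           C
ATOM      9  O   GLY A   2      14.736   6.956  -1.613  1.00 12.00           O
ATOM     10  N   SER B   5       2.161   2.441   4.630  1.00 15.00           N
ATOM     11  CA  SER B   5       3.504   2.483   4.048  1.00 15.00           C
ATOM     12  C   SER B   5       4.563   2.021   5.043  1.00 15.00           C
ATOM     13  O   SER B   5       4.291   1.225   5.945  1.00 15.00           O
ATOM     14  CB  SER B   5       3.836   3.899   3.576  1.00 15.00           C
ATOM     15  OG  SER B   5       3.061   4.251   2.442  1.00 15.00           O
HETATM   16  ZN  ZN  B 101       0.000   0.000   0.000  1.00 20.00          ZN
HETATM   17  O   HOH B 102       8.000   8.000   8.000  1.00 30.00           O
END
"""


@pytest.fixture
def mini_pdb_path(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path


def make_structure(coords, elements=None, res_ids=None, res_names=None,
                   atom_names=None, chain="A") -> Structure:
    """Build a Structure from bare coordinates for geometry tests."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    if elements is None:
        elements = ["C"] * n
    if res_ids is None:
        res_ids = list(range(1, n + 1))
    if res_names is None:
        res_names = ["ALA"] * n
    if atom_names is None:
        atom_names = ["CA"] * n
    elements = np.asarray([e.upper() for e in elements])
    return Structure(
        chain_id=np.asarray([chain] * n, dtype="U4"),
        res_id=np.asarray(res_ids, dtype=int),
        res_name=np.asarray(res_names, dtype="U4"),
        atom_name=np.asarray(atom_names, dtype="U5"),
        element=elements,
        coord=coords,
        b_factor=np.zeros(n),
        radius=np.asarray([VDW_RADII.get(e, DEFAULT_RADIUS)
                           for e in elements]),
    )
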