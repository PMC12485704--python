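"""Shared fixtures: hand-built PDB text and seeded synthetic traces."""

import numpy as np
import pytest

from gaussflex import BackboneParams, make_backbone


def pdb_atom_line(serial, name, res_name, chain, res_seq, x, y, z,
                  occupancy=1.0, altloc=" ", element="C", icode=" "):
    """One fixed-column ATOM record."""
    return (
        f"ATOM  {serial:5d} {name:<4s}{altloc}{res_name:<3s} {chain}"
        f"{res_seq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def make_pdb_text(residues, chain="A"):
    """PDB text from a list of residue dicts.

    Each dict: ``res_seq``, ``atoms`` = list of (name, x, y, z) or
    (name, x, y, z, occupancy, altloc).
    """
    lines = []
    serial = 1
    for res in residues:
        for atom in res["atoms"]:
            name, x, y, z = atom[:4]
            occ = atom[4] if len(atom) > 4 else 1.0
            alt = atom[5] if len(atom) > 5 else " "
            lines.append(
                pdb_atom_line(serial, name, res.get("res_name", "GLY"), chain,
                              res["res_seq"], x, y, z, occupancy=occ, altloc=alt)
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def simple_pdb(tmp_path):
    """Minimal 3-residue single-chain PDB file."""
    residues = [
        {"res_seq": i + 1, "atoms": [("CA", 3.8 * i, (-1.0) ** i, 0.1 * i)]}
        for i in range(3)
    ]
    path = tmp_path / "simple.pdb"
    path.write_text(make_pdb_text(residues))
    return path


@pytest.fixture
def coil_trace():
    return make_backbone(BackboneParams(kind="coil", n_residues=20, seed=12))


@pytest.fixture
def helix_trace():
    return make_backbone(BackboneParams(kind="helix", n_residues=40))


def random_writhe_like_matrix(n, rng):
    """Symmetric matrix with the writhe-matrix zero structure (band |i-j|<=1)."""
    A = rng.normal(size=(n, n))
    W = np.triu(A, 2)
    return W + W.T
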