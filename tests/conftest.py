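"""Shared fixtures: tiny hand-built structures and session-scoped bundles."""

import numpy as np
import pytest

from bundledock.coiledcoil import BundleSpec, ChainSpec, assign_register, build_bundle
from bundledock.structure import Atom, Residue, Structure


def residue(resname, chain_id, seq_id, atoms):
    """atoms: list of (name, element, (x, y, z))."""
    return Residue(resname, seq_id, chain_id,
                   [Atom(n, e, np.array(p, dtype=float)) for n, e, p in atoms])


def ala(chain_id, seq_id, origin=(0.0, 0.0, 0.0)):
    o = np.asarray(origin, float)
    return residue("ALA", chain_id, seq_id, [
        ("N", "N", o + [-1.46, 0.0, 0.0]),
        ("CA", "C", o),
        ("C", "C", o + [1.21, 0.84, 0.0]),
        ("O", "O", o + [1.30, 2.07, 0.0]),
        ("CB", "C", o + [0.12, -0.90, 1.22]),
    ])


def lys(chain_id, seq_id, nz_at):
    """Lysine whose NZ sits exactly at ``nz_at``; arm along +x (backbone at -x)."""
    nz = np.asarray(nz_at, float)
    ca = nz - np.array([5.0, 0.0, 0.0])
    return residue("LYS", chain_id, seq_id, [
        ("N", "N", ca + [-1.2, 0.9, 0.0]),
        ("CA", "C", ca),
        ("C", "C", ca + [-0.9, -1.2, 0.0]),
        ("O", "O", ca + [-2.1, -1.5, 0.0]),
        ("CB", "C", ca + [1.5, 0.0, 0.2]),
        ("CG", "C", ca + [2.6, 0.0, 0.0]),
        ("CD", "C", ca + [3.6, 0.2, 0.0]),
        ("CE", "C", ca + [4.4, 0.0, 0.2]),
        ("NZ", "N", nz),
    ])


def glu(chain_id, seq_id, oe1_at):
    """Glutamate whose OE1 sits exactly at ``oe1_at``; arm along -x (backbone at +x)."""
    oe1 = np.asarray(oe1_at, float)
    ca = oe1 + np.array([4.2, 0.0, 0.0])
    return residue("GLU", chain_id, seq_id, [
        ("N", "N", ca + [1.2, 0.9, 0.0]),
        ("CA", "C", ca),
        ("C", "C", ca + [0.9, -1.2, 0.0]),
        ("O", "O", ca + [2.1, -1.5, 0.0]),
        ("CB", "C", ca + [-1.5, 0.0, 0.2]),
        ("CG", "C", ca + [-2.6, 0.0, 0.0]),
        ("CD", "C", ca + [-3.6, 0.3, 0.0]),
        ("OE1", "O", oe1),
        ("OE2", "O", oe1 + [-0.4, 1.1, 0.0]),
    ])


@pytest.fixture(scope="session")
def ideal_dimer():
    """28-residue parallel homodimer, Leu zipper, mixed surface."""
    seq = "LAAKQAE" * 4
    reg = assign_register(seq, [1])
    spec = BundleSpec([ChainSpec(seq, reg, 1, "A", "A"),
                       ChainSpec(seq, reg, 1, "B", "B")])
    return build_bundle(spec)


@pytest.fixture(scope="session")
def dimer_partition():
    return (["A"], ["B"])


ALA_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.750   1.220  1.00  0.00           C
TER       6      ALA A   1
END
"""


@pytest.fixture()
def ala_pdb(tmp_path):
    p = tmp_path / "ala.pdb"
    p.write_text(ALA_PDB)
    return p
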