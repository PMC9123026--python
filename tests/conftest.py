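"""Shared fixtures and synthetic-fixture builders for the test suite.

All structural fixtures are generated programmatically: backbone
coordinates are constructed atom-by-atom (NeRF internal-coordinate
placement) from prescribed phi/psi torsions with standard bond lengths and
angles, and written as plain-text PDB when a file is needed.
"""

from __future__ import annotations

import numpy as np
import pytest

# standard backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array([
        -np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone(phis, psis):
    """N/CA/C coordinates of a chain with the given phi/psi torsions.

    ``phis[0]`` and ``psis[-1]`` are ignored (undefined at the termini);
    omega is fixed at 180 degrees.  Returns an (n, 3, 3) array.
    """
    n = len(phis)
    assert len(psis) == n
    N = [np.zeros(3)]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = np.radians(ANGLE_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(n - 1):
        nn = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psis[i])
        can = place_atom(CA[i], C[i], nn, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        cn = place_atom(C[i], nn, can, BOND_CA_C, ANGLE_N_CA_C, phis[i + 1])
        N.append(nn)
        CA.append(can)
        C.append(cn)
    return np.stack([np.stack([N[i], CA[i], C[i]]) for i in range(n)])


def write_pdb(path, sequence, atoms, chain_id="A"):
    """Write N/CA/C coordinates as a minimal plain-text PDB file."""
    lines = []
    serial = 1
    for i, aa in enumerate(sequence):
        res = THREE_LETTER[aa]
        for name, pos in zip(("N", "CA", "C"), atoms[i]):
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {res} {chain_id}{i + 1:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
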