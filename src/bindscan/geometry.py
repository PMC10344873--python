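"""Idealised side-chain geometry.

Side chains are rebuilt from internal coordinates (bond length, bond angle,
dihedral) relative to the backbone N/CA/C atoms, with the rotatable dihedrals
driven by chi angles from the rotamer library.  Geometry is idealised, not
crystallographic: bond lengths and angles are canonical values, and aromatic
rings are closed approximately by fixed dihedrals.  That is sufficient for a
pairwise-decomposable energy model on heavy atoms; no hydrogens are built.
"""

from __future__ import annotations

import math
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple, Union

import numpy as np

# Dihedral spec: a fixed angle in degrees, or ("chi", k) / ("chi", k, offset)
# meaning chi_k (1-based) plus a fixed offset for branch atoms.
Dihedral = Union[float, Tuple[str, int], Tuple[str, int, float]]

# Entry: (atom, a1, a2, a3, bond Å, angle X-a1-a2 deg, dihedral X-a1-a2-a3)
Entry = Tuple[str, str, str, str, float, float, Dihedral]

# CB improper dihedral CB-CA-N-C producing an L-amino-acid-like branch.
_CB: Entry = ("CB", "CA", "N", "C", 1.53, 110.5, 122.5)

SIDECHAIN_TEMPLATES: Dict[str, List[Entry]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", "CB", "CA", "N", 1.42, 110.8, ("chi", 1))],
    "CYS": [_CB, ("SG", "CB", "CA", "N", 1.81, 113.0, ("chi", 1))],
    "THR": [
        _CB,
        ("OG1", "CB", "CA", "N", 1.42, 109.5, ("chi", 1)),
        ("CG2", "CB", "CA", "N", 1.52, 110.5, ("chi", 1, -120.0)),
    ],
    "VAL": [
        _CB,
        ("CG1", "CB", "CA", "N", 1.52, 110.5, ("chi", 1)),
        ("CG2", "CB", "CA", "N", 1.52, 110.5, ("chi", 1, 120.0)),
    ],
    "LEU": [
        _CB,
        ("CG", "CB", "CA", "N", 1.53, 116.0, ("chi", 1)),
        ("CD1", "CG", "CB", "CA", 1.52, 110.7, ("chi", 2)),
        ("CD2", "CG", "CB", "CA", 1.52, 110.7, ("chi", 2, 120.0)),
    ],
    "ILE": [
        _CB,
        ("CG1", "CB", "CA", "N", 1.53, 110.4, ("chi", 1)),
        ("CG2", "CB", "CA", "N", 1.52, 110.5, ("chi", 1, -120.0)),
        ("CD1", "CG1", "CB", "CA", 1.52, 113.9, ("chi", 2)),
    ],
    "MET": [
        _CB,
        ("CG", "CB", "CA", "N", 1.52, 114.0, ("chi", 1)),
        ("SD", "CG", "CB", "CA", 1.81, 112.7, ("chi", 2)),
        ("CE", "SD", "CG", "CB", 1.79, 100.9, ("chi", 3)),
    ],
    "PRO": [
        _CB,
        ("CG", "CB", "CA", "N", 1.49, 104.5, ("chi", 1)),
        ("CD", "CG", "CB", "CA", 1.50, 106.1, ("chi", 2)),
    ],
    "PHE": [
        _CB,
        ("CG", "CB", "CA", "N", 1.51, 114.0, ("chi", 1)),
        ("CD1", "CG", "CB", "CA", 1.39, 120.0, ("chi", 2)),
        ("CD2", "CG", "CB", "CA", 1.39, 120.0, ("chi", 2, 180.0)),
        ("CE1", "CD1", "CG", "CB", 1.39, 120.0, 180.0),
        ("CE2", "CD2", "CG", "CB", 1.39, 120.0, 180.0),
        ("CZ", "CE1", "CD1", "CG", 1.39, 120.0, 0.0),
    ],
    "TRP": [
        _CB,
        ("CG", "CB", "CA", "N", 1.50, 114.0, ("chi", 1)),
        ("CD1", "CG", "CB", "CA", 1.37, 127.0, ("chi", 2)),
        ("CD2", "CG", "CB", "CA", 1.43, 126.0, ("chi", 2, 180.0)),
        ("NE1", "CD1", "CG", "CB", 1.38, 110.0, 180.0),
        ("CE2", "CD2", "CG", "CB", 1.40, 107.0, 180.0),
        ("CE3", "CD2", "CG", "CB", 1.40, 125.0, 0.0),
        ("CZ2", "CE2", "CD2", "CG", 1.40, 122.0, 180.0),
        ("CZ3", "CE3", "CD2", "CG", 1.39, 118.0, 180.0),
        ("CH2", "CZ2", "CE2", "CD2", 1.37, 117.0, 180.0),
    ],
    "ASP": [
        _CB,
        ("CG", "CB", "CA", "N", 1.52, 113.0, ("chi", 1)),
        ("OD1", "CG", "CB", "CA", 1.25, 118.5, ("chi", 2)),
        ("OD2", "CG", "CB", "CA", 1.25, 118.5, ("chi", 2, 180.0)),
    ],
    "ASN": [
        _CB,
        ("CG", "CB", "CA", "N", 1.52, 112.7, ("chi", 1)),
        ("OD1", "CG", "CB", "CA", 1.23, 120.8, ("chi", 2)),
        ("ND2", "CG", "CB", "CA", 1.33, 116.4, ("chi", 2, 180.0)),
    ],
    "GLU": [
        _CB,
        ("CG", "CB", "CA", "N", 1.52, 114.0, ("chi", 1)),
        ("CD", "CG", "CB", "CA", 1.52, 112.6, ("chi", 2)),
        ("OE1", "CD", "CG", "CB", 1.25, 118.5, ("chi", 3)),
        ("OE2", "CD", "CG", "CB", 1.25, 118.5, ("chi", 3, 180.0)),
    ],
    "GLN": [
        _CB,
        ("CG", "CB", "CA", "N", 1.52, 114.0, ("chi", 1)),
        ("CD", "CG", "CB", "CA", 1.52, 112.6, ("chi", 2)),
        ("OE1", "CD", "CG", "CB", 1.23, 120.8, ("chi", 3)),
        ("NE2", "CD", "CG", "CB", 1.33, 116.4, ("chi", 3, 180.0)),
    ],
    "LYS": [
        _CB,
        ("CG", "CB", "CA", "N", 1.52, 114.0, ("chi", 1)),
        ("CD", "CG", "CB", "CA", 1.52, 111.3, ("chi", 2)),
        ("CE", "CD", "CG", "CB", 1.52, 111.7, ("chi", 3)),
        ("NZ", "CE", "CD", "CG", 1.49, 111.9, ("chi", 4)),
    ],
    "ARG": [
        _CB,
        ("CG", "CB", "CA", "N", 1.52, 114.0, ("chi", 1)),
        ("CD", "CG", "CB", "CA", 1.52, 111.3, ("chi", 2)),
        ("NE", "CD", "CG", "CB", 1.46, 111.5, ("chi", 3)),
        ("CZ", "NE", "CD", "CG", 1.33, 124.0, ("chi", 4)),
        ("NH1", "CZ", "NE", "CD", 1.33, 120.0, 0.0),
        ("NH2", "CZ", "NE", "CD", 1.33, 120.0, 180.0),
    ],
    "HIS": [
        _CB,
        ("CG", "CB", "CA", "N", 1.49, 114.0, ("chi", 1)),
        ("ND1", "CG", "CB", "CA", 1.38, 122.7, ("chi", 2)),
        ("CD2", "CG", "CB", "CA", 1.36, 131.0, ("chi", 2, 180.0)),
        ("CE1", "ND1", "CG", "CB", 1.32, 109.0, 180.0),
        ("NE2", "CD2", "CG", "CB", 1.37, 107.0, 180.0),
    ],
}

# His protonation variants share the imidazole geometry.
for _v in ("HIS_H1", "HIS_H2", "HIS_H3"):
    SIDECHAIN_TEMPLATES[_v] = SIDECHAIN_TEMPLATES["HIS"]

# Ring/cycle closures not expressed by the parent tree above.
EXTRA_BONDS: Dict[str, List[Tuple[str, str]]] = {
    "PHE": [("CZ", "CE2")],
    "TYR": [("CZ", "CE2")],
    "TRP": [("NE1", "CE2"), ("CH2", "CZ3")],
    "HIS": [("CE1", "NE2")],
    "HIS_H1": [("CE1", "NE2")],
    "HIS_H2": [("CE1", "NE2")],
    "HIS_H3": [("CE1", "NE2")],
    "PRO": [("CD", "N")],
}

SIDECHAIN_TEMPLATES["TYR"] = SIDECHAIN_TEMPLATES["PHE"] + [
    ("OH", "CZ", "CE1", "CD1", 1.38, 120.0, 180.0)
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def num_chi(res_type: str) -> int:
    """Number of chi dihedrals a residue type's template consumes."""
    k = 0
    for entry in SIDECHAIN_TEMPLATES[res_type]:
        dih = entry[6]
        if isinstance(dih, tuple):
            k = max(k, dih[1])
    return k


def place_atom(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place X bonded to p1 with angle(X,p1,p2)=angle, torsion(X,p1,p2,p3)=torsion (NeRF)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    bc = p1 - p2
    bc = bc / np.linalg.norm(bc)
    ab = p2 - p3
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return p1 + rot @ d


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def build_sidechain(
    res_type: str,
    chis: Sequence[float],
    backbone: Dict[str, np.ndarray],
) -> List[Tuple[str, np.ndarray]]:
    """Construct side-chain heavy-atom coordinates for ``res_type``.

    ``backbone`` must supply N, CA and C positions.  ``chis`` supplies the
    rotatable dihedrals in order (chi1, chi2, ...); its length must equal
    :func:`num_chi` for the type.
    """
    template = SIDECHAIN_TEMPLATES[res_type]
    need = num_chi(res_type)
    if len(chis) != need:
        raise ValueError(
            f"{res_type} requires {need} chi angles, got {len(chis)}"
        )
    coords: Dict[str, np.ndarray] = {
        "N": np.asarray(backbone["N"], dtype=float),
        "CA": np.asarray(backbone["CA"], dtype=float),
        "C": np.asarray(backbone["C"], dtype=float),
    }
    out: List[Tuple[str, np.ndarray]] = []
    for name, a1, a2, a3, bond, angle, dih in template:
        if isinstance(dih, tuple):
            k = dih[1]
            offset = dih[2] if len(dih) == 3 else 0.0
            torsion = chis[k - 1] + offset
        else:
            torsion = dih
        pos = place_atom(coords[a1], coords[a2], coords[a3], bond, angle, torsion)
        coords[name] = pos
        out.append((name, pos))
    return out


def residue_bond_graph(res_type: str) -> Dict[str, Set[str]]:
    """Heavy-atom bond graph of one residue (backbone + side chain + closures)."""
    adj: Dict[str, Set[str]] = {}

    def add(a: str, b: str) -> None:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    add("N", "CA")
    add("CA", "C")
    add("C", "O")
    for entry in SIDECHAIN_TEMPLATES.get(res_type, []):
        add(entry[0], entry[1])
    for a, b in EXTRA_BONDS.get(res_type, []):
        add(a, b)
    return adj


def excluded_pairs(res_type: str) -> FrozenSet[FrozenSet[str]]:
    """Intra-residue atom pairs separated by 1 or 2 bonds (1-2/1-3 exclusions)."""
    adj = residue_bond_graph(res_type)
    pairs: Set[FrozenSet[str]] = set()
    for a, nbrs in adj.items():
        for b in nbrs:
            pairs.add(frozenset((a, b)))
            for c in adj[b]:
                if c != a:
                    pairs.add(frozenset((a, c)))
    return frozenset(pairs)
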