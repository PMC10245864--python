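"""Internal-coordinate (NeRF) atom placement and residue z-matrices.

Every heavy atom of every canonical residue type is defined relative to
three previously placed reference atoms by a bond length (Angstrom), a bond
angle (degrees) and a torsion (degrees).  Sidechain torsions are expressed
in terms of the rotatable chi angles where chemistry allows, and fixed for
rigid groups (planar rings, guanidinium, amides).

The same dataset drives the synthetic-fixture builder and, measured once on
a reference build, the ideal bond-length/angle tables of the geometry
metrics, so the two are exactly self-consistent: a fixture built from these
values scores a bond-length RMSE of zero.

Values are Engh-Huber-style standards; five- and six-membered aromatic
rings are laid out as exact regular polygons (imidazole side 1.370 A,
benzene side 1.390 A) so that the ring-closure bonds close exactly.  The
proline ring closes only at its reference torsions (a near-flat ring under
the generic tetrahedral CA/CB angles used here), where the CD-N closure
distance defines the ideal; other puckers strain the ring, as in real
chemistry.
"""

from __future__ import annotations

from typing import Dict, List, Tuple, Union

import numpy as np

from .residues import AA_ORDER

__all__ = [
    "BACKBONE_GEOM",
    "CB_TORSION",
    "SIDECHAIN_ZMAT",
    "CHI_ATOMS",
    "SYMMETRIC_CHI",
    "REFERENCE_CHIS",
    "N_CHI",
    "place_atom",
    "build_residue_frame",
]

# --------------------------------------------------------------------------
# NeRF placement
# --------------------------------------------------------------------------

_COLLINEAR_TOL = 1e-8


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    length: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place a point p with |p-c| = length, angle(b,c,p) = angle and
    dihedral(a,b,c,p) = torsion (degrees, IUPAC sign convention).

    Raises ValueError if the three reference points are collinear.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    bc = c - b
    bc_n = np.linalg.norm(bc)
    if bc_n < _COLLINEAR_TOL:
        raise ValueError("reference atoms b and c coincide")
    bc = bc / bc_n
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < _COLLINEAR_TOL:
        raise ValueError("reference atoms a, b, c are collinear")
    n = n / n_norm
    m = np.cross(n, bc)
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    d = np.array(
        [
            -length * np.cos(ang),
            length * np.sin(ang) * np.cos(tor),
            length * np.sin(ang) * np.sin(tor),
        ]
    )
    frame = np.stack([bc, m, n], axis=1)
    return c + frame @ d


# --------------------------------------------------------------------------
# Backbone geometry
# --------------------------------------------------------------------------

#: Backbone bond lengths (A) and angles (deg).
BACKBONE_GEOM: Dict[str, float] = {
    "N_CA": 1.458,
    "CA_C": 1.525,
    "C_N": 1.329,      # peptide bond
    "C_O": 1.231,
    "CA_CB": 1.530,
    "N_CA_C": 111.0,
    "CA_C_N": 116.2,
    "C_N_CA": 121.7,
    "CA_C_O": 120.8,
    "N_CA_CB": 110.4,
    "OMEGA": 180.0,    # trans peptide
}

#: Improper torsion dihedral(C, N, CA, CB) fixing the L configuration at CA.
#: The sign convention is validated against the community backbone-to-CB
#: reconstruction vector formula (see tests).
CB_TORSION: float = -122.6

# --------------------------------------------------------------------------
# Sidechain z-matrices
# --------------------------------------------------------------------------

# Torsion spec: ("chi", k, offset) -> chis[k-1] + offset; ("fixed", value).
Tor = Union[Tuple[str, int, float], Tuple[str, float]]
# Entry: (atom, (ref_a, ref_b, ref_c), length, angle, torsion_spec)
ZEntry = Tuple[str, Tuple[str, str, str], float, float, Tor]


def _chi(k: int, offset: float = 0.0) -> Tor:
    return ("chi", k, offset)


def _fix(v: float) -> Tor:
    return ("fixed", v)


SIDECHAIN_ZMAT: Dict[str, List[ZEntry]] = {
    "ALA": [],
    "GLY": [],
    "ARG": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
        ("NE", ("CB", "CG", "CD"), 1.460, 112.0, _chi(3)),
        ("CZ", ("CG", "CD", "NE"), 1.330, 124.2, _chi(4)),
        ("NH1", ("CD", "NE", "CZ"), 1.330, 120.0, _fix(0.0)),
        ("NH2", ("CD", "NE", "CZ"), 1.330, 120.0, _fix(180.0)),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, _chi(2)),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, _chi(2, 180.0)),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2)),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2, 180.0)),
    ],
    "CYS": [
        ("SG", ("N", "CA", "CB"), 1.808, 114.4, _chi(1)),
    ],
    "GLN": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
        ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, _chi(3)),
        ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, _chi(3, 180.0)),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
        ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3)),
        ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3, 180.0)),
    ],
    # Imidazole as an exact regular pentagon, side 1.370 A.
    "HIS": [
        ("CG", ("N", "CA", "CB"), 1.497, 113.8, _chi(1)),
        ("ND1", ("CA", "CB", "CG"), 1.370, 126.0, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.370, 126.0, _chi(2, 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.370, 108.0, _fix(180.0)),
        ("NE2", ("CG", "ND1", "CE1"), 1.370, 108.0, _fix(0.0)),
    ],
    "ILE": [
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.9, _chi(2)),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, _chi(1)),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2, 122.0)),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
        ("CE", ("CB", "CG", "CD"), 1.508, 111.9, _chi(3)),
        ("NZ", ("CG", "CD", "CE"), 1.489, 111.7, _chi(4)),
    ],
    "MET": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("SD", ("CA", "CB", "CG"), 1.803, 112.7, _chi(2)),
        ("CE", ("CB", "CG", "SD"), 1.791, 100.9, _chi(3)),
    ],
    # Benzene as an exact regular hexagon, side 1.390 A.
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.508, 113.8, _chi(1)),
        ("CD1", ("CA", "CB", "CG"), 1.390, 120.0, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.390, 120.0, _chi(2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.390, 120.0, _fix(180.0)),
        ("CE2", ("CB", "CG", "CD2"), 1.390, 120.0, _fix(180.0)),
        ("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, _fix(0.0)),
    ],
    "PRO": [
        ("CG", ("N", "CA", "CB"), 1.495, 104.5, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.507, 106.1, _chi(2)),
    ],
    "SER": [
        ("OG", ("N", "CA", "CB"), 1.417, 110.8, _chi(1)),
    ],
    "THR": [
        ("OG1", ("N", "CA", "CB"), 1.433, 109.6, _chi(1)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.0)),
    ],
    # Indole: planar fused bicycle; the two closure bonds (NE1-CE2, CZ2-CH2)
    # take their ideal lengths from the reference build.
    "TRP": [
        ("CG", ("N", "CA", "CB"), 1.498, 113.6, _chi(1)),
        ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.433, 126.6, _chi(2, 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, _fix(180.0)),
        ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, _fix(180.0)),
        ("CE3", ("CB", "CG", "CD2"), 1.398, 130.4, _fix(0.0)),
        ("CZ2", ("CG", "CD2", "CE2"), 1.394, 121.3, _fix(180.0)),
        ("CZ3", ("CE2", "CD2", "CE3"), 1.382, 115.0, _fix(0.0)),
        ("CH2", ("CD2", "CE3", "CZ3"), 1.400, 124.1, _fix(0.0)),
    ],
    "TYR": [
        ("CG", ("N", "CA", "CB"), 1.512, 113.8, _chi(1)),
        ("CD1", ("CA", "CB", "CG"), 1.390, 120.0, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.390, 120.0, _chi(2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.390, 120.0, _fix(180.0)),
        ("CE2", ("CB", "CG", "CD2"), 1.390, 120.0, _fix(180.0)),
        ("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, _fix(0.0)),
        ("OH", ("CD1", "CE1", "CZ"), 1.376, 120.0, _fix(180.0)),
    ],
    "VAL": [
        ("CG1", ("N", "CA", "CB"), 1.527, 110.5, _chi(1)),
        ("CG2", ("N", "CA", "CB"), 1.527, 110.5, _chi(1, 122.0)),
    ],
}

# --------------------------------------------------------------------------
# Chi angle definitions
# --------------------------------------------------------------------------

#: Atom quadruples defining chi_1..chi_4 per residue type (standard
#: nomenclature); residues without a given chi are simply shorter lists.
CHI_ATOMS: Dict[str, List[Tuple[str, str, str, str]]] = {
    "ALA": [],
    "GLY": [],
    "ARG": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "NE"),
        ("CG", "CD", "NE", "CZ"),
    ],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ],
    "GLU": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ],
    "MET": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "SD"),
        ("CB", "CG", "SD", "CE"),
    ],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

#: Number of chi angles per residue type.
N_CHI: Dict[str, int] = {aa: len(CHI_ATOMS[aa]) for aa in AA_ORDER}

#: (residue type, chi index 1-based) of 180-degree-symmetric terminal
#: dihedrals, reported in the canonical half-range [-90, 90).
SYMMETRIC_CHI: frozenset = frozenset(
    {("ASP", 2), ("GLU", 3), ("PHE", 2), ("TYR", 2)}
)

#: Reference rotamer torsions (deg) used for the ideal-geometry reference
#: build and as default fixture rotamers (common rotamers).
REFERENCE_CHIS: Dict[str, Tuple[float, ...]] = {
    "ALA": (),
    "GLY": (),
    "ARG": (-67.0, 180.0, 65.0, 85.0),
    "ASN": (-65.0, -20.0),
    "ASP": (-70.0, -15.0),
    "CYS": (-65.0,),
    "GLN": (-67.0, 180.0, -25.0),
    "GLU": (-67.0, 180.0, -10.0),
    "HIS": (-63.0, -75.0),
    "ILE": (-61.0, 169.0),
    "LEU": (-70.0, 165.0),
    "LYS": (-67.0, 180.0, 180.0, 180.0),
    "MET": (-65.0, 180.0, 75.0),
    "PHE": (-65.0, 85.0),
    "PRO": (-14.4, -0.9),
    "SER": (-65.0,),
    "THR": (-60.0,),
    "TRP": (-65.0, 95.0),
    "TYR": (-65.0, 85.0),
    "VAL": (175.0,),
}


def _torsion_value(tor: Tor, chis) -> float:
    if tor[0] == "fixed":
        return float(tor[1])
    _, k, offset = tor
    if len(chis) < k:
        raise ValueError(f"chi{k} required but only {len(chis)} supplied")
    return float(chis[k - 1]) + offset


def build_residue_frame(
    residue_type: str, chis=None, phi_ref: float = -57.0
) -> Dict[str, np.ndarray]:
    """Build one standalone residue from ideal internal coordinates.

    Returns a dict atom name -> 3-vector.  The backbone is laid out from an
    arbitrary local frame (the preceding-C direction is synthesised from
    ``phi_ref``); sidechain torsions default to the reference rotamer.
    Used for the ideal-geometry reference measurements and by the chain
    builder.
    """
    from .residues import RESIDUE_ATOMS, _canon3  # local import, no cycle

    aa = _canon3(residue_type)
    if chis is None:
        chis = REFERENCE_CHIS[aa]
    g = BACKBONE_GEOM
    coords: Dict[str, np.ndarray] = {}
    # Local backbone frame: N at origin, CA on +x, C in the xy-plane.
    coords["N"] = np.zeros(3)
    coords["CA"] = np.array([g["N_CA"], 0.0, 0.0])
    ang = np.deg2rad(g["N_CA_C"])
    coords["C"] = coords["CA"] + g["CA_C"] * np.array(
        [-np.cos(ang), np.sin(ang), 0.0]
    )
    # A virtual preceding carbonyl C, placed with the reference phi, anchors
    # O and CB torsions for a standalone residue.
    c_prev = place_atom(
        coords["C"], coords["CA"], coords["N"],
        g["C_N"], g["C_N_CA"], phi_ref,
    )
    coords["O"] = place_atom(
        coords["N"], coords["CA"], coords["C"], g["C_O"], g["CA_C_O"], 180.0
    )
    if aa != "GLY":
        coords["CB"] = place_atom(
            coords["C"], coords["N"], coords["CA"],
            g["CA_CB"], g["N_CA_CB"], CB_TORSION,
        )
    for atom, (ra, rb, rc), length, angle, tor in SIDECHAIN_ZMAT[aa]:
        coords[atom] = place_atom(
            coords[ra], coords[rb], coords[rc],
            length, angle, _torsion_value(tor, chis),
        )
    assert set(coords) >= set(RESIDUE_ATOMS[aa])
    return coords
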