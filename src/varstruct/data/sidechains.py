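"""Idealized side-chain internal coordinates and a compact rotamer library.

Each side chain beyond CB is described as a Z-matrix: every atom is placed
by natural-extension from three previously placed atoms with an ideal bond
length (A), bond angle (deg) and a torsion that is either a fixed number or
a chi angle reference ('chi1'..'chi4') plus an additive offset for branch
atoms.  Bond lengths and angles are standard peptide-geometry values; ring
closure is by construction (planar rings laid out atom by atom).

The rotamer library is backbone-independent: for each residue type a short
list of chi-angle tuples with prior weights summing to 1, covering the
dominant gauche-/trans/gauche+ combinations seen in high-resolution
structures.  It is intentionally compact — the mutant builder does a
discrete clash-minimizing choice over these, with no continuous refinement.
"""

from __future__ import annotations

# --- backbone ideal geometry -------------------------------------------------

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5
OMEGA_TRANS = 180.0

# Torsion of CB about the backbone, measured as dihedral(C, N, CA, CB);
# the sign fixes L-chirality.
TORSION_C_N_CA_CB = 122.6

# --- side-chain Z-matrices ---------------------------------------------------
# entry: (atom, (ref1, ref2, ref3), bond, angle, torsion)
# torsion: float (fixed) or (chi_name, offset_deg).  ref3 is the bonded atom.

ZMatrixEntry = tuple[str, tuple[str, str, str], float, float, object]

SIDECHAIN_ZMATRIX: dict[str, list[ZMatrixEntry]] = {
    "A": [],
    "G": [],
    "S": [("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi1", 0.0))],
    "C": [("SG", ("N", "CA", "CB"), 1.808, 114.4, ("chi1", 0.0))],
    "T": [
        ("OG1", ("N", "CA", "CB"), 1.433, 109.6, ("chi1", 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi1", -120.0)),
    ],
    "V": [
        ("CG1", ("N", "CA", "CB"), 1.521, 110.5, ("chi1", 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi1", 122.3)),
    ],
    "I": [
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, ("chi1", 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi1", -122.3)),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, ("chi2", 0.0)),
    ],
    "L": [
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, ("chi1", 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, ("chi2", 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, ("chi2", 122.6)),
    ],
    "M": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi1", 0.0)),
        ("SD", ("CA", "CB", "CG"), 1.803, 112.7, ("chi2", 0.0)),
        ("CE", ("CB", "CG", "SD"), 1.791, 100.2, ("chi3", 0.0)),
    ],
    "F": [
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi1", 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.384, 120.7, ("chi2", 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.384, 120.7, ("chi2", 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.382, 120.7, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.382, 120.7, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
    ],
    "Y": [
        ("CG", ("N", "CA", "CB"), 1.512, 113.9, ("chi1", 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.389, 120.8, ("chi2", 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.389, 120.8, ("chi2", 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.382, 121.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.382, 121.2, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0),
    ],
    "W": [
        ("CG", ("N", "CA", "CB"), 1.498, 113.6, ("chi1", 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, ("chi2", 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.433, 126.8, ("chi2", 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
        ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, 180.0),
        ("CH2", ("CD2", "CE3", "CZ3"), 1.368, 121.1, 0.0),
    ],
    "D": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi1", 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, ("chi2", 0.0)),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, ("chi2", 180.0)),
    ],
    "N": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi1", 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, ("chi2", 0.0)),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("chi2", 180.0)),
    ],
    "E": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi1", 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi2", 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, ("chi3", 0.0)),
        ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, ("chi3", 180.0)),
    ],
    "Q": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi1", 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi2", 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, ("chi3", 0.0)),
        ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, ("chi3", 180.0)),
    ],
    "K": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi1", 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi2", 0.0)),
        ("CE", ("CB", "CG", "CD"), 1.520, 111.3, ("chi3", 0.0)),
        ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, ("chi4", 0.0)),
    ],
    "R": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi1", 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi2", 0.0)),
        ("NE", ("CB", "CG", "CD"), 1.460, 111.8, ("chi3", 0.0)),
        ("CZ", ("CG", "CD", "NE"), 1.329, 124.6, ("chi4", 0.0)),
        ("NH1", ("CD", "NE", "CZ"), 1.326, 120.3, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.326, 120.3, 180.0),
    ],
    "H": [
        ("CG", ("N", "CA", "CB"), 1.497, 113.8, ("chi1", 0.0)),
        ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, ("chi2", 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.354, 131.2, ("chi2", 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.321, 109.3, 180.0),
        ("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0),
    ],
    "P": [
        ("CG", ("N", "CA", "CB"), 1.492, 104.5, ("chi1", 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.503, 106.1, ("chi2", 0.0)),
    ],
}

# --- rotamer library ---------------------------------------------------------
# residue -> list of (chi tuple in degrees, prior weight); weights sum to 1.

ROTAMERS: dict[str, list[tuple[tuple[float, ...], float]]] = {
    "A": [((), 1.0)],
    "G": [((), 1.0)],
    "S": [((-65.0,), 0.45), ((180.0,), 0.25), ((62.0,), 0.30)],
    "C": [((-65.0,), 0.50), ((180.0,), 0.30), ((62.0,), 0.20)],
    "T": [((-60.0,), 0.45), ((60.0,), 0.45), ((180.0,), 0.10)],
    "V": [((175.0,), 0.65), ((-60.0,), 0.25), ((64.0,), 0.10)],
    "I": [((-65.0, 170.0), 0.55), ((-57.0, -60.0), 0.15),
          ((180.0, 165.0), 0.15), ((62.0, 170.0), 0.15)],
    "L": [((-65.0, 175.0), 0.55), ((180.0, 65.0), 0.30),
          ((-85.0, 65.0), 0.10), ((180.0, 180.0), 0.05)],
    "M": [((-65.0, 180.0, 75.0), 0.25), ((-65.0, 180.0, 180.0), 0.25),
          ((-65.0, 180.0, -75.0), 0.20), ((180.0, 180.0, 75.0), 0.15),
          ((180.0, 180.0, 180.0), 0.15)],
    "F": [((-65.0, 90.0), 0.50), ((180.0, 80.0), 0.35), ((62.0, 90.0), 0.15)],
    "Y": [((-65.0, 90.0), 0.50), ((180.0, 80.0), 0.35), ((62.0, 90.0), 0.15)],
    "W": [((-65.0, 95.0), 0.30), ((-65.0, -90.0), 0.25),
          ((180.0, -105.0), 0.25), ((62.0, -90.0), 0.20)],
    "D": [((-65.0, -15.0), 0.50), ((180.0, 15.0), 0.30), ((62.0, -15.0), 0.20)],
    "N": [((-65.0, -20.0), 0.45), ((180.0, 30.0), 0.30),
          ((62.0, -20.0), 0.15), ((-65.0, 120.0), 0.10)],
    "E": [((-65.0, 180.0, -10.0), 0.40), ((180.0, 180.0, 0.0), 0.30),
          ((-65.0, -65.0, -40.0), 0.20), ((62.0, 180.0, 0.0), 0.10)],
    "Q": [((-65.0, 180.0, -20.0), 0.40), ((180.0, 180.0, 20.0), 0.30),
          ((-65.0, -65.0, -40.0), 0.20), ((62.0, 180.0, 20.0), 0.10)],
    "K": [((-65.0, 180.0, 180.0, 180.0), 0.40),
          ((180.0, 180.0, 180.0, 180.0), 0.30),
          ((-65.0, -68.0, 180.0, 180.0), 0.10),
          ((-65.0, 180.0, 180.0, -65.0), 0.10),
          ((62.0, 180.0, 180.0, 180.0), 0.10)],
    "R": [((-65.0, 180.0, 180.0, 180.0), 0.35),
          ((180.0, 180.0, 180.0, 180.0), 0.25),
          ((-65.0, 180.0, -65.0, -85.0), 0.15),
          ((-65.0, -68.0, 180.0, 180.0), 0.15),
          ((62.0, 180.0, 180.0, 180.0), 0.10)],
    "H": [((-65.0, -75.0), 0.40), ((180.0, 75.0), 0.30),
          ((-65.0, 75.0), 0.15), ((62.0, -75.0), 0.15)],
    "P": [((-26.0, 38.0), 0.55), ((26.0, -35.0), 0.45)],
}

LIBRARY_VERSION = "compact-1"
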