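"""Chemical reference data.

Van der Waals radii follow the Chothia set used by classical accessibility
programs; maximum per-residue accessibilities are theoretical Gly-X-Gly
values, so relative accessibility of extended conformations may exceed 100%.
"""

from __future__ import annotations

# Chothia van-der-Waals radii (Angstrom), keyed by element.
VDW_RADII: dict[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "H": 1.00,
}
DEFAULT_VDW_RADIUS = 1.80

# Theoretical maximum accessible surface areas (A^2) of residue X in an
# extended Gly-X-Gly tripeptide (Tien et al. 2013 theoretical set).
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Burial-class thresholds on relative accessibility (percent).  A value
# exactly on a boundary goes to the more exposed class.
RSA_BURIED_MAX = 20.0       # rsa <  20  -> buried
RSA_PARTIAL_MAX = 50.0      # 20 <= rsa < 50 -> partially exposed; >= 50 exposed

# Side-chain nitrogen atoms carrying positive charge and side-chain oxygen
# atoms carrying negative charge, for salt-bridge detection.  Histidine is
# treated as positively charged.
BASIC_NITROGENS: dict[str, tuple[str, ...]] = {
    "K": ("NZ",),
    "R": ("NE", "NH1", "NH2"),
    "H": ("ND1", "NE2"),
}
ACIDIC_OXYGENS: dict[str, tuple[str, ...]] = {
    "D": ("OD1", "OD2"),
    "E": ("OE1", "OE2"),
}

# Apolar side-chain carbons (carbons whose bonded heavy neighbours are all
# carbon or sulfur) used for hydrophobic-contact detection.
APOLAR_CARBONS: dict[str, tuple[str, ...]] = {
    "A": ("CB",),
    "R": ("CB", "CG"),
    "N": ("CB",),
    "D": ("CB",),
    "C": ("CB",),
    "Q": ("CB", "CG"),
    "E": ("CB", "CG"),
    "G": (),
    "H": ("CB",),
    "I": ("CB", "CG1", "CG2", "CD1"),
    "L": ("CB", "CG", "CD1", "CD2"),
    "K": ("CB", "CG", "CD"),
    "M": ("CB", "CG", "CE"),
    "F": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "P": ("CB", "CG", "CD"),
    "S": ("CB",),
    "T": ("CG2",),
    "W": ("CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "Y": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "V": ("CB", "CG1", "CG2"),
}

# Hydrogen-bond donors: donor atom -> (antecedent atom, geometry, n_hydrogens).
# geometry: 'sp2' hydrogens fixed in the plane of the group, 'sp3' rotatable
# about the antecedent-donor axis, 'hydroxyl' rotatable single hydrogen.
SIDECHAIN_DONORS: dict[str, tuple[tuple[str, str, str, int], ...]] = {
    "R": (("NE", "CD", "sp2", 1), ("NH1", "CZ", "sp2", 2), ("NH2", "CZ", "sp2", 2)),
    "K": (("NZ", "CE", "sp3", 3),),
    "H": (("ND1", "CG", "sp2", 1), ("NE2", "CD2", "sp2", 1)),
    "W": (("NE1", "CD1", "sp2", 1),),
    "N": (("ND2", "CG", "sp2", 2),),
    "Q": (("NE2", "CD", "sp2", 2),),
    "S": (("OG", "CB", "hydroxyl", 1),),
    "T": (("OG1", "CB", "hydroxyl", 1),),
    "Y": (("OH", "CZ", "hydroxyl", 1),),
}

# Hydrogen-bond acceptors: residue -> side-chain acceptor atom names.
# Backbone carbonyl O (and terminal OXT) is an acceptor for every residue.
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "D": ("OD1", "OD2"),
    "E": ("OE1", "OE2"),
    "N": ("OD1",),
    "Q": ("OE1",),
    "S": ("OG",),
    "T": ("OG1",),
    "Y": ("OH",),
    "H": ("ND1", "NE2"),
    "M": (),
}


def element_of(atom_name: str) -> str:
    """Infer the element from a PDB heavy-atom name."""
    name = atom_name.strip()
    if not name:
        return ""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)
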