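"""Geometric placement of polar hydrogens on donor groups.

Input structures are heavy-atom only (hydrogens are dropped at read time);
hydrogens needed for H-bond detection are rebuilt here by idealized
geometry, so wild-type and mutant models are treated identically:

* backbone amide H: in the peptide plane, 1.0 A from N, opposite the
  bisector of the N-CA and N-C(prev) bonds (proline and chain-leading
  residues have none);
* sp2 side-chain N-H (Arg, His, Trp, Asn, Gln): fixed in the plane of the
  group, completing trigonal geometry;
* rotatable donors (Lys NZ, Ser/Thr/Tyr hydroxyls): hydrogen constrained to
  the tetrahedral cone about the antecedent bond, azimuth oriented toward
  the nearest candidate acceptor.
"""

from __future__ import annotations

import numpy as np

from .core import ProteinStructure, Residue
from .data.chemistry import SIDECHAIN_DONORS
from .geometry import unit

N_H_BOND = 1.00  # A
O_H_BOND = 0.96  # A
TETRA_ANGLE = 109.5  # deg


def _bisector_h(donor: np.ndarray, n1: np.ndarray, n2: np.ndarray,
                bond: float = N_H_BOND) -> np.ndarray:
    """H opposite the bisector of two heavy-atom neighbours of the donor."""
    d = -(unit(n1 - donor) + unit(n2 - donor))
    return donor + bond * unit(d)


def _sp2_pair(donor: np.ndarray, antecedent: np.ndarray, plane_ref: np.ndarray,
              bond: float = N_H_BOND) -> list[np.ndarray]:
    """Two hydrogens completing a trigonal NH2 in the group plane."""
    axis = unit(donor - antecedent)
    ref = plane_ref - antecedent
    perp = ref - np.dot(ref, axis) * axis
    w = unit(perp)
    out = []
    for sign in (1.0, -1.0):
        # 120 deg from the antecedent bond (60 deg from its extension),
        # in-plane, two mirror positions
        d = np.cos(np.radians(60.0)) * axis + sign * np.sin(np.radians(60.0)) * w
        out.append(donor + bond * unit(d))
    return out


def _cone_h(donor: np.ndarray, antecedent: np.ndarray, toward: np.ndarray,
            bond: float, cone_angle: float = TETRA_ANGLE,
            n_equivalent: int = 1) -> list[np.ndarray]:
    """Hydrogen(s) on the rotatable cone about antecedent->donor, the first
    oriented as close to `toward` as the cone allows."""
    a = unit(antecedent - donor)
    t = toward - donor
    perp = t - np.dot(t, a) * a
    if np.linalg.norm(perp) < 1e-9:  # acceptor on-axis; arbitrary fixed azimuth
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, a)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        perp = helper - np.dot(helper, a) * a
    w = unit(perp)
    theta = np.radians(cone_angle)
    hs = []
    for k in range(n_equivalent):
        phi = 2.0 * np.pi * k / 3.0 if n_equivalent > 1 else 0.0
        w2 = np.cos(phi) * w + np.sin(phi) * np.cross(a, w)
        hs.append(donor + bond * (np.cos(theta) * a + np.sin(theta) * w2))
    return hs


def backbone_amide_h(prev: Residue | None, res: Residue) -> np.ndarray | None:
    """Amide hydrogen of `res`, or None (proline, missing atoms, chain start)."""
    if res.aa == "P" or prev is None:
        return None
    n, ca = res.atom("N"), res.atom("CA")
    c_prev = prev.atom("C")
    if n is None or ca is None or c_prev is None:
        return None
    return _bisector_h(n.coords, ca.coords, c_prev.coords)


def sidechain_donor_hydrogens(res: Residue, acceptors: np.ndarray | None
                              ) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """All side-chain donor hydrogens of a residue.

    Returns (donor atom name, donor coords, H coords) triples.  `acceptors`
    is an (M, 3) array of candidate acceptor positions used to orient
    rotatable donors; rotatables fall back to a fixed azimuth when empty.
    """
    out: list[tuple[str, np.ndarray, np.ndarray]] = []
    for donor_name, ante_name, geom, n_h in SIDECHAIN_DONORS.get(res.aa, ()):
        donor = res.atom(donor_name)
        ante = res.atom(ante_name)
        if donor is None or ante is None:
            continue  # incomplete side chain: donor skipped
        d, a = donor.coords, ante.coords
        if geom == "sp2":
            hs = _sp2_hydrogens(res, donor_name, ante_name, d, a, n_h)
        else:
            bond = N_H_BOND if donor_name.startswith("N") else O_H_BOND
            toward = _nearest(acceptors, d)
            if toward is None:
                toward = d + np.array([1.0, 0.0, 0.0])
            hs = _cone_h(d, a, toward, bond,
                         n_equivalent=3 if geom == "sp3" else 1)
            if geom == "sp3":
                hs = hs[:n_h]
        out.extend((donor_name, d, h) for h in hs)
    return out


def _nearest(points: np.ndarray | None, ref: np.ndarray) -> np.ndarray | None:
    if points is None or len(points) == 0:
        return None
    d = np.linalg.norm(points - ref, axis=1)
    return points[int(np.argmin(d))]


def _sp2_hydrogens(res: Residue, donor_name: str, ante_name: str,
                   d: np.ndarray, a: np.ndarray, n_h: int) -> list[np.ndarray]:
    """Fixed in-plane hydrogens for sp2 nitrogens."""
    # second heavy neighbour (ring closure) if the nitrogen has one
    second = {
        ("R", "NE"): "CZ", ("H", "ND1"): "CE1", ("H", "NE2"): "CE1",
        ("W", "NE1"): "CE2",
    }.get((res.aa, donor_name))
    if second is not None:
        other = res.atom(second)
        if other is None:
            return []
        return [_bisector_h(d, a, other.coords)]
    if n_h == 1:
        nb = res.atom(ante_name)
        return [] if nb is None else [d + N_H_BOND * unit(d - a)]
    # NH2 groups: need an in-plane reference atom bonded to the antecedent
    plane_ref_name = {
        ("R", "NH1"): "NE", ("R", "NH2"): "NE",
        ("N", "ND2"): "OD1", ("Q", "NE2"): "OE1",
    }.get((res.aa, donor_name))
    ref_atom = res.atom(plane_ref_name) if plane_ref_name else None
    if ref_atom is None:
        return []
    return _sp2_pair(d, a, ref_atom.coords)


def collect_acceptor_coords(structure: ProteinStructure,
                            extra: ProteinStructure | None = None) -> np.ndarray:
    """Coordinates of every H-bond acceptor atom (for orienting rotatables)."""
    from .data.chemistry import SIDECHAIN_ACCEPTORS
    pts = []
    chains = [structure] + ([extra] if extra is not None else [])
    for s in chains:
        for r in s.residues:
            for at in r.atoms:
                if at.name in ("O", "OXT") or \
                        at.name in SIDECHAIN_ACCEPTORS.get(r.aa, ()):
                    pts.append(at.coords)
    return np.array(pts).reshape(-1, 3)
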