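"""First-principles structural analysis operators.

This module computes, from heavy-atom coordinates alone, the per-residue
structural profile used to compare wild-type and mutant models:

* secondary structure by the Kabsch-Sander electrostatic H-bond model
  (reduced alphabet H/G/E/T/C);
* solvent-accessible surface area by Shrake-Rupley sphere sampling with a
  deterministic golden-spiral point set, and relative accessibility
  against Gly-X-Gly reference maxima with buried / partially exposed /
  exposed classes;
* geometric H-bonds (donor-acceptor and hydrogen-acceptor distances plus
  a donor-hydrogen-acceptor angle, after geometric hydrogen placement);
* salt bridges (basic side-chain N within cutoff of acidic side-chain O);
* disulfides (SG-SG pairs, greedy closest matching);
* hydrophobic contacts (apolar side-chain carbon pairs);
* backbone dihedrals with a coarse favored/allowed/outlier label;
* Kabsch superposition CA RMSD.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .core import ProteinStructure, Residue, VarstructError
from .data.chemistry import (ACIDIC_OXYGENS, APOLAR_CARBONS, BASIC_NITROGENS,
                             MAX_ASA, RSA_BURIED_MAX, RSA_PARTIAL_MAX,
                             SIDECHAIN_ACCEPTORS, vdw_radius)
from .geometry import angle as _angle
from .geometry import dihedral, distance, kabsch_superpose, rmsd
from .hydrogens import backbone_amide_h, sidechain_donor_hydrogens

CHAIN_BREAK_CA_CA = 4.5   # A between consecutive CA atoms
HBOND_DA_MAX = 3.9        # A donor-acceptor
HBOND_HA_MAX = 2.5        # A hydrogen-acceptor
HBOND_DHA_MIN = 90.0      # deg donor-H-acceptor
SALT_BRIDGE_MAX = 4.0     # A basic N - acidic O
DISULFIDE_MAX = 2.5       # A SG-SG
HYDROPHOBIC_MAX = 3.9     # A apolar C - apolar C
KS_ENERGY_CUTOFF = -0.5   # kcal/mol
PROBE_RADIUS = 1.4        # A
SASA_POINTS = 960


class HBond(NamedTuple):
    donor_pos: int
    acceptor_pos: int
    donor_atom: str
    acceptor_atom: str
    distance: float
    donor_chain: str = "A"
    acceptor_chain: str = "A"

    @property
    def pair(self) -> frozenset:
        return frozenset([(self.donor_chain, self.donor_pos),
                          (self.acceptor_chain, self.acceptor_pos)])


class SaltBridge(NamedTuple):
    basic_pos: int
    acidic_pos: int
    basic_atom: str
    acidic_atom: str
    distance: float
    basic_chain: str = "A"
    acidic_chain: str = "A"

    @property
    def pair(self) -> frozenset:
        return frozenset([(self.basic_chain, self.basic_pos),
                          (self.acidic_chain, self.acidic_pos)])


class Disulfide(NamedTuple):
    pos1: int
    pos2: int
    distance: float


class HydrophobicContact(NamedTuple):
    pos1: int
    pos2: int
    atom1: str
    atom2: str
    distance: float
    chain1: str = "A"
    chain2: str = "A"

    @property
    def pair(self) -> frozenset:
        return frozenset([(self.chain1, self.pos1), (self.chain2, self.pos2)])


# --------------------------------------------------------------------------
# secondary structure (Kabsch-Sander)
# --------------------------------------------------------------------------

def _segments(residues: list[Residue]) -> list[list[int]]:
    """Indices grouped into covalently continuous stretches."""
    segs: list[list[int]] = []
    cur: list[int] = []
    for idx, res in enumerate(residues):
        if not res.has("N", "CA", "C", "O"):
            if cur:
                segs.append(cur)
            cur = []
            continue
        if cur:
            prev = residues[cur[-1]]
            if (res.number - prev.number != 1 or
                    distance(prev.atom("CA").coords, res.atom("CA").coords)
                    > CHAIN_BREAK_CA_CA):
                segs.append(cur)
                cur = []
        cur.append(idx)
    if cur:
        segs.append(cur)
    return segs


def _ks_hbond_matrix(residues: list[Residue], segs: list[list[int]]) -> np.ndarray:
    """boolean [i, j]: C=O of residue index i bonded to N-H of index j."""
    n = len(residues)
    seg_of = {}
    pos_in_seg = {}
    for s_id, seg in enumerate(segs):
        for k, idx in enumerate(seg):
            seg_of[idx] = s_id
            pos_in_seg[idx] = k
    # amide H per residue (None where absent)
    h_coords: list[np.ndarray | None] = [None] * n
    for seg in segs:
        for k, idx in enumerate(seg):
            prev = residues[seg[k - 1]] if k > 0 else None
            h_coords[idx] = backbone_amide_h(prev, residues[idx])
    bonded = np.zeros((n, n), dtype=bool)
    q = 0.084 * 332.0
    for i in range(n):  # acceptor C=O
        ri = residues[i]
        if i not in seg_of or not ri.has("C", "O"):
            continue
        c, o = ri.atom("C").coords, ri.atom("O").coords
        for j in range(n):  # donor N-H
            if j not in seg_of or abs(i - j) < 2:
                continue
            hj = h_coords[j]
            if hj is None:
                continue
            nj = residues[j].atom("N").coords
            r_on = distance(o, nj)
            if r_on > 5.2:  # energy cannot reach -0.5 beyond this
                continue
            e = q * (1.0 / r_on + 1.0 / distance(c, hj)
                     - 1.0 / distance(o, hj) - 1.0 / distance(c, nj))
            if e < KS_ENERGY_CUTOFF:
                bonded[i, j] = True
    return bonded


def assign_secondary_structure(structure: ProteinStructure) -> dict[int, str]:
    """Per-residue reduced secondary-structure labels {H, G, E, T, C}.

    Helices need two consecutive i->i+4 (or i->i+3 for G) turns; strands
    come from Kabsch-Sander parallel/antiparallel bridge patterns; isolated
    turns give T; everything else is coil.  Chain breaks (missing backbone,
    non-consecutive numbering, CA-CA > 4.5 A) split the assignment windows.
    """
    residues = structure.residues
    n = len(residues)
    segs = _segments(residues)
    bonded = _ks_hbond_matrix(residues, segs)
    seg_of = {}
    for s_id, seg in enumerate(segs):
        for idx in seg:
            seg_of[idx] = s_id

    def same_run(i: int, j: int) -> bool:
        """i..j continuous within one segment."""
        if i < 0 or j >= n or seg_of.get(i) is None or seg_of.get(i) != seg_of.get(j):
            return False
        seg = segs[seg_of[i]]
        return abs(seg.index(j) - seg.index(i)) == j - i

    turn = {m: np.zeros(n, dtype=bool) for m in (3, 4, 5)}
    for m in turn:
        for i in range(n - m):
            if same_run(i, i + m) and bonded[i, i + m]:
                turn[m][i] = True

    labels = np.array(["C"] * n, dtype=object)

    # turns (lowest priority; overwritten below)
    for m in (3, 4, 5):
        for i in np.nonzero(turn[m])[0]:
            for k in range(i + 1, i + m):
                labels[k] = "T"

    # 3-10 helices
    for i in range(1, n):
        if turn[3][i - 1] and turn[3][i]:
            for k in range(i, min(i + 3, n)):
                labels[k] = "G"

    # bridges / strands
    is_e = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 3, n):
            para = bool(
                (i >= 1 and i + 1 < n and bonded[i - 1, j] and bonded[j, i + 1])
                or (j >= 1 and j + 1 < n and bonded[j - 1, i] and bonded[i, j + 1]))
            anti = bool(
                (bonded[i, j] and bonded[j, i])
                or (i >= 1 and i + 1 < n and j >= 1 and j + 1 < n
                    and bonded[i - 1, j + 1] and bonded[j - 1, i + 1]))
            if para or anti:
                is_e[i] = is_e[j] = True
    for i in np.nonzero(is_e)[0]:
        labels[i] = "E"

    # alpha helices (highest priority)
    for i in range(1, n):
        if turn[4][i - 1] and turn[4][i]:
            for k in range(i, min(i + 4, n)):
                labels[k] = "H"

    return {residues[i].number: str(labels[i]) for i in range(n)}


# --------------------------------------------------------------------------
# SASA (Shrake-Rupley)
# --------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * (np.pi * (3.0 - np.sqrt(5.0)))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def compute_sasa(structure: ProteinStructure, probe: float = PROBE_RADIUS,
                 n_points: int = SASA_POINTS
                 ) -> tuple[dict[int, float], list[float]]:
    """Shrake-Rupley solvent-accessible surface area.

    Returns (per-residue SASA in A^2 keyed by position, per-atom SASA in
    input atom order).  Deterministic for a given n_points.
    """
    atoms = [(res.number, at) for res in structure.residues for at in res.atoms]
    if not atoms:
        return {}, []
    coords = np.array([at.coords for _, at in atoms])
    radii = np.empty(len(atoms))
    for i, (_, at) in enumerate(atoms):
        r = vdw_radius(at.element)
        if at.element.upper() not in ("C", "N", "O", "S", "H"):
            warnings.warn(f"atom {at.name}: unknown element {at.element!r}, "
                          f"default radius used")
        radii[i] = r
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * (radii.max() + probe)
    per_atom = np.zeros(len(atoms))
    for i in range(len(atoms)):
        ri = radii[i] + probe
        sphere = coords[i] + ri * pts
        neigh = [j for j in tree.query_ball_point(coords[i], max_reach)
                 if j != i and np.linalg.norm(coords[j] - coords[i])
                 < ri + radii[j] + probe]
        if neigh:
            d = np.linalg.norm(sphere[:, None, :] - coords[neigh][None, :, :],
                               axis=2)
            buried = (d < (radii[neigh] + probe)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = 4.0 * np.pi * ri * ri * frac
    per_res: dict[int, float] = {}
    for (pos, _), a in zip(atoms, per_atom):
        per_res[pos] = per_res.get(pos, 0.0) + float(a)
    return per_res, per_atom.tolist()


def relative_accessibility(sasa: float, aa: str) -> tuple[float, str]:
    """Relative accessibility (percent of Gly-X-Gly maximum) + burial class.

    A value exactly on a class boundary goes to the more exposed class.
    """
    if sasa < 0:
        raise VarstructError("SASA must be >= 0")
    ref = MAX_ASA[aa]
    rsa = min(100.0 * sasa / ref, 200.0)
    if rsa >= RSA_PARTIAL_MAX:
        cls = "exposed"
    elif rsa >= RSA_BURIED_MAX:
        cls = "partially_exposed"
    else:
        cls = "buried"
    return rsa, cls


# --------------------------------------------------------------------------
# interaction detectors
# --------------------------------------------------------------------------

def _all_residues(structure: ProteinStructure,
                  other: ProteinStructure | None) -> list[Residue]:
    res = list(structure.residues)
    if other is not None:
        res = res + list(other.residues)
    return res


def _acceptor_atoms(res: Residue) -> list:
    out = [a for a in res.atoms if a.name in ("O", "OXT")]
    out += [a for a in res.atoms if a.name in SIDECHAIN_ACCEPTORS.get(res.aa, ())]
    return out


def detect_hbonds(structure: ProteinStructure,
                  other: ProteinStructure | None = None,
                  da_max: float = HBOND_DA_MAX, ha_max: float = HBOND_HA_MAX,
                  dha_min: float = HBOND_DHA_MIN) -> list[HBond]:
    """Geometric H-bonds after idealized polar-hydrogen placement.

    Criteria: donor-acceptor <= 3.9 A, hydrogen-acceptor <= 2.5 A and
    donor-H-acceptor angle >= 90 deg.  Same-residue and covalently adjacent
    backbone pairs are excluded.  With `other` given, only cross-chain
    bonds between the two structures are reported.
    """
    residues = _all_residues(structure, other)
    cross_only = other is not None

    acceptors = []  # (res, atom)
    for r in residues:
        for a in _acceptor_atoms(r):
            acceptors.append((r, a))
    acc_coords = np.array([a.coords for _, a in acceptors]).reshape(-1, 3)

    donors = []  # (res, donor_atom_name, donor_coords, h_coords)
    for seg in _segments(residues):
        for k, idx in enumerate(seg):
            res = residues[idx]
            prev = residues[seg[k - 1]] if k > 0 else None
            h = backbone_amide_h(prev, res)
            if h is not None:
                donors.append((res, "N", res.atom("N").coords, h))
    for r in residues:
        if r.aa not in ("S", "T", "Y", "K"):
            cand = acc_coords
        else:  # orient rotatables toward acceptors outside the residue
            mask = [ar is not r for ar, _ in acceptors]
            cand = acc_coords[np.array(mask, dtype=bool)] if acceptors else acc_coords
        for name, d, h in sidechain_donor_hydrogens(r, cand):
            donors.append((r, name, d, h))

    out: list[HBond] = []
    for dres, dname, dpos, hpos in donors:
        for ares, aatom in acceptors:
            if ares is dres:
                continue
            if cross_only and ares.chain == dres.chain:
                continue
            if dname == "N" and aatom.name in ("O", "OXT") and \
                    ares.chain == dres.chain and dres.number - ares.number == 1:
                continue  # 1-3 bonded backbone pair
            da = distance(dpos, aatom.coords)
            if da > da_max:
                continue
            if distance(hpos, aatom.coords) > ha_max:
                continue
            if _angle(dpos, hpos, aatom.coords) < dha_min:
                continue
            out.append(HBond(dres.number, ares.number, dname, aatom.name,
                             round(da, 3), dres.chain, ares.chain))
    # one bond per (donor atom, acceptor atom) pair: keep the closest H variant
    best: dict[tuple, HBond] = {}
    for hb in out:
        key = (hb.donor_chain, hb.donor_pos, hb.donor_atom,
               hb.acceptor_chain, hb.acceptor_pos, hb.acceptor_atom)
        if key not in best or hb.distance < best[key].distance:
            best[key] = hb
    return sorted(best.values())


def detect_salt_bridges(structure: ProteinStructure,
                        other: ProteinStructure | None = None,
                        cutoff: float = SALT_BRIDGE_MAX) -> list[SaltBridge]:
    """Basic side-chain N within `cutoff` of acidic side-chain O.

    Histidine counts as basic.  One bridge per residue pair, at the
    minimum-distance atom pair.
    """
    residues = _all_residues(structure, other)
    cross_only = other is not None
    basics, acidics = [], []
    for r in residues:
        for name in BASIC_NITROGENS.get(r.aa, ()):
            a = r.atom(name)
            if a is not None:
                basics.append((r, a))
        for name in ACIDIC_OXYGENS.get(r.aa, ()):
            a = r.atom(name)
            if a is not None:
                acidics.append((r, a))
    best: dict[tuple, SaltBridge] = {}
    for br, ba in basics:
        for ar, aa_ in acidics:
            if cross_only and br.chain == ar.chain:
                continue
            d = distance(ba.coords, aa_.coords)
            if d <= cutoff:
                key = (br.chain, br.number, ar.chain, ar.number)
                sb = SaltBridge(br.number, ar.number, ba.name, aa_.name,
                                round(d, 3), br.chain, ar.chain)
                if key not in best or sb.distance < best[key].distance:
                    best[key] = sb
    return sorted(best.values())


def detect_disulfides(structure: ProteinStructure,
                      cutoff: float = DISULFIDE_MAX) -> list[Disulfide]:
    """Cys SG-SG pairs within cutoff; greedy closest-first matching so each
    cysteine joins at most one bond."""
    cys = []
    for r in structure.residues:
        if r.aa != "C":
            continue
        sg = r.atom("SG")
        if sg is None:
            warnings.warn(f"Cys{r.number}: missing SG, skipped")
            continue
        cys.append((r.number, sg.coords))
    candidates = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = distance(cys[i][1], cys[j][1])
            if d <= cutoff:
                candidates.append((d, cys[i][0], cys[j][0]))
    used: set[int] = set()
    out: list[Disulfide] = []
    for d, p1, p2 in sorted(candidates):
        if p1 in used or p2 in used:
            continue
        used.update((p1, p2))
        out.append(Disulfide(min(p1, p2), max(p1, p2), round(d, 3)))
    return sorted(out)


def detect_hydrophobic_contacts(structure: ProteinStructure,
                                other: ProteinStructure | None = None,
                                cutoff: float = HYDROPHOBIC_MAX
                                ) -> list[HydrophobicContact]:
    """Apolar side-chain carbon pairs of distinct residues within cutoff."""
    residues = _all_residues(structure, other)
    cross_only = other is not None
    groups = []
    for r in residues:
        atoms = [r.atom(n) for n in APOLAR_CARBONS.get(r.aa, ())]
        atoms = [a for a in atoms if a is not None]
        if atoms:
            groups.append((r, atoms))
    best: dict[tuple, HydrophobicContact] = {}
    for i in range(len(groups)):
        ri, ai = groups[i]
        for j in range(i + 1, len(groups)):
            rj, aj = groups[j]
            if cross_only and ri.chain == rj.chain:
                continue
            for a in ai:
                for b in aj:
                    d = distance(a.coords, b.coords)
                    if d <= cutoff:
                        key = (ri.chain, ri.number, rj.chain, rj.number)
                        c = HydrophobicContact(ri.number, rj.number, a.name,
                                               b.name, round(d, 3),
                                               ri.chain, rj.chain)
                        if key not in best or c.distance < best[key].distance:
                            best[key] = c
    return sorted(best.values())


# --------------------------------------------------------------------------
# superposition and dihedrals
# --------------------------------------------------------------------------

def superpose_rmsd(a: ProteinStructure, b: ProteinStructure,
                   selection: tuple[int, int] | list[int] | None = None) -> float:
    """CA RMSD after optimal (Kabsch) superposition.

    `selection` is an inclusive (start, end) precursor range or an explicit
    position list; default is all positions shared by both structures.
    """
    if selection is None:
        pos = sorted(set(a.positions) & set(b.positions))
    elif isinstance(selection, tuple):
        pos = [p for p in range(selection[0], selection[1] + 1)
               if a.has_position(p) and b.has_position(p)]
    else:
        pos = list(selection)
    pa, pb = [], []
    for p in pos:
        ca_a = a.residue_at(p).atom("CA")
        ca_b = b.residue_at(p).atom("CA")
        if ca_a is None or ca_b is None:
            raise VarstructError(f"position {p}: missing CA for superposition")
        pa.append(ca_a.coords)
        pb.append(ca_b.coords)
    if len(pa) != len(pb) or len(pa) < 3:
        raise VarstructError("selection must give >= 3 matched CA atoms")
    _, _, moved = kabsch_superpose(np.array(pa), np.array(pb))
    return rmsd(moved, np.array(pb))


# documented coarse phi/psi rectangles (degrees)
_FAVORED_BOXES = [(-140.0, -35.0, -70.0, 5.0),     # right-handed helix
                  (-180.0, -45.0, 90.0, 180.0)]    # beta strand
_ALLOWED_BOXES = [(-180.0, -20.0, -120.0, 45.0),
                  (-180.0, -20.0, 45.0, 180.0),
                  (-180.0, -20.0, -180.0, -120.0),
                  (20.0, 110.0, -45.0, 90.0)]      # left-handed helix


def _phi_psi_label(phi: float | None, psi: float | None, aa: str) -> str | None:
    if phi is None or psi is None:
        return None
    for lo, hi, plo, phi_ in _FAVORED_BOXES:
        if lo <= phi <= hi and plo <= psi <= phi_:
            return "favored"
    for lo, hi, plo, phi_ in _ALLOWED_BOXES:
        if lo <= phi <= hi and plo <= psi <= phi_:
            return "allowed"
    if aa == "G":
        return "allowed"
    return "outlier"


def compute_phi_psi(structure: ProteinStructure
                    ) -> dict[int, tuple[float | None, float | None, str | None]]:
    """Backbone (phi, psi) in degrees plus a coarse region label.

    Angles undefined at termini and across chain breaks are None with a
    None label.
    """
    residues = structure.residues
    out: dict[int, tuple[float | None, float | None, str | None]] = {}
    for seg in _segments(residues):
        for k, idx in enumerate(seg):
            res = residues[idx]
            phi = psi = None
            if k > 0:
                prev = residues[seg[k - 1]]
                phi = dihedral(prev.atom("C").coords, res.atom("N").coords,
                               res.atom("CA").coords, res.atom("C").coords)
            if k < len(seg) - 1:
                nxt = residues[seg[k + 1]]
                psi = dihedral(res.atom("N").coords, res.atom("CA").coords,
                               res.atom("C").coords, nxt.atom("N").coords)
            out[res.number] = (phi, psi, _phi_psi_label(phi, psi, res.aa))
    for res in residues:  # residues with broken backbone
        out.setdefault(res.number, (None, None, None))
    return out


# --------------------------------------------------------------------------
# profile assembly
# --------------------------------------------------------------------------

@dataclass
class StructuralProfile:
    """Per-residue structural profile of one model plus structure-level
    disulfides."""

    positions: list[int]
    aa: dict[int, str]
    ss: dict[int, str]
    sasa: dict[int, float]
    rsa: dict[int, float]
    burial_class: dict[int, str]
    hbonds: list[HBond]
    salt_bridges: list[SaltBridge]
    hydrophobic_contacts: list[HydrophobicContact]
    disulfides: list[Disulfide]
    phi_psi: dict[int, tuple] = field(default_factory=dict)

    def partners(self, kind: str, position: int) -> set[int]:
        """Interaction partner positions of one residue."""
        items = {"hbond": self.hbonds, "salt_bridge": self.salt_bridges,
                 "hydrophobic": self.hydrophobic_contacts}[kind]
        out: set[int] = set()
        for it in items:
            pair = [p for _, p in it.pair]
            if position in pair:
                out.update(p for p in pair if p != position)
        return out

    def to_rows(self) -> list[dict]:
        rows = []
        for p in self.positions:
            rows.append({
                "position": p,
                "aa": self.aa[p],
                "ss": self.ss[p],
                "sasa": round(self.sasa[p], 2),
                "rsa": round(self.rsa[p], 2),
                "burial_class": self.burial_class[p],
                "hbond_partners": ";".join(map(str, sorted(self.partners("hbond", p)))),
                "salt_bridge_partners": ";".join(
                    map(str, sorted(self.partners("salt_bridge", p)))),
                "hydrophobic_partners": ";".join(
                    map(str, sorted(self.partners("hydrophobic", p)))),
            })
        return rows

    def to_tsv(self, path: str) -> None:
        import pandas as pd
        pd.DataFrame(self.to_rows()).to_csv(path, sep="\t", index=False)

    def to_json(self, path: str) -> None:
        payload = {
            "residues": self.to_rows(),
            "disulfides": [d._asdict() for d in self.disulfides],
            "hbonds": [h._asdict() for h in self.hbonds],
            "salt_bridges": [s._asdict() for s in self.salt_bridges],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def build_profile(structure: ProteinStructure, probe: float = PROBE_RADIUS,
                  n_points: int = SASA_POINTS) -> StructuralProfile:
    """Compute the full per-residue profile of one model."""
    ss = assign_secondary_structure(structure)
    per_res_sasa, _ = compute_sasa(structure, probe=probe, n_points=n_points)
    rsa, burial = {}, {}
    for r in structure.residues:
        rsa[r.number], burial[r.number] = relative_accessibility(
            per_res_sasa.get(r.number, 0.0), r.aa)
    return StructuralProfile(
        positions=structure.positions,
        aa={r.number: r.aa for r in structure.residues},
        ss=ss,
        sasa=per_res_sasa,
        rsa=rsa,
        burial_class=burial,
        hbonds=detect_hbonds(structure),
        salt_bridges=detect_salt_bridges(structure),
        hydrophobic_contacts=detect_hydrophobic_contacts(structure),
        disulfides=detect_disulfides(structure),
        phi_psi=compute_phi_psi(structure),
    )
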