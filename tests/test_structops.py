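"""Geometry operators: secondary structure, SASA, interactions, dihedrals."""

import numpy as np
import pytest

import varstruct as vs
from varstruct.core import Atom, ProteinStructure, Residue, VarstructError
from varstruct.fixtures import FixtureSpec, build_chain, make_structure
from varstruct.geometry import dihedral, distance
from varstruct.structops import (HBOND_DA_MAX, HBOND_DHA_MIN, HBOND_HA_MAX,
                                 relative_accessibility)

from conftest import (oracle_disulfides, oracle_hbonds, oracle_hydrophobic,
                      oracle_salt_bridges)


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def test_ideal_helix_labels(ideal_helix):
    s, truth = ideal_helix
    ss = vs.assign_secondary_structure(s)
    labels = "".join(ss[p] for p in s.positions)
    assert set(labels[1:-1]) == {"H"}
    assert labels[0] == "C" and labels[-1] == "C"


def test_beta_hairpin_labels(beta_hairpin):
    s, truth = beta_hairpin
    ss = vs.assign_secondary_structure(s)
    for p in truth["strand1"] + truth["strand2"]:
        assert ss[p] == "E", f"position {p}"
    for p in truth["turn"]:
        assert ss[p] == "T"


def test_ss_agreement_with_external_dssp(tmp_path, ideal_helix, beta_hairpin):
    """Reduced-alphabet agreement with an independent DSSP implementation."""
    md = pytest.importorskip("mdtraj")
    reduce = {"H": "H", "G": "G", "I": "H", "E": "E", "B": "E",
              "T": "T", "S": "C", " ": "C", "C": "C"}
    for name, (s, _) in (("helix", ideal_helix), ("hairpin", beta_hairpin)):
        path = tmp_path / f"{name}.pdb"
        vs.write_pdb(s, str(path))
        ext = [reduce[c] for c in
               md.compute_dssp(md.load(str(path)), simplified=False)[0]]
        ours = vs.assign_secondary_structure(s)
        mine = [ours[p] for p in s.positions]
        assert mine == ext


def test_ss_covers_every_residue(random_coil_30):
    ss = vs.assign_secondary_structure(random_coil_30)
    assert sorted(ss) == random_coil_30.positions
    assert all(lab in "HGETC" for lab in ss.values())


def test_short_chain_is_coil():
    s = build_chain("AAA", [(-57.0, -47.0)] * 3)
    assert set(vs.assign_secondary_structure(s).values()) == {"C"}


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def _atom_structure(*coords):
    residues = [Residue(i + 1, "G", [Atom("CA", "C", np.array(c))])
                for i, c in enumerate(coords)]
    return ProteinStructure(residues=residues)


def test_sasa_isolated_sphere():
    s = _atom_structure([0.0, 0.0, 0.0])
    _, per_atom = vs.compute_sasa(s)
    analytic = 4.0 * np.pi * (1.87 + 1.4) ** 2
    assert per_atom[0] == pytest.approx(analytic, rel=1e-6)


def test_sasa_two_sphere_closed_form():
    R = 1.87 + 1.4
    d = 3.0
    s = _atom_structure([0.0, 0.0, 0.0], [d, 0.0, 0.0])
    _, per_atom = vs.compute_sasa(s)
    h = R - d / 2.0
    analytic = 2.0 * (4.0 * np.pi * R * R - 2.0 * np.pi * R * h)
    assert sum(per_atom) == pytest.approx(analytic, rel=0.01)


def test_sasa_convergence_on_density_doubling(random_coil_30):
    res1, _ = vs.compute_sasa(random_coil_30, n_points=960)
    res2, _ = vs.compute_sasa(random_coil_30, n_points=1920)
    t1, t2 = sum(res1.values()), sum(res2.values())
    assert abs(t2 - t1) / t1 < 0.005


def test_sasa_per_residue_sums_to_total(random_coil_30):
    per_res, per_atom = vs.compute_sasa(random_coil_30, n_points=240)
    assert sum(per_res.values()) == pytest.approx(sum(per_atom), abs=1e-9)


def test_rsa_and_burial_classes():
    assert relative_accessibility(0.0, "W") == (0.0, "buried")
    ref = 285.0  # Trp reference maximum
    rsa, cls = relative_accessibility(0.2 * ref, "W")
    assert rsa == pytest.approx(20.0) and cls == "partially_exposed"
    rsa, cls = relative_accessibility(0.5 * ref, "W")
    assert rsa == pytest.approx(50.0) and cls == "exposed"
    rsa, cls = relative_accessibility(0.19 * ref, "W")
    assert cls == "buried"


# ---------------------------------------------------------------------------
# interaction detectors vs brute-force oracles
# ---------------------------------------------------------------------------

def test_helix_backbone_hbond_count(ideal_helix):
    s, truth = ideal_helix
    hb = [h for h in vs.detect_hbonds(s) if h.donor_atom == "N"
          and h.acceptor_atom == "O"]
    assert len(hb) == truth["expected_backbone_hbonds"]
    assert all(h.donor_pos - h.acceptor_pos == 4 for h in hb)


def test_distant_residues_no_hbonds():
    s = build_chain("GG", [(-57.0, -47.0)] * 2)
    far = build_chain("GG", [(-57.0, -47.0)] * 2, start_number=10)
    for r in far.residues:
        for a in r.atoms:
            a.coords = a.coords + np.array([15.0, 0.0, 0.0])
    combined = ProteinStructure(residues=[r.copy() for r in s.residues]
                                + [r.copy() for r in far.residues])
    assert [h for h in vs.detect_hbonds(combined)
            if abs(h.donor_pos - h.acceptor_pos) > 2] == []


@pytest.mark.parametrize("seed", range(6))
def test_hbond_detector_matches_bruteforce(seed):
    s, _ = make_structure(FixtureSpec("random_coil", length=12, seed=seed))
    mine = {(h.donor_pos, h.acceptor_pos, h.donor_atom, h.acceptor_atom)
            for h in vs.detect_hbonds(s)}
    assert mine == oracle_hbonds(s)


@pytest.mark.parametrize("seed", range(6))
def test_salt_bridge_detector_matches_bruteforce(seed):
    s, _ = make_structure(FixtureSpec(
        "random_coil", length=12, seed=100 + seed,
        parameters={"alphabet": "KRDEHG"}))
    mine = {frozenset((b.basic_pos, b.acidic_pos))
            for b in vs.detect_salt_bridges(s)}
    assert mine == oracle_salt_bridges(s)


def test_salt_bridge_distance_examples():
    s, truth = make_structure(FixtureSpec("salt_bridge_pair",
                                          parameters={"distance": 3.5}))
    bridges = vs.detect_salt_bridges(s)
    assert [[b.basic_pos, b.acidic_pos] for b in bridges] == truth["expected_bridges"]
    s, truth = make_structure(FixtureSpec("salt_bridge_pair",
                                          parameters={"distance": 4.5}))
    assert vs.detect_salt_bridges(s) == []


def test_disulfide_greedy_matching():
    """Three cysteines at SG distances 2.0/2.1/8.0: only the closest pair
    bonds, matching exhaustive matching enumeration."""
    def cys(number, sg_xyz):
        return Residue(number, "C", [
            Atom("N", "N", [0.0, 3.0 + number, 0.0]),
            Atom("CA", "C", [1.0, 3.0 + number, 0.0]),
            Atom("C", "C", [2.0, 3.0 + number, 0.0]),
            Atom("O", "O", [2.5, 4.0 + number, 0.0]),
            Atom("CB", "C", [1.0, 2.0 + number, 0.0]),
            Atom("SG", "S", sg_xyz)])
    s = ProteinStructure(residues=[
        cys(1, [0.0, 0.0, 0.0]), cys(2, [2.0, 0.0, 0.0]),
        cys(3, [2.0, 2.1, 0.0])])
    out = vs.detect_disulfides(s)
    assert [(d.pos1, d.pos2) for d in out] == [(1, 2)]
    assert {frozenset((d.pos1, d.pos2)) for d in out} == oracle_disulfides(s)


def test_no_cysteines_no_disulfides(ideal_helix):
    s, _ = ideal_helix
    assert vs.detect_disulfides(s) == []


def test_hydrophobic_contacts_examples():
    s, _ = make_structure(FixtureSpec("random_coil", length=12, seed=42,
                                      parameters={"alphabet": "LIVFG"}))
    mine = {frozenset((c.pos1, c.pos2))
            for c in vs.detect_hydrophobic_contacts(s)}
    assert mine == oracle_hydrophobic(s)


def test_all_glycine_no_hydrophobic_contacts():
    s = build_chain("GGGGGG", [(-57.0, -47.0)] * 6)
    assert vs.detect_hydrophobic_contacts(s) == []


def test_reported_interactions_satisfy_thresholds(random_coil_30):
    """Self-audit: every reported interaction re-checks against its own
    geometric criterion."""
    s = random_coil_30
    for b in vs.detect_salt_bridges(s):
        a1 = s.residue_at(b.basic_pos).atom(b.basic_atom)
        a2 = s.residue_at(b.acidic_pos).atom(b.acidic_atom)
        assert distance(a1.coords, a2.coords) <= 4.0 + 1e-6
    for h in vs.detect_hbonds(s):
        a1 = s.residue_at(h.donor_pos).atom(h.donor_atom)
        a2 = s.residue_at(h.acceptor_pos).atom(h.acceptor_atom)
        assert distance(a1.coords, a2.coords) <= HBOND_DA_MAX + 1e-6
    for c in vs.detect_hydrophobic_contacts(s):
        a1 = s.residue_at(c.pos1).atom(c.atom1)
        a2 = s.residue_at(c.pos2).atom(c.atom2)
        assert distance(a1.coords, a2.coords) <= 3.9 + 1e-6


# ---------------------------------------------------------------------------
# superposition and dihedrals
# ---------------------------------------------------------------------------

def test_rmsd_self_and_rigid_motion(ideal_helix):
    s, _ = ideal_helix
    assert vs.superpose_rmsd(s, s) == pytest.approx(0.0, abs=1e-9)
    rot = s.copy()
    theta = np.radians(33.0)
    R = np.array([[np.cos(theta), -np.sin(theta), 0.0],
                  [np.sin(theta), np.cos(theta), 0.0],
                  [0.0, 0.0, 1.0]])
    for r in rot.residues:
        for a in r.atoms:
            a.coords = R @ a.coords + np.array([5.0, -2.0, 7.0])
    assert vs.superpose_rmsd(s, rot) == pytest.approx(0.0, abs=1e-6)


def test_rmsd_symmetry_and_bound(ideal_helix):
    s, _ = ideal_helix
    pert = s.copy()
    ca = pert.residue_at(8).atom("CA")
    ca.coords = ca.coords + np.array([1.0, 0.0, 0.0])
    fwd = vs.superpose_rmsd(s, pert)
    assert fwd == pytest.approx(vs.superpose_rmsd(pert, s), abs=1e-9)
    n = len(s)
    assert 0.0 < fwd <= 1.0 / np.sqrt(n) + 1e-9


def test_rmsd_mismatched_selection_errors(ideal_helix):
    s, _ = ideal_helix
    with pytest.raises(VarstructError):
        vs.superpose_rmsd(s, s, selection=[1, 2])  # < 3 CA atoms


def test_phi_psi_ideal_helix(ideal_helix):
    s, _ = ideal_helix
    pp = vs.compute_phi_psi(s)
    phi, psi, label = pp[8]
    assert phi == pytest.approx(-57.0, abs=1.0)
    assert psi == pytest.approx(-47.0, abs=1.0)
    assert label == "favored"
    assert pp[1][0] is None and pp[1][2] is None        # phi undefined
    assert pp[s.positions[-1]][1] is None               # psi undefined


def test_phi_psi_matches_direct_dihedral(random_coil_30):
    s = random_coil_30
    pp = vs.compute_phi_psi(s)
    r4, r5, r6 = (s.residue_at(p) for p in (4, 5, 6))
    phi = dihedral(r4.atom("C").coords, r5.atom("N").coords,
                   r5.atom("CA").coords, r5.atom("C").coords)
    psi = dihedral(r5.atom("N").coords, r5.atom("CA").coords,
                   r5.atom("C").coords, r6.atom("N").coords)
    assert pp[5][0] == pytest.approx(phi, abs=1e-9)
    assert pp[5][1] == pytest.approx(psi, abs=1e-9)
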