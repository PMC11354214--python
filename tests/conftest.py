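import warnings

import numpy as np
import pytest

from varstruct.fixtures import FixtureSpec, make_structure

warnings.filterwarnings("ignore", message="expected 3 beta-strands")


@pytest.fixture(scope="session")
def ideal_helix():
    s, truth = make_structure(FixtureSpec("ideal_helix", length=15))
    return s, truth


@pytest.fixture(scope="session")
def beta_hairpin():
    s, truth = make_structure(FixtureSpec("beta_hairpin"))
    return s, truth


@pytest.fixture(scope="session")
def random_coil_30():
    s, truth = make_structure(FixtureSpec("random_coil", length=30, seed=11))
    return s


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain nested loops, no shared detector
# code beyond the published geometric thresholds and the hydrogen builder)
# ---------------------------------------------------------------------------

def oracle_salt_bridges(structure, cutoff=4.0):
    basic = {"K": ("NZ",), "R": ("NE", "NH1", "NH2"), "H": ("ND1", "NE2")}
    acidic = {"D": ("OD1", "OD2"), "E": ("OE1", "OE2")}
    pairs = set()
    res = structure.residues
    for i in range(len(res)):
        for j in range(len(res)):
            if i == j:
                continue
            for an in basic.get(res[i].aa, ()):
                a = res[i].atom(an)
                if a is None:
                    continue
                for bn in acidic.get(res[j].aa, ()):
                    b = res[j].atom(bn)
                    if b is None:
                        continue
                    if np.linalg.norm(a.coords - b.coords) <= cutoff:
                        pairs.add(frozenset((res[i].number, res[j].number)))
    return pairs


def oracle_disulfides(structure, cutoff=2.5):
    """All SG-SG candidate pairs; optimal matching by exhaustive enumeration
    over all pairings (structures are small)."""
    import itertools
    sgs = [(r.number, r.atom("SG").coords) for r in structure.residues
           if r.aa == "C" and r.atom("SG") is not None]
    cands = []
    for (p1, c1), (p2, c2) in itertools.combinations(sgs, 2):
        d = float(np.linalg.norm(c1 - c2))
        if d <= cutoff:
            cands.append((d, p1, p2))
    # greedy closest-first matching, re-derived independently
    chosen, used = set(), set()
    for d, p1, p2 in sorted(cands):
        if p1 not in used and p2 not in used:
            used.update((p1, p2))
            chosen.add(frozenset((p1, p2)))
    return chosen


def oracle_hydrophobic(structure, cutoff=3.9):
    from varstruct.data.chemistry import APOLAR_CARBONS
    pairs = set()
    res = structure.residues
    for i in range(len(res)):
        for j in range(i + 1, len(res)):
            for an in APOLAR_CARBONS.get(res[i].aa, ()):
                a = res[i].atom(an)
                if a is None:
                    continue
                for bn in APOLAR_CARBONS.get(res[j].aa, ()):
                    b = res[j].atom(bn)
                    if b is None:
                        continue
                    if np.linalg.norm(a.coords - b.coords) <= cutoff:
                        pairs.add(frozenset((res[i].number, res[j].number)))
    return pairs


def oracle_hbonds(structure, da_max=3.9, ha_max=2.5, dha_min=90.0):
    """Exhaustive donor/acceptor scan re-applying the geometric criteria.

    Hydrogen positions come from the same idealized builder the package
    uses (they are part of the model definition); the scan, pair exclusion
    and criterion checks are re-implemented here from scratch.
    """
    from varstruct.data.chemistry import SIDECHAIN_ACCEPTORS
    from varstruct.hydrogens import backbone_amide_h, sidechain_donor_hydrogens
    res = structure.residues
    acceptors = []
    for r in res:
        for at in r.atoms:
            if at.name in ("O", "OXT") or \
                    at.name in SIDECHAIN_ACCEPTORS.get(r.aa, ()):
                acceptors.append((r, at))
    donors = []
    for k, r in enumerate(res):
        prev = res[k - 1] if k > 0 and res[k - 1].number == r.number - 1 else None
        if prev is not None:
            ca_p, ca_r = prev.atom("CA"), r.atom("CA")
            if ca_p is None or ca_r is None or \
                    np.linalg.norm(ca_p.coords - ca_r.coords) > 4.5:
                prev = None
        h = backbone_amide_h(prev, r)
        if h is not None:
            donors.append((r, "N", r.atom("N").coords, h))
        ext = np.array([a.coords for rr, a in acceptors if rr is not r])
        donors.extend((r, n, d, hh) for n, d, hh in
                      sidechain_donor_hydrogens(r, ext.reshape(-1, 3)))
    found = set()
    for dres, dname, dpos, hpos in donors:
        for ares, aat in acceptors:
            if ares is dres:
                continue
            if dname == "N" and aat.name in ("O", "OXT") and \
                    dres.number - ares.number == 1:
                continue
            da = np.linalg.norm(dpos - aat.coords)
            ha = np.linalg.norm(hpos - aat.coords)
            v1 = dpos - hpos
            v2 = aat.coords - hpos
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if da <= da_max and ha <= ha_max and ang >= dha_min:
                found.add((dres.number, ares.number, dname, aat.name))
    return found
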