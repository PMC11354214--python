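"""Consensus stability calls, profile diffs, interface mapping."""

import itertools

import pytest

import varstruct as vs
from varstruct.compare import (LESS_STABLE, MORE_STABLE, UNCERTAIN,
                               consensus_stability, diff_profiles,
                               interface_contacts, map_interface_positions)
from varstruct.core import VariantSpec, VarstructError
from varstruct.fixtures import (FixtureSpec, make_charge_reversal_site,
                                make_cys_scaffold, make_structure)
from varstruct.structops import build_profile

METHODS = ("m1", "m2", "m3", "m4", "m5")
CUTOFFS = {m: 0.5 for m in METHODS}


def _call(values):
    return consensus_stability(dict(zip(METHODS, values)), CUTOFFS).call


@pytest.mark.parametrize("values,expected", [
    ((-1.2, -0.8, -1.5, 0.1, -0.05), LESS_STABLE),   # 3 significant 'less'
    ((-1.0, -1.0, 1.0, 1.0, 0.0), UNCERTAIN),        # 2 vs 2 split
    ((0.1, -0.2, 0.3, 0.0, 0.4), UNCERTAIN),         # all abstain
    ((0.8, 0.9, 2.0, 0.6, -3.0), MORE_STABLE),       # 4 'more', 1 'less'
    ((-0.5, -0.5, -0.5, 0.49, 0.0), LESS_STABLE),    # cutoff is inclusive
])
def test_consensus_worked_examples(values, expected):
    assert _call(values) == expected


def test_consensus_truth_table_exhaustive():
    """All 3^5 sign/abstain vote patterns resolve exactly as an
    independently evaluated 3-of-5 majority rule."""
    rep = {"less": -1.0, "more": 1.0, "abstain": 0.0}
    for pattern in itertools.product(("less", "more", "abstain"), repeat=5):
        call = _call([rep[p] for p in pattern])
        n_less = pattern.count("less")
        n_more = pattern.count("more")
        expected = (LESS_STABLE if n_less >= 3
                    else MORE_STABLE if n_more >= 3 else UNCERTAIN)
        assert call == expected, pattern


def test_consensus_permutation_invariance():
    values = (-1.2, 0.8, -0.6, 0.2, -2.0)
    calls = {_call(p) for p in itertools.permutations(values)}
    assert len(calls) == 1


def test_missing_value_abstains():
    sc = consensus_stability(
        dict(zip(METHODS, (-1.0, -1.0, -1.0, None, None))), CUTOFFS)
    assert sc.call == LESS_STABLE
    assert sorted(sc.missing) == ["m4", "m5"]
    assert sc.votes_less == 3 and sc.votes_more == 0


def test_diff_identity_is_empty(ideal_helix):
    s, _ = ideal_helix
    prof = build_profile(s, n_points=240)
    rep = diff_profiles(prof, prof, VariantSpec(8, "A", "V"))
    assert not rep.any_structural_change
    assert rep.delta_rsa == 0.0


def test_diff_antisymmetry():
    s, truth = make_charge_reversal_site()
    mut, _ = vs.build_mutant(s, VariantSpec(78, "K", "E"))
    wt_prof = build_profile(s, n_points=240)
    mut_prof = build_profile(mut, n_points=240)
    fwd = diff_profiles(wt_prof, mut_prof, VariantSpec(78, "K", "E"))
    rev = diff_profiles(mut_prof, wt_prof, VariantSpec(78, "E", "K"))
    assert fwd.hbonds_gained == rev.hbonds_lost
    assert fwd.salt_bridges_gained == rev.salt_bridges_lost
    assert fwd.hydrophobic_gained == rev.hydrophobic_lost


def test_charge_reversal_gains_salt_bridge_with_histidine():
    """A Lys->Glu charge reversal next to a histidine creates a new salt
    bridge that the wild type lacks."""
    s, truth = make_charge_reversal_site()
    mut, _ = vs.build_mutant(s, VariantSpec(78, "K", "E"))
    wt_prof = build_profile(s, n_points=240)
    mut_prof = build_profile(mut, n_points=240)
    rep = diff_profiles(wt_prof, mut_prof, VariantSpec(78, "K", "E"))
    assert tuple(truth["expected_gain"]) in {tuple(p)
                                             for p in rep.salt_bridges_gained}
    assert rep.any_structural_change


def test_cys_substitution_loses_disulfide():
    s, truth = make_cys_scaffold()
    mut, _ = vs.build_mutant(s, VariantSpec(34, "C", "S"))
    rep = diff_profiles(build_profile(s, n_points=240),
                        build_profile(mut, n_points=240),
                        VariantSpec(34, "C", "S"))
    assert rep.disulfide_lost
    assert not rep.cys_introduced


def test_cys_introduction_flagged(random_coil_30):
    s = random_coil_30
    pos = 8
    wt = s.residue_at(pos).aa
    if wt == "C":
        pytest.skip("fixture already Cys here")
    mut, _ = vs.build_mutant(s, VariantSpec(pos, wt, "C"))
    rep = diff_profiles(build_profile(s, n_points=120),
                        build_profile(mut, n_points=120),
                        VariantSpec(pos, wt, "C"))
    assert rep.cys_introduced


def test_diff_numbering_mismatch_errors(ideal_helix, random_coil_30):
    s, _ = ideal_helix
    with pytest.raises(VarstructError):
        diff_profiles(build_profile(s, n_points=120),
                      build_profile(random_coil_30, n_points=120),
                      VariantSpec(2, "A", "V"))


def test_any_structural_change_self_consistency():
    s, _ = make_cys_scaffold()
    mut, _ = vs.build_mutant(s, VariantSpec(34, "C", "S"))
    rep = diff_profiles(build_profile(s, n_points=120),
                        build_profile(mut, n_points=120),
                        VariantSpec(34, "C", "S"))
    rederived = bool(rep.ss_changed or rep.burial_changed or rep.hbonds_gained
                     or rep.hbonds_lost or rep.salt_bridges_gained
                     or rep.salt_bridges_lost or rep.disulfide_lost
                     or rep.cys_introduced)
    assert rep.any_structural_change == rederived


# ---------------------------------------------------------------------------
# interface mapping
# ---------------------------------------------------------------------------

def test_interface_salt_bridge_detected():
    a, truth = make_structure(FixtureSpec("two_chain_complex"))
    b = truth["chain_b"]
    contacts = interface_contacts(a, b)
    assert (truth["expected_salt_bridge"][0], truth["expected_salt_bridge"][1],
            "salt_bridge") in contacts


def test_distant_chains_no_interface():
    import numpy as np
    a, truth = make_structure(FixtureSpec("two_chain_complex"))
    b = truth["chain_b"]
    for r in b.residues:
        for at in r.atoms:
            at.coords = at.coords + np.array([50.0, 0.0, 0.0])
    assert interface_contacts(a, b) == []


def test_single_chain_interface_errors():
    a, _ = make_structure(FixtureSpec("ideal_helix", length=8))
    with pytest.raises(VarstructError):
        interface_contacts(a, a)


def test_map_interface_positions(tmp_path):
    # ligand position 2 aligns to reference position 29 via an N-terminal gap
    path = tmp_path / "aln.fasta"
    path.write_text(">ligand\n" + "-" * 27 + "SN\n"
                    ">reference\n" + "A" * 27 + "IS\n")
    aln = vs.read_alignment(str(path))
    flagged, dropped = map_interface_positions(
        [(1, 50, "hbond"), (2, 51, "hbond")], aln, "ligand", "reference")
    assert flagged == [28, 29]
    assert dropped == 0


def test_map_interface_drops_gapped_columns(tmp_path):
    path = tmp_path / "aln.fasta"
    path.write_text(">ligand\nSNK\n>reference\nS-K\n")
    aln = vs.read_alignment(str(path))
    flagged, dropped = map_interface_positions(
        [(1, 9, "hbond"), (2, 9, "hbond"), (3, 9, "salt_bridge")],
        aln, "ligand", "reference")
    assert flagged == [1, 2]
    assert dropped == 1


def test_map_interface_identity_passthrough(tmp_path):
    path = tmp_path / "aln.fasta"
    path.write_text(">ligand\nMKWV\n>reference\nMKWV\n")
    aln = vs.read_alignment(str(path))
    flagged, dropped = map_interface_positions(
        [(2, 1, "hbond")], aln, "ligand", "reference")
    assert flagged == [2] and dropped == 0
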