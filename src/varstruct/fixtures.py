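"""Deterministic synthetic structures, cohorts and alignments with known
ground truth.

Everything here is built from ideal internal coordinates (standard peptide
bond lengths and angles) or drawn from a seeded generator, so tests and the
acceptance workflow never need a downloaded structure.  Each generator
returns its ground truth alongside the object: the expected secondary
structure of an ideal helix, the constructed pair distances of a salt
bridge or disulfide fixture, the preset consensus calls of a predictor
cohort.  None of these are real proteins; they emulate local geometry, not
evolved tertiary structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Atom, ProteinStructure, Residue, VariantSpec, VarstructError
from .data.sidechains import (ANGLE_C_N_CA, ANGLE_CA_C_N, ANGLE_CA_C_O,
                              ANGLE_N_CA_C, BOND_C_N, BOND_C_O, BOND_CA_C,
                              BOND_N_CA, OMEGA_TRANS)
from .geometry import place_atom, unit
from .io import PredictorTable, DEFAULT_CUTOFF
from .mutate import build_sidechain, DEFAULT_LIBRARY

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -120.0, 135.0


@dataclass
class FixtureSpec:
    kind: str
    length: int = 15
    seed: int = 0
    parameters: dict = field(default_factory=dict)


def _backbone_from_dihedrals(phi_psi: list[tuple[float, float]],
                             omega: float = OMEGA_TRANS) -> list[dict]:
    """Backbone N/CA/C/O coordinates for a chain with given (phi, psi).

    phi of the first residue and psi of the last are ignored (undefined).
    """
    n_res = len(phi_psi)
    coords: list[dict] = []
    # seed the first residue explicitly
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + BOND_N_CA * np.array([1.0, 0.0, 0.0])
    theta = np.radians(180.0 - ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([np.cos(theta), np.sin(theta), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = coords[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"],
                         BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i,
                          BOND_N_CA, ANGLE_C_N_CA, omega)
        phi_i = phi_psi[i][0]
        c_i = place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi_i)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl oxygens: in the peptide plane, trans to the next N
    for i, frame in enumerate(coords):
        if i + 1 < n_res:
            psi_i = phi_psi[i][1]
            o = place_atom(frame["N"], frame["CA"], frame["C"],
                           BOND_C_O, ANGLE_CA_C_O, psi_i + 180.0)
        else:
            o = place_atom(frame["N"], frame["CA"], frame["C"],
                           BOND_C_O, ANGLE_CA_C_O, 0.0)
        frame["O"] = o
    return coords


def build_chain(sequence: str, phi_psi: list[tuple[float, float]],
                start_number: int = 1, chain_id: str = "A",
                rng: np.random.Generator | None = None) -> ProteinStructure:
    """A full-atom chain with the given sequence and backbone dihedrals.

    Side chains take each residue type's highest-prior rotamer (or a seeded
    random one when `rng` is given).
    """
    if len(sequence) != len(phi_psi):
        raise VarstructError("sequence and dihedral list lengths differ")
    frames = _backbone_from_dihedrals(phi_psi)
    residues = []
    for i, (aa, frame) in enumerate(zip(sequence, frames)):
        atoms = [Atom("N", "N", frame["N"]), Atom("CA", "C", frame["CA"]),
                 Atom("C", "C", frame["C"]), Atom("O", "O", frame["O"])]
        rots = DEFAULT_LIBRARY.for_type(aa)
        if rng is None:
            chis = max(rots, key=lambda rw: rw[1])[0]
        else:
            idx = int(rng.integers(len(rots)))
            chis = rots[idx][0]
        atoms += build_sidechain(frame["N"], frame["CA"], frame["C"], aa, chis)
        residues.append(Residue(start_number + i, aa, atoms))
    return ProteinStructure(chain_id=chain_id, residues=residues,
                            source=f"fixture:{sequence[:8]}")


def _translate(structure: ProteinStructure, shift: np.ndarray) -> None:
    for r in structure.residues:
        for a in r.atoms:
            a.coords = a.coords + shift


def _place_group(chain: ProteinStructure, anchor: np.ndarray,
                 inner: np.ndarray, target: np.ndarray,
                 approach: np.ndarray) -> None:
    """Rigidly move `chain` so its anchor atom lands on `target` with the
    inner->anchor bond pointing along `approach` (so the rest of the group
    sits behind the anchor, away from the partner atom)."""
    from .geometry import rotation_between
    # inner sits beyond the anchor along `approach`, i.e. the rest of the
    # group points away from the partner atom
    R = rotation_between(anchor - inner, -approach)
    for r in chain.residues:
        for a in r.atoms:
            a.coords = R @ (a.coords - anchor) + anchor
    _translate(chain, target - anchor)


def make_structure(spec: FixtureSpec) -> tuple[ProteinStructure, dict]:
    """Build a synthetic fixture structure plus its ground-truth sidecar."""
    kind = spec.kind
    rng = np.random.default_rng(spec.seed)
    params = spec.parameters

    if kind == "ideal_helix":
        n = spec.length
        phi = params.get("phi", HELIX_PHI)
        psi = params.get("psi", HELIX_PSI)
        seq = params.get("sequence", "A" * n)
        s = build_chain(seq, [(phi, psi)] * n)
        truth = {"kind": kind,
                 "helix_core": list(range(2, n)),  # interior residues
                 "expected_backbone_hbonds": max(0, n - 4)}
        return s, truth

    if kind == "beta_hairpin":
        arm = params.get("arm", 6)
        seq = params.get("sequence", "V" * arm + "NG" + "V" * arm)
        # near-type-I' turn closing the hairpin with correct ladder registry
        dihedrals = ([(STRAND_PHI, STRAND_PSI)] * arm
                     + [(55.0, 45.0), (90.0, 0.0)]
                     + [(STRAND_PHI, STRAND_PSI)] * arm)
        s = build_chain(seq, dihedrals)
        truth = {"kind": kind, "n_strands": 2,
                 "strand1": list(range(2, arm + 1)),
                 "strand2": list(range(arm + 3, 2 * arm + 2)),
                 "turn": [arm + 1, arm + 2]}
        return s, truth

    if kind == "salt_bridge_pair":
        d = params.get("distance", 3.5)
        basic = build_chain("GKG", [(HELIX_PHI, HELIX_PSI)] * 3, start_number=1)
        acidic = build_chain("GEG", [(HELIX_PHI, HELIX_PSI)] * 3, start_number=10)
        nz = basic.residue_at(2).atom("NZ").coords
        # approach along the Lys side-chain direction, carboxylate pointing
        # back at NZ so OE1 is the closest acidic atom
        ca = basic.residue_at(2).atom("CA").coords
        direction = unit(nz - ca)
        target = nz + d * direction
        _place_group(acidic, acidic.residue_at(11).atom("OE1").coords,
                     acidic.residue_at(11).atom("CD").coords, target, direction)
        combined = ProteinStructure(
            chain_id="A",
            residues=[r.copy() for r in basic.residues]
            + [r.copy() for r in acidic.residues],
            source="fixture:salt_bridge_pair")
        from .structops import SALT_BRIDGE_MAX
        # ground truth from the placed coordinates themselves, so exact
        # boundary cases resolve the same way for every consumer
        nz_f = combined.residue_at(2).atom("NZ").coords
        d_min = min(
            float(np.linalg.norm(nz_f - combined.residue_at(11).atom(n).coords))
            for n in ("OE1", "OE2"))
        truth = {"kind": kind, "distance": d,
                 "expected_bridges": [[2, 11]] if d_min <= SALT_BRIDGE_MAX
                 else []}
        return combined, truth

    if kind == "disulfide_pair":
        d = params.get("distance", 2.05)
        c1 = build_chain("GCG", [(HELIX_PHI, HELIX_PSI)] * 3, start_number=1)
        c2 = build_chain("GCG", [(HELIX_PHI, HELIX_PSI)] * 3, start_number=10)
        sg1 = c1.residue_at(2).atom("SG").coords
        ca1 = c1.residue_at(2).atom("CA").coords
        direction = unit(sg1 - ca1)
        target = sg1 + d * direction
        _place_group(c2, c2.residue_at(11).atom("SG").coords,
                     c2.residue_at(11).atom("CB").coords, target, direction)
        combined = ProteinStructure(
            chain_id="A",
            residues=[r.copy() for r in c1.residues]
            + [r.copy() for r in c2.residues],
            source="fixture:disulfide_pair")
        from .structops import DISULFIDE_MAX
        d_placed = float(np.linalg.norm(
            combined.residue_at(2).atom("SG").coords
            - combined.residue_at(11).atom("SG").coords))
        truth = {"kind": kind, "distance": d,
                 "expected_pairs": [[2, 11]] if d_placed <= DISULFIDE_MAX
                 else []}
        return combined, truth

    if kind == "two_chain_complex":
        d = params.get("distance", 3.2)
        a = build_chain("AAKAA", [(HELIX_PHI, HELIX_PSI)] * 5, chain_id="A")
        b = build_chain("AAEAA", [(HELIX_PHI, HELIX_PSI)] * 5, chain_id="B")
        nz = a.residue_at(3).atom("NZ").coords
        ca = a.residue_at(3).atom("CA").coords
        direction = unit(nz - ca)
        target = nz + d * direction
        _place_group(b, b.residue_at(3).atom("OE1").coords,
                     b.residue_at(3).atom("CD").coords, target, direction)
        truth = {"kind": kind, "distance": d,
                 "expected_salt_bridge": [3, 3]}
        return a, {"chain_b": b, **truth}

    if kind == "random_coil":
        n = spec.length
        alphabet = params.get("alphabet", "ACDEFGHIKLMNPQRSTVWY")
        seq = "".join(rng.choice(list(alphabet)) for _ in range(n))
        dihedrals = [(float(rng.uniform(-150.0, -50.0)),
                      float(rng.uniform(60.0, 170.0))) for _ in range(n)]
        s = build_chain(seq, dihedrals, rng=rng)
        return s, {"kind": kind, "sequence": seq}

    raise VarstructError(f"unknown fixture kind {kind!r}")


def make_cys_scaffold(pair_distance: float = 2.05
                      ) -> tuple[ProteinStructure, dict]:
    """Synthetic chemokine-style cysteine scaffold in precursor numbering.

    Three chain segments carry cysteines at precursor positions 33, 34, 57
    and 73, rigidly placed so the SG-SG pairs (33, 57) and (34, 73) sit at
    `pair_distance`.  This is a constructed geometry, not a real chemokine:
    it exercises precursor-numbered disulfide detection and loss, nothing
    else.
    """
    core = build_chain("GACCAG", [(STRAND_PHI, STRAND_PSI)] * 6,
                       start_number=31)  # Cys33, Cys34
    seg57 = build_chain("ACA", [(HELIX_PHI, HELIX_PSI)] * 3, start_number=56)
    seg73 = build_chain("ACA", [(HELIX_PHI, HELIX_PSI)] * 3, start_number=72)
    for cys_pos, seg, seg_cys in ((33, seg57, 57), (34, seg73, 73)):
        sg = core.residue_at(cys_pos).atom("SG").coords
        cb = core.residue_at(cys_pos).atom("CB").coords
        direction = unit(sg - cb)
        _place_group(seg, seg.residue_at(seg_cys).atom("SG").coords,
                     seg.residue_at(seg_cys).atom("CB").coords,
                     sg + pair_distance * direction, direction)
    combined = ProteinStructure(
        chain_id="A",
        residues=[r.copy() for r in core.residues]
        + [r.copy() for r in seg57.residues]
        + [r.copy() for r in seg73.residues],
        source="fixture:cys_scaffold(synthetic)")
    truth = {"expected_pairs": [[33, 57], [34, 73]],
             "distance": pair_distance}
    return combined, truth


def make_charge_reversal_site(distance: float = 3.5
                              ) -> tuple[ProteinStructure, dict]:
    """Synthetic helix site where a Lys -> Glu charge reversal creates a
    salt bridge with a nearby histidine.

    A Lys at precursor position 78 sits on an ideal helix; a His at
    position 39 is rigidly placed where the Glu78 carboxylate of the
    rebuilt mutant side chain will point, `distance` A from OE1.  In the
    wild type the His makes no salt bridge; after the K78E substitution it
    does.  Constructed geometry, precursor numbering only.
    """
    helix = build_chain("AAAAKAAAAAA", [(HELIX_PHI, HELIX_PSI)] * 11,
                        start_number=74)
    probe = ProteinStructure(residues=[r.copy() for r in helix.residues])
    from .mutate import build_mutant
    mut_iso, _ = build_mutant(probe, VariantSpec(78, "K", "E"))
    oe1 = mut_iso.residue_at(78).atom("OE1").coords
    cd = mut_iso.residue_at(78).atom("CD").coords
    outward = unit(oe1 - cd)
    his = build_chain("AHA", [(HELIX_PHI, HELIX_PSI)] * 3, start_number=38)
    _place_group(his, his.residue_at(39).atom("NE2").coords,
                 his.residue_at(39).atom("CD2").coords,
                 oe1 + distance * outward, outward)
    combined = ProteinStructure(
        chain_id="A",
        residues=[r.copy() for r in his.residues]
        + [r.copy() for r in helix.residues],
        source="fixture:charge_reversal(synthetic)")
    truth = {"variant": "K78E", "expected_gain": [39, 78],
             "distance": distance}
    return combined, truth


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

METHOD_NAMES = ("maestro", "inps3d", "popmusic", "dynamut2", "duet")


def make_variant_cohort(n: int, seed: int, sequence: str,
                        fractions: tuple[float, float, float] = (0.5, 0.2, 0.3),
                        cutoff: float = DEFAULT_CUTOFF
                        ) -> tuple[list[VariantSpec], PredictorTable, dict]:
    """Random distinct missense variants plus a predictor table whose
    3-of-5 consensus outcomes are preset.

    `fractions` = (less, more, uncertain) target proportions.  Returns
    (variants, predictor table, ground truth mapping each variant label to
    its intended consensus call).
    """
    max_variants = 19 * len(sequence)
    if n > max_variants:
        raise VarstructError(f"cannot draw {n} distinct variants from a "
                             f"{len(sequence)}-residue sequence")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise VarstructError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    chosen: set[tuple[int, str]] = set()
    variants: list[VariantSpec] = []
    while len(variants) < n:
        pos = int(rng.integers(1, len(sequence) + 1))
        wt = sequence[pos - 1]
        mut = aas[int(rng.integers(20))]
        if mut == wt or (pos, mut) in chosen:
            continue
        chosen.add((pos, mut))
        variants.append(VariantSpec(pos, wt, mut))

    calls = (["less_stable"] * int(round(fractions[0] * n))
             + ["more_stable"] * int(round(fractions[1] * n)))
    calls += ["uncertain"] * (n - len(calls))
    rng.shuffle(calls)

    table = PredictorTable(methods=list(METHOD_NAMES),
                           cutoffs={m: cutoff for m in METHOD_NAMES})
    truth: dict[str, str] = {}
    for v, call in zip(variants, calls):
        values = _draw_record(rng, call, cutoff)
        table.records[v.label] = dict(zip(METHOD_NAMES, values))
        truth[v.label] = call
    return variants, table, truth


def _draw_record(rng: np.random.Generator, call: str, cutoff: float
                 ) -> list[float]:
    """Five ddG values resolving to the requested consensus call."""
    small = lambda: float(rng.uniform(-0.9, 0.9)) * cutoff  # abstaining value
    strong = lambda sign: sign * float(rng.uniform(1.2, 4.0)) * cutoff
    idx = list(range(5))
    rng.shuffle(idx)
    vals = [0.0] * 5
    if call in ("less_stable", "more_stable"):
        sign = -1.0 if call == "less_stable" else 1.0
        k = int(rng.integers(3, 6))  # 3..5 agreeing significant votes
        for i in idx[:k]:
            vals[i] = strong(sign)
        for i in idx[k:]:
            # remainder must not assemble an opposing majority; with <=2
            # slots left it cannot, so anything goes
            vals[i] = small() if rng.random() < 0.7 else strong(-sign)
    else:
        # uncertain: at most 2 significant votes in each direction
        n_less = int(rng.integers(0, 3))
        n_more = int(rng.integers(0, 3))
        for i in idx[:n_less]:
            vals[i] = strong(-1.0)
        for i in idx[n_less:n_less + n_more]:
            vals[i] = strong(1.0)
        for i in idx[n_less + n_more:]:
            vals[i] = small()
    return [round(v, 3) for v in vals]
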