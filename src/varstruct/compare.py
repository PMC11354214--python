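"""Wild-type vs mutant comparison: profile diffs, consensus stability calls
and interface mapping.

The stability call follows a 3-of-5 predictor vote: a method votes
"less stable" when its ddG is at or below minus its significance cutoff,
"more stable" at or above plus the cutoff, and abstains in between (or when
its value is missing); three agreeing significant votes decide the call,
anything else is "uncertain".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ProteinStructure, VariantSpec, VarstructError
from .io import Alignment, PredictorTable
from .structops import (StructuralProfile, detect_hbonds, detect_salt_bridges)

LESS_STABLE = "less_stable"
MORE_STABLE = "more_stable"
UNCERTAIN = "uncertain"
NOT_EVALUATED = "not_evaluated"
CONSENSUS_VOTES = 3


@dataclass
class StabilityCall:
    votes: dict[str, str]           # method -> 'less' | 'more' | 'abstain'
    call: str
    missing: list[str] = field(default_factory=list)

    @property
    def votes_less(self) -> int:
        return sum(1 for v in self.votes.values() if v == "less")

    @property
    def votes_more(self) -> int:
        return sum(1 for v in self.votes.values() if v == "more")


def consensus_stability(record: dict[str, float | None],
                        cutoffs: dict[str, float]) -> StabilityCall:
    """3-of-5 consensus stability classification of one variant.

    `record` maps each of the five method names to a ddG in kcal/mol
    (negative = destabilizing) or None; `cutoffs` gives each method's
    absolute significance cutoff.
    """
    if len(record) != 5:
        raise VarstructError("consensus needs exactly 5 predictor values")
    votes: dict[str, str] = {}
    missing: list[str] = []
    for method, value in record.items():
        cut = cutoffs[method]
        if value is None:
            votes[method] = "abstain"
            missing.append(method)
        elif value <= -cut:
            votes[method] = "less"
        elif value >= cut:
            votes[method] = "more"
        else:
            votes[method] = "abstain"
    n_less = sum(1 for v in votes.values() if v == "less")
    n_more = sum(1 for v in votes.values() if v == "more")
    if n_less >= CONSENSUS_VOTES:
        call = LESS_STABLE
    elif n_more >= CONSENSUS_VOTES:
        call = MORE_STABLE
    else:
        call = UNCERTAIN
    return StabilityCall(votes=votes, call=call, missing=missing)


@dataclass
class ImpactReport:
    """Structural and stability impact of one variant relative to wild type."""

    variant: VariantSpec
    ss_changed: bool = False
    ss_old: str = ""
    ss_new: str = ""
    burial_changed: bool = False
    burial_old: str = ""
    burial_new: str = ""
    delta_rsa: float = 0.0
    hbonds_gained: list[tuple[int, int]] = field(default_factory=list)
    hbonds_lost: list[tuple[int, int]] = field(default_factory=list)
    salt_bridges_gained: list[tuple[int, int]] = field(default_factory=list)
    salt_bridges_lost: list[tuple[int, int]] = field(default_factory=list)
    hydrophobic_gained: list[tuple[int, int]] = field(default_factory=list)
    hydrophobic_lost: list[tuple[int, int]] = field(default_factory=list)
    disulfide_lost: bool = False
    cys_introduced: bool = False
    stability: str = NOT_EVALUATED
    stability_votes: StabilityCall | None = None
    conserved_flag: bool = False
    conservation_grade: int | None = None
    region: str = ""
    error: str = ""

    @property
    def any_structural_change(self) -> bool:
        return bool(self.ss_changed or self.burial_changed
                    or self.hbonds_gained or self.hbonds_lost
                    or self.salt_bridges_gained or self.salt_bridges_lost
                    or self.disulfide_lost or self.cys_introduced)

    def to_dict(self) -> dict:
        def fmt(pairs):
            return ";".join(f"{a}-{b}" for a, b in sorted(pairs))
        return {
            "variant": self.variant.label,
            "position": self.variant.position,
            "region": self.region,
            "ss_changed": self.ss_changed,
            "ss": f"{self.ss_old}>{self.ss_new}",
            "burial_changed": self.burial_changed,
            "burial": f"{self.burial_old}>{self.burial_new}",
            "delta_rsa": round(self.delta_rsa, 2),
            "hbonds_gained": fmt(self.hbonds_gained),
            "hbonds_lost": fmt(self.hbonds_lost),
            "salt_bridges_gained": fmt(self.salt_bridges_gained),
            "salt_bridges_lost": fmt(self.salt_bridges_lost),
            "hydrophobic_gained": fmt(self.hydrophobic_gained),
            "hydrophobic_lost": fmt(self.hydrophobic_lost),
            "disulfide_lost": self.disulfide_lost,
            "cys_introduced": self.cys_introduced,
            "stability": self.stability,
            "conserved_flag": self.conserved_flag,
            "conservation_grade": self.conservation_grade,
            "any_structural_change": self.any_structural_change,
            "annotation": self.variant.annotation,
            "error": self.error,
        }


def _pair_set(items) -> set[tuple[int, int]]:
    out = set()
    for it in items:
        pos = sorted(p for _, p in it.pair)
        if len(pos) == 1:  # self-pair cannot happen, defensive
            continue
        out.add((pos[0], pos[1]))
    return out


def diff_profiles(wt: StructuralProfile, mut: StructuralProfile,
                  variant: VariantSpec) -> ImpactReport:
    """Site-focused structural diff of two same-length, same-numbering
    profiles.  Gains/losses are residue pairs present in one interaction
    set and not the other; with a rigid backbone these are confined to
    pairs involving the mutated side chain or partners whose local
    geometry it perturbs."""
    if wt.positions != mut.positions:
        raise VarstructError("profiles have mismatched residue numbering")
    p = variant.position
    if p not in wt.ss:
        raise VarstructError(f"variant position {p} not in profile")

    rep = ImpactReport(variant=variant)
    rep.ss_old, rep.ss_new = wt.ss[p], mut.ss[p]
    rep.ss_changed = rep.ss_old != rep.ss_new
    rep.burial_old, rep.burial_new = wt.burial_class[p], mut.burial_class[p]
    rep.burial_changed = rep.burial_old != rep.burial_new
    rep.delta_rsa = mut.rsa[p] - wt.rsa[p]

    for kind, gained_attr, lost_attr in (
            ("hbonds", "hbonds_gained", "hbonds_lost"),
            ("salt_bridges", "salt_bridges_gained", "salt_bridges_lost"),
            ("hydrophobic_contacts", "hydrophobic_gained", "hydrophobic_lost")):
        wt_set = _pair_set(getattr(wt, kind))
        mut_set = _pair_set(getattr(mut, kind))
        setattr(rep, gained_attr, sorted(mut_set - wt_set))
        setattr(rep, lost_attr, sorted(wt_set - mut_set))

    wt_ss_pairs = {(d.pos1, d.pos2) for d in wt.disulfides}
    mut_ss_pairs = {(d.pos1, d.pos2) for d in mut.disulfides}
    rep.disulfide_lost = any(p in pair for pair in wt_ss_pairs - mut_ss_pairs)
    rep.cys_introduced = variant.mut_aa == "C"
    return rep


def attach_stability(report: ImpactReport, table: PredictorTable | None) -> None:
    if table is None:
        return
    record = table.record(report.variant.label) or table.record(report.variant.hgvs)
    if record is None:
        return
    call = consensus_stability(record, table.cutoffs)
    report.stability = call.call
    report.stability_votes = call


# --------------------------------------------------------------------------
# interface mapping
# --------------------------------------------------------------------------

def interface_contacts(chain_a: ProteinStructure, chain_b: ProteinStructure
                       ) -> list[tuple[int, int, str]]:
    """Inter-chain H-bonds and salt bridges of a two-chain complex.

    Returns (position in chain A, position in chain B, interaction type)
    triples; both chains keep their own numbering.
    """
    if chain_a.chain_id == chain_b.chain_id:
        raise VarstructError("interface mapping needs two distinct chains")
    out: list[tuple[int, int, str]] = []
    for hb in detect_hbonds(chain_a, other=chain_b):
        if hb.donor_chain == chain_a.chain_id:
            out.append((hb.donor_pos, hb.acceptor_pos, "hbond"))
        else:
            out.append((hb.acceptor_pos, hb.donor_pos, "hbond"))
    for sb in detect_salt_bridges(chain_a, other=chain_b):
        if sb.basic_chain == chain_a.chain_id:
            out.append((sb.basic_pos, sb.acidic_pos, "salt_bridge"))
        else:
            out.append((sb.acidic_pos, sb.basic_pos, "salt_bridge"))
    return sorted(set(out))


def map_interface_positions(contacts: list[tuple[int, int, str]],
                            aln: Alignment, ligand: str, reference: str,
                            ligand_side: int = 0
                            ) -> tuple[list[int], int]:
    """Map contact positions of a complex's ligand chain onto a reference
    sequence through an alignment.

    `ligand_side` selects which element of each contact triple belongs to
    the aligned ligand chain (0 = first).  Returns (sorted flagged
    reference positions, number of contacts dropped at gapped columns).
    """
    for sid in (ligand, reference):
        if sid not in aln.rows:
            raise VarstructError(f"sequence {sid!r} not in alignment")
    flagged: set[int] = set()
    dropped = 0
    for contact in contacts:
        pos = contact[ligand_side]
        mapped = aln.map_position(ligand, pos, reference)
        if mapped is None:
            dropped += 1
        else:
            flagged.add(mapped)
    return sorted(flagged), dropped
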