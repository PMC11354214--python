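"""Chemokine-fold region annotation and cohort-level summaries.

The canonical chemokine fold, in precursor numbering, is: a cleavable
N-terminal signal peptide, an N-loop (carrying the CC cysteine pair), a
three-stranded antiparallel beta-sheet whose strands are connected by the
30s and 40s loops, a 50s loop after the third strand, and a C-terminal
alpha-helix.  Strand and helix intervals are derived from the model's own
secondary-structure segmentation; loops are named by order between them.
Any interval can be overridden by the user.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import pandas as pd

from .core import VarstructError
from .compare import ImpactReport, LESS_STABLE

REGION_NAMES = ("signal_peptide", "N_loop", "beta1", "thirties_loop", "beta2",
                "forties_loop", "beta3", "fifties_loop", "C_helix", "other")

SIGNAL_PEPTIDE_LENGTH = 23


@dataclass
class RegionAnnotation:
    """Ordered, non-overlapping (name, start, end) intervals covering the
    sequence, 1-based inclusive."""

    intervals: list[tuple[str, int, int]]
    n_strands_detected: int = 3

    def __post_init__(self) -> None:
        prev_end = 0
        for name, start, end in self.intervals:
            if start <= prev_end or end < start:
                raise VarstructError("region intervals must be ordered and "
                                     "non-overlapping")
            prev_end = end

    def region_of(self, position: int) -> str:
        for name, start, end in self.intervals:
            if start <= position <= end:
                return name
        return "other"

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.intervals, columns=["region", "start", "end"]).to_csv(
            path, sep="\t", index=False)


def _ss_segments(labels: list[str], wanted: str) -> list[tuple[int, int]]:
    """(start_idx, end_idx) 0-based inclusive runs of one SS letter."""
    segs, start = [], None
    for i, lab in enumerate(labels + ["$"]):
        if lab == wanted and start is None:
            start = i
        elif lab != wanted and start is not None:
            segs.append((start, i - 1))
            start = None
    return segs


def derive_regions(ss: dict[int, str], signal_len: int = SIGNAL_PEPTIDE_LENGTH,
                   overrides: dict[str, tuple[int, int]] | None = None
                   ) -> RegionAnnotation:
    """Derive chemokine-fold regions from per-residue SS labels.

    `ss` maps precursor positions to reduced labels.  Strands are E-runs
    after the signal peptide, expected to number three; the C-helix is the
    last H-run after the strands.  Fewer or more than three strands emits a
    warning and names loops by order.  `overrides` replaces the derived
    (start, end) of any named region.
    """
    positions = sorted(ss)
    if not positions:
        raise VarstructError("empty secondary-structure map")
    last = positions[-1]
    labels = [ss[p] for p in positions]

    strand_runs = [(positions[a], positions[b])
                   for a, b in _ss_segments(labels, "E")
                   if positions[a] > signal_len]
    if len(strand_runs) != 3:
        warnings.warn(f"expected 3 beta-strands, found {len(strand_runs)}; "
                      f"loop names assigned by order")
    helix_runs = [(positions[a], positions[b])
                  for a, b in _ss_segments(labels, "H")
                  if positions[a] > signal_len
                  and (not strand_runs or positions[a] > strand_runs[-1][1])]
    c_helix = helix_runs[-1] if helix_runs else None

    named: dict[str, tuple[int, int]] = {}
    if signal_len > 0:
        named["signal_peptide"] = (1, min(signal_len, last))
    strand_names = ["beta1", "beta2", "beta3"]
    for name, run in zip(strand_names, strand_runs):
        named[name] = run
    loop_names = ["thirties_loop", "forties_loop", "fifties_loop"]
    # N-loop: from end of signal to the first strand
    if strand_runs and strand_runs[0][0] > signal_len + 1:
        named["N_loop"] = (signal_len + 1, strand_runs[0][0] - 1)
    for k in range(len(strand_runs) - 1):
        lo = strand_runs[k][1] + 1
        hi = strand_runs[k + 1][0] - 1
        if lo <= hi and k < len(loop_names):
            named[loop_names[k]] = (lo, hi)
    if c_helix is not None:
        named["C_helix"] = c_helix
        if strand_runs:
            lo = strand_runs[-1][1] + 1
            if lo <= c_helix[0] - 1:
                named["fifties_loop"] = (lo, c_helix[0] - 1)
    # paint positions region by region; user overrides win over derived
    # intervals, uncovered positions become 'other'
    paint = ["other"] * (last + 1)
    for name, (s, e) in named.items():
        if overrides and name in overrides:
            continue
        for p in range(max(1, s), min(last, e) + 1):
            paint[p] = name
    for name, (s, e) in (overrides or {}).items():
        for p in range(max(1, s), min(last, e) + 1):
            paint[p] = name
    filled: list[tuple[str, int, int]] = []
    start = 1
    for p in range(2, last + 2):
        if p > last or paint[p] != paint[start]:
            filled.append((paint[start], start, p - 1))
            start = p
    return RegionAnnotation(filled, n_strands_detected=len(strand_runs))


# --------------------------------------------------------------------------
# cohort summary
# --------------------------------------------------------------------------

def cohort_summary(reports: list[ImpactReport],
                   annotation: RegionAnnotation | None = None) -> dict:
    """Aggregate per-variant impact flags into cohort counts.

    Counts variants per region, per changed parameter, stability
    decreases, the overlap of stability loss with interaction loss, and
    conserved positions with/without structural change.
    """
    if not reports:
        raise VarstructError("cohort summary needs at least one report")
    ok = [r for r in reports if not r.error]
    summary: dict = {
        "n_variants": len(reports),
        "n_failed": len(reports) - len(ok),
        "any_structural_change": sum(1 for r in ok if r.any_structural_change),
        "ss_changes": sum(1 for r in ok if r.ss_changed),
        "accessibility_changes": sum(1 for r in ok if r.burial_changed),
        "hbond_changes": sum(1 for r in ok if r.hbonds_gained or r.hbonds_lost),
        "salt_bridge_gains": sum(1 for r in ok if r.salt_bridges_gained),
        "salt_bridge_losses": sum(1 for r in ok if r.salt_bridges_lost),
        "disulfide_losses": sum(1 for r in ok if r.disulfide_lost),
        "cys_introduced": sum(1 for r in ok if r.cys_introduced),
        "less_stable": sum(1 for r in ok if r.stability == LESS_STABLE),
        "more_stable": sum(1 for r in ok if r.stability == "more_stable"),
        "uncertain_stability": sum(1 for r in ok if r.stability == "uncertain"),
        "stability_loss_with_interaction_loss": sum(
            1 for r in ok if r.stability == LESS_STABLE
            and (r.hbonds_lost or r.salt_bridges_lost or r.disulfide_lost)),
        "stability_loss_only": sum(
            1 for r in ok if r.stability == LESS_STABLE
            and not r.any_structural_change),
        "conserved_with_change": sum(
            1 for r in ok if r.conserved_flag and r.any_structural_change),
        "conserved_without_change": sum(
            1 for r in ok if r.conserved_flag and not r.any_structural_change),
    }
    if annotation is not None:
        per_region = {name: 0 for name in REGION_NAMES}
        for r in reports:
            per_region[annotation.region_of(r.variant.position)] += 1
        summary["per_region"] = per_region
    return summary


def summary_to_json(summary: dict, path: str, header: dict | None = None) -> None:
    with open(path, "w") as fh:
        json.dump({**(header or {}), "summary": summary}, fh, indent=1)


def summary_to_markdown(summary: dict) -> str:
    lines = ["| quantity | count |", "| --- | --- |"]
    for key, val in summary.items():
        if key == "per_region":
            continue
        lines.append(f"| {key} | {val} |")
    if "per_region" in summary:
        lines.append("")
        lines.append("| region | variants |")
        lines.append("| --- | --- |")
        for name, count in summary["per_region"].items():
            lines.append(f"| {name} | {count} |")
    return "\n".join(lines)
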