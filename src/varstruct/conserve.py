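"""Per-position conservation grades on the 1-9 scale.

Grades can be computed from a multiple sequence alignment with a
normalized-entropy binning (a desk-scale stand-in for phylogeny-aware rate
estimation: grade 9 = invariant column, grade 1 = maximally variable), or
ingested from an external grade export.  Either way, positions with grade
>= 7 are flagged as highly conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .core import VarstructError
from .io import Alignment

HIGH_CONSERVATION_GRADE = 7


@dataclass
class ConservationProfile:
    grades: dict[int, int]          # precursor position -> grade 1..9
    source: str = "computed"        # computed | ingested

    def grade(self, position: int) -> int:
        if position not in self.grades:
            raise VarstructError(f"position {position} has no conservation grade")
        return self.grades[position]


def column_entropy(residues: list[str]) -> float:
    """Normalized Shannon entropy of a column, base 20, gaps excluded."""
    counts: dict[str, int] = {}
    for ch in residues:
        if ch in ("-", ".", "X"):
            continue
        counts[ch] = counts.get(ch, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return 1.0
    h = -sum((c / total) * math.log(c / total) for c in counts.values())
    return min(h / math.log(20.0), 1.0)


def entropy_to_grade(h: float) -> int:
    """grade = 9 - floor(h * 9), clipped to [1, 9]."""
    return max(1, min(9, 9 - math.floor(h * 9.0)))


def conservation_grades(msa: Alignment, reference: str,
                        offset: int = 0) -> ConservationProfile:
    """Grade every ungapped position of the reference sequence.

    `offset` shifts reference positions onto precursor numbering when the
    aligned reference is a mature-chain sequence.
    """
    if reference not in msa.rows:
        raise VarstructError(f"reference {reference!r} not in alignment")
    if len(msa.ids) < 3:
        raise VarstructError("conservation needs >= 3 aligned sequences")
    grades: dict[int, int] = {}
    for col, pos in enumerate(msa.col_to_pos[reference]):
        if pos is None:
            continue
        h = column_entropy(msa.column_residues(col))
        grades[pos + offset] = entropy_to_grade(h)
    return ConservationProfile(grades, source="computed")


def read_grades(path: str) -> ConservationProfile:
    """Ingest a grade export with columns [position, aa, grade, ...]."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "position" not in cols or "grade" not in cols:
        raise VarstructError(f"{path}: needs 'position' and 'grade' columns")
    grades = {}
    for _, row in df.iterrows():
        g = int(row[cols["grade"]])
        if not 1 <= g <= 9:
            raise VarstructError(f"grade {g} out of range at position "
                                 f"{row[cols['position']]}")
        grades[int(row[cols["position"]])] = g
    return ConservationProfile(grades, source="ingested")


def write_grades(profile: ConservationProfile, path: str,
                 sequence: str | None = None) -> None:
    rows = [{"position": p, "aa": sequence[p - 1] if sequence else "",
             "grade": g, "source": profile.source}
            for p, g in sorted(profile.grades.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def is_highly_conserved(profile: ConservationProfile, position: int) -> bool:
    """True iff the position's grade is 7 or better."""
    return profile.grade(position) >= HIGH_CONSERVATION_GRADE
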