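"""Core domain types: atoms, residues, structures, variants.

All residue numbering throughout the package is *precursor* numbering:
position 1 is the first residue of the translated chain, signal peptide
included.  Structure files that use mature-chain numbering (e.g. NMR
structures of a secreted chemokine that lack the signal peptide) are
shifted onto precursor coordinates with a user-supplied offset at read
time, so every downstream report speaks a single coordinate system.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field

import numpy as np

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA = frozenset(AA3_TO_1.values())

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class VarstructError(Exception):
    """Base class for errors raised by this package."""


@dataclass
class Atom:
    """A heavy atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise VarstructError(f"atom {self.name}: coords must be a finite 3-vector")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(), self.occupancy)


@dataclass
class Residue:
    """One amino-acid residue in precursor numbering."""

    number: int
    aa: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    chain: str = "A"

    def __post_init__(self) -> None:
        if self.aa not in STANDARD_AA:
            raise VarstructError(f"residue {self.number}: unknown amino acid {self.aa!r}")
        if self.number < 1:
            raise VarstructError(f"residue number must be >= 1, got {self.number}")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has(self, *names: str) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)

    @property
    def backbone(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_backbone]

    @property
    def sidechain(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_backbone]

    def copy(self) -> "Residue":
        return Residue(self.number, self.aa, [a.copy() for a in self.atoms],
                       self.insertion_code, self.chain)


@dataclass
class ProteinStructure:
    """An ordered single protein chain in precursor numbering."""

    chain_id: str = "A"
    residues: list[Residue] = field(default_factory=list)
    numbering_offset: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise VarstructError("residue numbers must be strictly increasing")
        for r in self.residues:
            r.chain = self.chain_id

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def positions(self) -> list[int]:
        return [r.number for r in self.residues]

    def residue_at(self, position: int) -> Residue:
        for r in self.residues:
            if r.number == position:
                return r
        raise VarstructError(f"no residue at precursor position {position}")

    def has_position(self, position: int) -> bool:
        return any(r.number == position for r in self.residues)

    def coords(self, atom_names: tuple[str, ...] | None = None) -> np.ndarray:
        """Stacked coordinates, optionally restricted to given atom names."""
        rows = [a.coords for r in self.residues for a in r.atoms
                if atom_names is None or a.name in atom_names]
        return np.array(rows).reshape(-1, 3)

    def copy(self) -> "ProteinStructure":
        s = ProteinStructure(self.chain_id, [r.copy() for r in self.residues],
                             self.numbering_offset, self.source)
        return s


_VARIANT_RE = re.compile(
    r"^(?:p\.)?"
    r"(?P<wt>[A-Z][a-z]{2}|[A-Z])"
    r"(?P<pos>\d+)"
    r"(?P<mut>[A-Z][a-z]{2}|[A-Z]|\*|Ter|fs.*|del|dup)$"
)

_NON_MISSENSE = {"*", "Ter", "del", "dup"}


def _to_one_letter(token: str) -> str | None:
    if len(token) == 1:
        return token if token in STANDARD_AA else None
    return AA3_TO_1.get(token.upper())


@dataclass(frozen=True)
class VariantSpec:
    """One missense substitution in precursor coordinates."""

    position: int
    wt_aa: str
    mut_aa: str
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.wt_aa not in STANDARD_AA or self.mut_aa not in STANDARD_AA:
            raise VarstructError(f"invalid amino acid in variant {self}")
        if self.wt_aa == self.mut_aa:
            raise VarstructError(
                f"variant {self.label}: substitution must change the amino acid")
        if self.position < 1:
            raise VarstructError("variant position must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @property
    def hgvs(self) -> str:
        return f"p.{AA1_TO_3[self.wt_aa].capitalize()}{self.position}" \
               f"{AA1_TO_3[self.mut_aa].capitalize()}"

    @classmethod
    def parse(cls, text: str, annotation: str = "") -> "VariantSpec":
        """Parse 'p.Lys78Glu', 'Lys78Glu' or 'K78E' notation.

        Raises VarstructError for stop/frameshift/indel notation and for
        silent (wt == mut) substitutions.
        """
        m = _VARIANT_RE.match(text.strip())
        if not m:
            raise VarstructError(f"cannot parse variant notation {text!r}")
        mut_tok = m.group("mut")
        if mut_tok in _NON_MISSENSE or mut_tok.startswith("fs"):
            raise VarstructError(f"variant {text!r} is not a missense substitution")
        wt = _to_one_letter(m.group("wt"))
        mut = _to_one_letter(mut_tok)
        if wt is None or mut is None:
            raise VarstructError(f"unknown amino-acid code in {text!r}")
        return cls(int(m.group("pos")), wt, mut, annotation)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)
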