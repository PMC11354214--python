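"""Reading and writing structures, variant tables, predictor tables, MSAs.

PDB parsing is delegated to gemmi; only ATOM records of standard amino
acids are kept (HETATM, waters, hydrogens and alternate locations other
than the first are dropped).  Residue numbers are shifted onto precursor
numbering by a caller-supplied offset at read time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from Bio import AlignIO

from .core import (AA3_TO_1, Atom, ProteinStructure, Residue, VariantSpec,
                   VarstructError)
from .data.chemistry import element_of

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# structures
# --------------------------------------------------------------------------

def _convert_chain(chain: gemmi.Chain, offset: int, source: str) -> ProteinStructure:
    residues: list[Residue] = []
    for res in chain:
        aa = AA3_TO_1.get(res.name.upper())
        if aa is None:
            continue  # hetero / non-standard residue
        atoms: list[Atom] = []
        seen: set[str] = set()
        for at in res:
            if at.altloc not in ("", "\0", "A"):
                continue
            if at.element.is_hydrogen:
                continue  # hydrogens are rebuilt geometrically downstream
            if at.name in seen:
                continue
            seen.add(at.name)
            elem = at.element.name.upper() or element_of(at.name)
            atoms.append(Atom(at.name, elem, np.array([at.pos.x, at.pos.y, at.pos.z]),
                              at.occ))
        if not atoms:
            continue
        if "CA" not in seen:
            warnings.warn(f"residue {res.name} {res.seqid.num}: no CA atom; retained")
        residues.append(Residue(res.seqid.num + offset, aa, atoms,
                                res.seqid.icode.strip()))
    return ProteinStructure(chain_id=chain.name or "A", residues=residues,
                            numbering_offset=offset, source=source)


def read_pdb(path: str, offset: int = 0, chain: str | None = None) -> ProteinStructure:
    """Read a single chain from a PDB file onto precursor numbering.

    Parameters
    ----------
    path : PDB-format file.  Only the first MODEL of an ensemble is used.
    offset : integer added to file residue numbers to obtain precursor
        numbering (e.g. 23 for a mature-chain chemokine file whose signal
        peptide was cleaved).
    chain : chain identifier; default is the first protein chain.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise VarstructError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise VarstructError(f"{path}: no models")
    model = st[0]
    names = [ch.name for ch in model]
    if chain is None:
        picked = model[0]
    else:
        if chain not in names:
            raise VarstructError(f"{path}: no chain {chain!r} (has {names})")
        picked = model[chain]
    structure = _convert_chain(picked, offset, source=str(path))
    if not structure.residues:
        raise VarstructError(f"{path}: chain {picked.name!r} has no standard residues")
    return structure


def read_chains(path: str, offsets: dict[str, int] | None = None
                ) -> dict[str, ProteinStructure]:
    """Read every protein chain of a (possibly multi-chain) PDB file."""
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise VarstructError(f"{path}: no models")
    out: dict[str, ProteinStructure] = {}
    for ch in st[0]:
        off = (offsets or {}).get(ch.name, 0)
        conv = _convert_chain(ch, off, source=f"{path}:{ch.name}")
        if conv.residues:
            out[ch.name] = conv
    if not out:
        raise VarstructError(f"{path}: no protein chains")
    return out


def write_pdb(structure: ProteinStructure, path: str,
              remarks: list[str] | None = None) -> None:
    """Write a structure as PDB ATOM records (file numbering = precursor
    numbering minus the structure's offset)."""
    lines: list[str] = []
    for text in remarks or []:
        lines.append(f"REMARK 999 {text}"[:80])
    serial = 0
    from .core import AA1_TO_3
    for res in structure.residues:
        resname = AA1_TO_3[res.aa]
        file_num = res.number - structure.numbering_offset
        for at in res.atoms:
            serial += 1
            name = at.name if len(at.name) == 4 else f" {at.name:<3s}"
            x, y, z = at.coords
            lines.append(
                f"ATOM  {serial:>5d} {name}{'':1s}{resname:<3s} "
                f"{structure.chain_id[:1]:1s}{file_num:>4d}{res.insertion_code[:1] or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{at.occupancy:6.2f}{0.0:6.2f}"
                f"          {at.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# variant tables
# --------------------------------------------------------------------------

def parse_variant_table(path: str, reference_sequence: str | None = None
                        ) -> list[VariantSpec]:
    """Parse a TSV/CSV variant table with columns [variant, annotation].

    Accepts 'p.Lys78Glu', 'Lys78Glu' and 'K78E' dialects.  Duplicates are
    collapsed with a warning; stop/frameshift rows are skipped (count
    logged).  If a reference sequence (precursor, position 1 = first
    residue) is given, wild-type letters are validated against it and a
    mismatch raises an error naming the position.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#").fillna("")
    cols = {c.lower(): c for c in df.columns}
    if "variant" not in cols:
        raise VarstructError(f"{path}: no 'variant' column (has {list(df.columns)})")
    ann_col = cols.get("annotation")
    out: list[VariantSpec] = []
    seen: set[tuple[int, str, str]] = set()
    skipped = 0
    duplicates = 0
    for _, row in df.iterrows():
        text = row[cols["variant"]].strip()
        if not text:
            continue
        try:
            v = VariantSpec.parse(text, annotation=row[ann_col].strip() if ann_col else "")
        except VarstructError as exc:
            skipped += 1
            logger.info("skipping row %r: %s", text, exc)
            continue
        key = (v.position, v.wt_aa, v.mut_aa)
        if key in seen:
            duplicates += 1
            warnings.warn(f"duplicate variant {v.label} collapsed")
            continue
        seen.add(key)
        out.append(v)
    if skipped:
        logger.info("%s: skipped %d non-missense/unparsable rows", path, skipped)
    if reference_sequence is not None:
        for v in out:
            if v.position > len(reference_sequence):
                raise VarstructError(
                    f"variant {v.label}: position beyond sequence length "
                    f"{len(reference_sequence)}")
            ref = reference_sequence[v.position - 1]
            if ref != v.wt_aa:
                raise VarstructError(
                    f"variant {v.label}: wild-type mismatch at position "
                    f"{v.position} (sequence has {ref})")
    return out


def write_variant_table(variants: list[VariantSpec], path: str) -> None:
    pd.DataFrame(
        {"variant": [v.label for v in variants],
         "annotation": [v.annotation for v in variants]}
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# predictor tables
# --------------------------------------------------------------------------

@dataclass
class PredictorTable:
    """Per-variant ddG values (kcal/mol) from five stability predictors.

    Sign convention after ingestion: negative = destabilizing.  Each method
    carries an absolute significance cutoff (kcal/mol).
    """

    methods: list[str]
    cutoffs: dict[str, float]
    records: dict[str, dict[str, float | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.methods) != 5:
            raise VarstructError("a predictor table needs exactly 5 methods")
        for m in self.methods:
            if self.cutoffs.get(m, 0.0) <= 0:
                raise VarstructError(f"method {m}: cutoff must be > 0")

    def record(self, variant_label: str) -> dict[str, float | None] | None:
        return self.records.get(variant_label)


DEFAULT_CUTOFF = 0.5  # kcal/mol, applied to every method unless overridden


def read_predictor_table(path: str, cutoffs: dict[str, float] | None = None,
                         flip_sign: tuple[str, ...] = ()) -> PredictorTable:
    """Read a TSV with columns [variant, <method1>..<method5>].

    `flip_sign` lists methods whose native convention is positive =
    destabilizing; their values are negated so that, internally, negative
    always means destabilizing.  Missing values stay None (that method
    abstains in the consensus).
    """
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.lower() != "variant"]
    if len(cols) != 5:
        raise VarstructError(f"{path}: expected 5 method columns, got {cols}")
    var_col = [c for c in df.columns if c.lower() == "variant"][0]
    cut = {m: DEFAULT_CUTOFF for m in cols}
    cut.update(cutoffs or {})
    table = PredictorTable(methods=list(cols), cutoffs=cut)
    for _, row in df.iterrows():
        rec: dict[str, float | None] = {}
        for m in cols:
            val = row[m]
            if pd.isna(val):
                rec[m] = None
            else:
                rec[m] = -float(val) if m in flip_sign else float(val)
        table.records[str(row[var_col]).strip()] = rec
    return table


def write_predictor_table(table: PredictorTable, path: str) -> None:
    rows = [{"variant": label, **vals} for label, vals in table.records.items()]
    pd.DataFrame(rows, columns=["variant", *table.methods]).to_csv(
        path, sep="\t", index=False)


# --------------------------------------------------------------------------
# alignments
# --------------------------------------------------------------------------

@dataclass
class Alignment:
    """An aligned set of sequences with per-sequence column maps.

    `col_to_pos[seq_id][column]` (0-based column) gives the 1-based ungapped
    position in that sequence, or None at a gap.
    """

    ids: list[str]
    rows: dict[str, str]
    col_to_pos: dict[str, list[int | None]]
    pos_to_col: dict[str, dict[int, int]]

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def map_position(self, from_id: str, position: int, to_id: str) -> int | None:
        """Map an ungapped 1-based position of one sequence onto another."""
        for sid in (from_id, to_id):
            if sid not in self.rows:
                raise VarstructError(f"sequence {sid!r} not in alignment")
        col = self.pos_to_col[from_id].get(position)
        if col is None:
            raise VarstructError(f"{from_id}: no position {position}")
        return self.col_to_pos[to_id][col]

    def column_residues(self, column: int) -> list[str]:
        return [self.rows[i][column] for i in self.ids]


def read_alignment(path: str) -> Alignment:
    """Read an aligned FASTA file; sequences must have equal aligned length."""
    try:
        msa = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise VarstructError(f"{path}: not a valid alignment: {exc}") from exc
    ids = [rec.id for rec in msa]
    rows = {rec.id: str(rec.seq).upper() for rec in msa}
    col_to_pos: dict[str, list[int | None]] = {}
    pos_to_col: dict[str, dict[int, int]] = {}
    for sid, seq in rows.items():
        cmap: list[int | None] = []
        pmap: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(seq):
            if ch in ("-", "."):
                cmap.append(None)
            else:
                pos += 1
                cmap.append(pos)
                pmap[pos] = col
        col_to_pos[sid] = cmap
        pos_to_col[sid] = pmap
    return Alignment(ids, rows, col_to_pos, pos_to_col)
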