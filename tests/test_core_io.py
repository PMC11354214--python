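"""Variant notation parsing, PDB round trips, tables and alignments."""

import numpy as np
import pytest

import varstruct as vs
from varstruct.core import VariantSpec, VarstructError
from varstruct.io import (parse_variant_table, read_alignment, read_pdb,
                          read_predictor_table, write_pdb,
                          write_variant_table)


@pytest.mark.parametrize("text,expected", [
    ("p.Lys78Glu", (78, "K", "E")),
    ("Lys78Glu", (78, "K", "E")),
    ("K78E", (78, "K", "E")),
    ("p.Cys34Ser", (34, "C", "S")),
    ("Trp80Gly", (80, "W", "G")),
])
def test_variant_notation_dialects(text, expected):
    v = VariantSpec.parse(text)
    assert (v.position, v.wt_aa, v.mut_aa) == expected


@pytest.mark.parametrize("text", [
    "K78K",          # silent substitution
    "p.Trp80Ter",    # stop
    "p.Trp80*",      # stop
    "p.Leu10del",    # deletion
    "nonsense",
])
def test_non_missense_rejected(text):
    with pytest.raises(VarstructError):
        VariantSpec.parse(text)


def test_hgvs_round_trip():
    v = VariantSpec.parse("K78E")
    assert v.hgvs == "p.Lys78Glu"
    assert VariantSpec.parse(v.hgvs) == v


def test_pdb_round_trip(tmp_path, ideal_helix):
    s, _ = ideal_helix
    path = tmp_path / "helix.pdb"
    write_pdb(s, str(path))
    back = read_pdb(str(path))
    assert back.sequence == s.sequence
    for r1, r2 in zip(s.residues, back.residues):
        assert [a.name for a in r1.atoms] == [a.name for a in r2.atoms]
        for a1, a2 in zip(r1.atoms, r2.atoms):
            assert np.allclose(a1.coords, a2.coords, atol=1e-3)


def test_numbering_offset_round_trip(tmp_path, ideal_helix):
    """A mature-numbered file read with the signal-peptide offset lands on
    precursor numbering; writing subtracts it again."""
    s, _ = ideal_helix
    shifted = s.copy()
    for i, r in enumerate(shifted.residues):
        r.number = r.number + 23
    shifted.numbering_offset = 23
    path = tmp_path / "mature.pdb"
    write_pdb(shifted, str(path))  # file numbering starts at 1
    back = read_pdb(str(path), offset=23)
    assert back.positions[0] == 24
    assert read_pdb(str(path), offset=0).positions[0] == 1


def test_variant_table_parsing(tmp_path):
    rows = ["variant\tannotation",
            "p.Lys78Glu\tmoderate",
            "K78E\t",                 # duplicate of the first
            "Cys34Ser\t",
            "p.Cys34Ser\t",           # duplicate
            "p.Trp80Ter\t",           # stop: skipped
            "Leu15His\t",
            "Leu16Pro\t",
            "Ala61Val\tmoderate",
            "Val47Ala\t",
            "Thr53Ser\t"]
    path = tmp_path / "variants.tsv"
    path.write_text("\n".join(rows) + "\n")
    with pytest.warns(UserWarning):
        variants = parse_variant_table(str(path))
    assert len(variants) == 7
    assert variants[0].annotation == "moderate"

    # idempotent on its own normalized output
    out = tmp_path / "normalized.tsv"
    write_variant_table(variants, str(out))
    again = parse_variant_table(str(out))
    assert again == variants


def test_variant_wt_mismatch_names_position(tmp_path):
    path = tmp_path / "v.tsv"
    path.write_text("variant\nL12M\n")
    seq = "MK" + "A" * 20  # position 12 is A, not L
    with pytest.raises(VarstructError, match="12"):
        parse_variant_table(str(path), reference_sequence=seq)


def test_alignment_column_maps(tmp_path):
    path = tmp_path / "aln.fasta"
    path.write_text(">s1\nAC-D\n>s2\nACED\n")
    aln = read_alignment(str(path))
    assert aln.map_position("s1", 3, "s2") == 4
    assert aln.map_position("s2", 3, "s1") is None  # gapped in s1
    # identity map for identical ungapped sequences
    path2 = tmp_path / "aln2.fasta"
    path2.write_text(">a\nMKWV\n>b\nMKWV\n")
    aln2 = read_alignment(str(path2))
    assert [aln2.map_position("a", i, "b") for i in range(1, 5)] == [1, 2, 3, 4]


def test_alignment_unequal_lengths_error(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">a\nMKWV\n>b\nMKW\n")
    with pytest.raises(VarstructError):
        read_alignment(str(path))


def test_msa_column_counts(tmp_path):
    path = tmp_path / "msa.fasta"
    path.write_text(">a\nMKL\n>b\nMKV\n>c\nMRL\n>d\nM-L\n>e\nMKL\n")
    aln = read_alignment(str(path))
    col1 = [c for c in aln.column_residues(1) if c != "-"]
    assert sorted(col1) == ["K", "K", "K", "R"]


def test_predictor_table_io(tmp_path):
    path = tmp_path / "pred.tsv"
    path.write_text("variant\tm1\tm2\tm3\tm4\tm5\n"
                    "K78E\t-1.0\t-0.8\t-0.6\t0.2\t\n")
    table = read_predictor_table(str(path))
    rec = table.record("K78E")
    assert rec["m1"] == -1.0 and rec["m5"] is None
    flipped = read_predictor_table(str(path), flip_sign=("m1",))
    assert flipped.record("K78E")["m1"] == 1.0


def test_predictor_table_requires_five_methods(tmp_path):
    path = tmp_path / "pred.tsv"
    path.write_text("variant\tm1\tm2\nX1Y\t0\t0\n")
    with pytest.raises(VarstructError):
        read_predictor_table(str(path))


def test_structure_invariants(ideal_helix):
    s, _ = ideal_helix
    assert s.sequence == "A" * 15
    assert s.positions == list(range(1, 16))
    with pytest.raises(VarstructError):
        vs.ProteinStructure(residues=[s.residues[1], s.residues[0]])
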