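"""Coordinate arithmetic, codon assembly, and sequence primitives."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bescreen import (
    CodingPosition,
    DomainError,
    MiniTranscript,
    OutOfModelError,
    ParseError,
    Segment,
    ValidationError,
    aa_three,
    c_to_codon,
    parse_c_position,
    revcomp,
    translate,
)

dna = st.text(alphabet="ACGTacgt", min_size=0, max_size=200)


# -- parsing ----------------------------------------------------------------


@pytest.mark.parametrize(
    "text,base,offset",
    [
        ("2843-2", 2843, -2),
        ("2234", 2234, 0),
        ("100+1", 100, 1),
        ("c.2843-2", 2843, -2),
    ],
)
def test_parse_c_position(text, base, offset):
    pos = parse_c_position(text)
    assert (pos.base, pos.intron_offset) == (base, offset)
    # re-rendering reproduces the canonical form
    assert str(pos) == text.removeprefix("c.")


@pytest.mark.parametrize("bad", ["", "abc", "2843--2", "+5", "12.3", "2843-2A>G"])
def test_parse_c_position_rejects_malformed(bad):
    with pytest.raises(ParseError):
        parse_c_position(bad)


# -- codon arithmetic --------------------------------------------------------


@pytest.mark.parametrize(
    "pos,codon,frame",
    [(2843, 948, 2), (2833, 945, 1), (2234, 745, 2), (1, 1, 1), (3, 1, 3), (4, 2, 1)],
)
def test_c_to_codon(pos, codon, frame):
    assert c_to_codon(pos) == (codon, frame)


def test_c_to_codon_rejects_nonpositive():
    with pytest.raises(DomainError):
        c_to_codon(0)


@given(st.integers(min_value=1, max_value=10**7))
def test_codon_span_roundtrip(pos):
    """Every CDS position lies inside the 3-base span of its codon."""
    codon, frame = c_to_codon(pos)
    start = 3 * codon - 2
    span = (start, start + 1, start + 2)
    assert pos in span
    assert span[frame - 1] == pos


# -- sequence primitives -----------------------------------------------------


def test_revcomp_known_value():
    assert revcomp("TTGAAGCATTCGGACAAACA") == "TGTTTGTCCGAATGCTTCAA"


def test_revcomp_handles_iupac():
    assert revcomp("NNGRRT") == "AYYCNN"


def test_revcomp_rejects_non_nucleotides():
    with pytest.raises(ParseError):
        revcomp("ACGU")


@given(dna)
def test_revcomp_involution(s):
    assert revcomp(revcomp(s)) == s


@pytest.mark.parametrize(
    "codon,aa1,aa3",
    [("ATG", "M", "Met"), ("TAT", "Y", "Tyr"), ("TGT", "C", "Cys"), ("TAA", "*", "Ter")],
)
def test_translate(codon, aa1, aa3):
    assert translate(codon) == aa1
    assert aa_three(aa1) == aa3


def test_translate_rejects_bad_codon():
    with pytest.raises(ParseError):
        translate("AT")
    with pytest.raises(ParseError):
        translate("AXG")


# -- transcript model --------------------------------------------------------


def test_codon_assembly_across_junction(fixture_ab):
    """Codon 948 spans the exon A / exon B junction: TGT -> Cys."""
    ref = fixture_ab.transcript.codon_sequence(948)
    assert (ref.bases, ref.aa1, ref.aa3, ref.complete) == ("TGT", "C", "Cys", True)


def test_codon_sequence_wild_type_values(fixture_ab, fixture_c):
    assert fixture_c.transcript.codon_sequence(745).bases == "ACG"  # Thr745
    assert fixture_c.transcript.codon_sequence(746).bases == "CTT"  # Leu746
    assert fixture_ab.transcript.codon_sequence(944).bases == "CAA"  # Gln944


def test_codon_sequence_mutant_945(fixture_ab):
    mut = fixture_ab.transcript.apply_edit("2833", "A")
    ref = mut.codon_sequence(945)
    assert (ref.bases, ref.aa3) == ("AGA", "Arg")


def test_incomplete_codon_at_slice_edge(fixture_c):
    ref = fixture_c.transcript.codon_sequence(740)
    assert not ref.complete
    assert ref.aa1 is None
    assert "." in ref.bases
    with pytest.raises(OutOfModelError):
        fixture_c.transcript.codon_sequence(700)


def test_get_base_and_apply_edit(fixture_ab):
    t = fixture_ab.transcript
    mut = t.apply_edit("2843", "A")
    assert mut.get_base("2843") == "A"
    assert mut.get_base(CodingPosition(2843, -2)) == "A"  # acceptor-side adenine
    # write-then-read restores, and no other base moved
    back = mut.apply_edit("2843", "G")
    assert back.get_base("2843") == "G"
    assert back.genomic_sequence == t.genomic_sequence
    with pytest.raises(OutOfModelError):
        t.get_base("9999")


def test_genomic_window_spanning_junction(fixture_ab):
    mut = fixture_ab.transcript.apply_edit("2833", "A")
    seq, positions = mut.genomic_window("2833", 6, 20)
    assert seq == "CTTCAAAGATTTGAATgtaggtagagt"
    # positions 17-27 are intronic with + offsets from c.2842
    assert [str(p) for p in positions[16:]] == [f"2842+{k}" for k in range(1, 12)]
    assert all(p.is_exonic for p in positions[:16])


def test_genomic_window_reverse_complement_matches_printed_guide(fixture_c):
    mut = fixture_c.transcript.apply_edit("2234", "T")
    seq, _ = mut.genomic_window("2234", 15, 7)
    from bescreen import revcomp

    assert revcomp(seq).upper() == "TTGAAGCATTCGGACAAACATGG"


def test_genomic_window_empty_and_out_of_range(fixture_ab):
    t = fixture_ab.transcript
    assert t.genomic_window("2833", 0, -1) == ("", [])
    with pytest.raises(OutOfModelError):
        t.genomic_window("2833", 500, 0)


def test_window_coordinate_map_monotone(fixture_ab):
    """Coordinates increase in genomic order; offsets only off-exon."""
    t = fixture_ab.transcript
    coords = t.coordinates
    kinds = t.segment_kinds
    for a, b in zip(coords, coords[1:]):
        assert (a.base, a.intron_offset) < (b.base, b.intron_offset) or a.base < b.base
    for pos, kind in zip(coords, kinds):
        assert (kind == "exon") == pos.is_exonic


def test_case_insensitivity(fixture_ab):
    t = fixture_ab.transcript
    lowered = MiniTranscript(
        t.name,
        t.cds_start_coord,
        tuple(Segment(s.kind, s.sequence.swapcase(), s.non_canonical) for s in t.segments),
    )
    assert lowered.genomic_sequence.upper() == t.genomic_sequence.upper()
    assert lowered.get_base("2843") == t.get_base("2843")
    assert lowered.codon_sequence(948) == t.codon_sequence(948)


@pytest.mark.parametrize(
    "segments",
    [
        (Segment("exon", "ACGT"), Segment("exon", "ACGT")),  # no alternation
        (Segment("intron", "gtag"),),  # no exon
        (Segment("exon", "ACGT"), Segment("flank", "cc"), Segment("exon", "ACGT")),
    ],
)
def test_invalid_segment_layouts_rejected(segments):
    with pytest.raises(ValidationError):
        MiniTranscript("bad", 1, segments)


def test_non_canonical_intron_needs_flag():
    with pytest.raises(ValidationError):
        MiniTranscript("bad", 1, (Segment("exon", "AAA"), Segment("intron", "cccc"), Segment("exon", "AAA")))
    t = MiniTranscript(
        "ok",
        1,
        (Segment("exon", "AAA"), Segment("intron", "cccc", non_canonical=True), Segment("exon", "AAA")),
    )
    assert len(t) == 10


def test_config_roundtrip(tmp_path, fixture_ab):
    from bescreen import load_transcript, save_transcript

    t = fixture_ab.transcript
    path = str(tmp_path / "t.yaml")
    save_transcript(t, path)
    assert load_transcript(path) == t
    jpath = str(tmp_path / "t.json")
    save_transcript(t, jpath)
    assert load_transcript(jpath) == t


def test_fasta_import(tmp_path):
    fasta = tmp_path / "exon.fa"
    fasta.write_text(">slice\nCCATGTTTGTCCGAACGCTTCAA\n")
    t = MiniTranscript.from_fasta(str(fasta), cds_start_coord=2219)
    assert t.get_base("2234") == "C"
    assert t.codon_sequence(745).bases == "ACG"
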