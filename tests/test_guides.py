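"""Protospacer enumeration, availability matrix, and oracle equivalence."""

import pytest

from bescreen import (
    DomainError,
    Variant,
    classify_variant,
    enumerate_guides,
    iupac_match,
    plant_amenable_variant,
    random_transcript,
    scramble_pam,
    screen_matrix,
)
from bescreen.transcript import revcomp

from .helpers import brute_force_placements


def _only_strategy(variant):
    (s,) = classify_variant(variant.ref, variant.alt)
    return s


def test_kkh_guide_for_c2843(fixture_ab, registry):
    v = Variant.parse("c.2843G>A")
    kkh = registry.get_construct("KKH-nSaCas9-ABE8e")
    (g,) = enumerate_guides(fixture_ab.transcript, v, kkh, _only_strategy(v))
    assert g.protospacer == "TTAGATATTGCAAATGCTGTT"
    assert g.pam == "TTTAAT"
    assert g.target_window_position == 5
    assert g.strand == "forward"
    assert g.contains_intronic  # the first four bases are acceptor-side intron
    assert str(g.span[4]) == "2843"
    assert str(g.span[2]) == "2843-2"


def test_no_spcas9_guide_for_c2843(fixture_ab, registry):
    v = Variant.parse("c.2843G>A")
    sp = registry.get_construct("nSpCas9-ABE8e")
    assert enumerate_guides(fixture_ab.transcript, v, sp, _only_strategy(v)) == []


def test_sacas9_guide_for_c2833_extends_into_intron(fixture_ab, registry):
    v = Variant.parse("c.2833G>A")
    sa = registry.get_construct("nSaCas9-ABE8e")
    (g,) = enumerate_guides(fixture_ab.transcript, v, sa, _only_strategy(v))
    assert g.protospacer == "CTTCAAAGATTTGAATGTAGG"
    assert g.pam == "TAGAGT"  # fully intronic PAM
    assert g.target_window_position == 7
    assert [str(p) for p in g.span[16:]] == [f"2842+{k}" for k in range(1, 6)]


def test_reverse_strand_guide_for_c2234(fixture_c, registry):
    v = Variant.parse("c.2234C>T")
    sp = registry.get_construct("nSpCas9-ABE8e")
    (g,) = enumerate_guides(fixture_c.transcript, v, sp, _only_strategy(v))
    assert g.protospacer == "TTGAAGCATTCGGACAAACA"
    assert g.pam == "TGG"
    assert g.target_window_position == 8
    assert g.strand == "reverse"
    # strand coherence: the reverse-complemented protospacer equals the
    # forward genomic slice of its span
    mut = fixture_c.transcript.apply_edit("2234", "T")
    lo = mut.index_of(g.span[-1])
    hi = mut.index_of(g.span[0])
    assert revcomp(g.protospacer) == mut.genomic_sequence.upper()[lo:hi + 1]


def test_class_mismatch_rejected(fixture_ab, registry):
    v = Variant.parse("c.2843G>A")
    (cbe_strategy,) = classify_variant("T", "C")
    with pytest.raises(DomainError):
        enumerate_guides(
            fixture_ab.transcript, v, registry.get_construct("nSpCas9-ABE8e"), cbe_strategy
        )


def test_wrong_reference_base_rejected(fixture_ab, registry):
    v = Variant.parse("c.2843C>T")  # fixture carries G at c.2843
    with pytest.raises(DomainError):
        enumerate_guides(
            fixture_ab.transcript, v, registry.get_construct("KKH-nSaCas9-ABE8e"),
            _only_strategy(v),
        )


@pytest.mark.parametrize(
    "which,vlabel,expected",
    [
        ("AB", "c.2843G>A", {"nSpCas9-ABE8e": 0, "nSaCas9-ABE8e": 0,
                             "KKH-nSaCas9-ABE8e": 1, "CasMINI-ABE8e": 0}),
        ("AB", "c.2833G>A", {"nSpCas9-ABE8e": 0, "nSaCas9-ABE8e": 1,
                             "KKH-nSaCas9-ABE8e": 1, "CasMINI-ABE8e": 0}),
        ("C", "c.2234C>T", {"nSpCas9-ABE8e": 1, "nSaCas9-ABE8e": 0,
                            "KKH-nSaCas9-ABE8e": 0, "CasMINI-ABE8e": 0}),
    ],
)
def test_screen_matrix_counts(which, vlabel, expected, fixture_ab, fixture_c, registry):
    fx = fixture_ab if which == "AB" else fixture_c
    v = next(x for x in fx.variants if x.label == vlabel)
    m = screen_matrix(fx.transcript, v, registry)
    assert m.counts == expected


def test_candidate_invariants_on_fixtures(fixture_ab, fixture_c, registry):
    for fx in (fixture_ab, fixture_c):
        for v in fx.variants:
            m = screen_matrix(fx.transcript, v, registry)
            for name, guide in m.best.items():
                if guide is None:
                    continue
                c = registry.get_construct(name)
                (s,) = classify_variant(v.ref, v.alt)
                assert guide.protospacer[guide.target_window_position - 1] == \
                    s.mutant_base_on_target_strand
                assert c.window[0] <= guide.target_window_position <= c.window[1]
                assert iupac_match(c.pam_pattern, guide.pam)
                assert len(guide.protospacer) == c.spacer_length
                assert len(guide.span) == c.spacer_length


def test_enumeration_deterministic(fixture_ab, registry):
    v = next(x for x in fixture_ab.variants if x.label == "c.2833G>A")
    a = screen_matrix(fixture_ab.transcript, v, registry)
    b = screen_matrix(fixture_ab.transcript, v, registry)
    assert a.counts == b.counts
    assert a.best == b.best


@pytest.mark.parametrize("seed", range(10))
def test_brute_force_scanner_equivalence_random(seed, registry):
    """Placement-based enumeration equals an independent sliding-window
    scan of the whole sequence, on random junction-bearing transcripts."""
    t = random_transcript(3, (60, 120), (30, 60), gc=0.45, seed=seed)
    # pick a G somewhere exonic and make it a G>A variant
    coords, kinds = t.coordinates, t.segment_kinds
    pos = next(
        c for c, k in zip(coords, kinds)
        if k == "exon" and t.get_base(c) == "G" and c.base > 30
    )
    v = Variant(pos, "G", "A", t.name)
    (s,) = classify_variant("G", "A")
    for construct in registry.values():
        got = enumerate_guides(t, v, construct, s)
        expected = brute_force_placements(t, v, construct, s.target_strand)
        assert sorted((g.protospacer, g.pam, g.target_window_position) for g in got) == \
            sorted(expected)


def test_brute_force_equivalence_on_fixtures(fixture_ab, fixture_c, registry):
    for fx in (fixture_ab, fixture_c):
        for v in fx.variants:
            (s,) = classify_variant(v.ref, v.alt)
            for construct in registry.values():
                if construct.editor_class != s.editor_class:
                    continue
                got = enumerate_guides(fx.transcript, v, construct, s)
                expected = brute_force_placements(fx.transcript, v, construct, s.target_strand)
                assert sorted((g.protospacer, g.pam, g.target_window_position) for g in got) \
                    == sorted(expected)


@pytest.mark.parametrize("construct_name", [
    "nSpCas9-ABE8e", "nSaCas9-ABE8e", "KKH-nSaCas9-ABE8e", "CasMINI-ABE8e",
])
def test_planted_guide_recovery_and_scramble(construct_name, registry):
    construct = registry.get_construct(construct_name)
    for seed in range(5):
        t = random_transcript(2, (80, 120), (30, 50), gc=0.4, seed=1000 + seed)
        case = plant_amenable_variant(t, construct, "ABE", seed=seed)
        guides = enumerate_guides(case.transcript, case.variant, construct, case.strategy)
        assert any(
            g.target_window_position == case.expected_target_position
            and g.strand == case.strand
            for g in guides
        )
        denied = scramble_pam(case, construct)
        guides2 = enumerate_guides(denied.transcript, denied.variant, construct, denied.strategy)
        assert not any(
            g.target_window_position == case.expected_target_position
            and g.strand == case.strand
            for g in guides2
        )
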