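"""Stage 3: bystander edits inside the editing window and their consequences.

Every substrate base in the editing window other than the therapeutic
target is a potential bystander edit.  Each is annotated at the c. level
(always rendered on the coding strand), at the codon/protein level for
exonic bases, and at the splice level for intronic ones: offsets +-1/+-2
hit the canonical gt/ag dinucleotides (canonical_splice), +-3..+-8 the
splice region, anything deeper is plain intronic.

Because the deaminase acts on every substrate base in the window with
some probability, edits combine: per affected codon the full 2^k on/off
combination space is enumerated (the target edit counted as a free
choice), yielding outcome sets such as Gln944 -> {Gln, Arg}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

from .editors import EditorConstruct
from .errors import DomainError
from .guides import GuideCandidate
from .transcript import (
    CodingPosition,
    MiniTranscript,
    Variant,
    aa_three,
    c_to_codon,
    complement,
    translate,
)

logger = logging.getLogger("bescreen")

SPLICE_REGION_MAX_OFFSET = 8  # |offset| 3..8 -> splice_region; beyond -> intronic

_CODING_CLASSES = ("silent", "missense", "nonsense", "start_loss")
_NONCODING_CLASSES = ("canonical_splice", "splice_region", "intronic", "incomplete_codon")


@dataclass(frozen=True)
class BystanderEdit:
    """One non-target editable base in the window, with its consequence."""

    window_position: int
    coding_pos: CodingPosition
    c_label: str  # e.g. "c.2843-2A>G", coding-strand alleles
    consequence_class: str
    p_label: str  # e.g. "p.Ile949Val"; empty for non-coding classes

    @property
    def label(self) -> str:
        """Protein-level label when available, else the c. label."""
        return self.p_label or self.c_label


@dataclass(frozen=True)
class CodonOutcomeSet:
    """Amino acids reachable in one codon across all edit combinations."""

    codon_index: int
    wt_aa: str  # one-letter
    outcome_aas: tuple[str, ...]  # distinct, alphabetical
    label: str  # e.g. "p.Q944Q/R"


@dataclass(frozen=True)
class BystanderReport:
    """Bystander edits of one guide plus per-codon outcome summary."""

    edits: tuple[BystanderEdit, ...]  # ordered by window position
    codon_outcomes: tuple[CodonOutcomeSet, ...]
    target_restores_wt: bool


def editable_positions(
    guide: GuideCandidate, construct: EditorConstruct
) -> tuple[int, list[int]]:
    """Window positions whose targeted-strand base is the substrate base.

    Returns ``(target_position, bystander_positions)``; the target is the
    variant's own position and is excluded from the bystander list.
    """
    substrate = construct.conversion[0]
    tp = guide.target_window_position
    if guide.protospacer[tp - 1] != substrate:
        raise DomainError(
            f"guide target base {guide.protospacer[tp - 1]!r} at position {tp} is not "
            f"the {construct.name} substrate {substrate!r}"
        )
    lo, hi = construct.window
    bystanders = [
        p for p in range(lo, hi + 1)
        if p != tp and guide.protospacer[p - 1] == substrate
    ]
    return tp, bystanders


def _coding_strand_change(strand: str, conversion: tuple[str, str]) -> tuple[str, str]:
    """Project an on-strand conversion onto the coding strand."""
    if strand == "forward":
        return conversion
    return complement(conversion[0]), complement(conversion[1])


def annotate_edit(
    t: MiniTranscript,
    coding_pos: CodingPosition,
    strand: str,
    conversion: tuple[str, str] = ("A", "G"),
    window_position: int = 0,
) -> BystanderEdit:
    """Consequence of editing one base, evaluated on the given transcript.

    ``t`` is the baseline against which codon changes are compared; for
    bystander reporting this is the wild-type transcript (i.e. the
    consequence assuming the therapeutic target is corrected).
    """
    ref_c, alt_c = _coding_strand_change(strand, conversion)
    have = t.get_base(coding_pos)
    if have != ref_c:
        raise DomainError(
            f"base at c.{coding_pos} is {have}, not the expected substrate "
            f"{ref_c} (coding strand)"
        )
    c_label = f"c.{coding_pos}{ref_c}>{alt_c}"
    kind = t.kind_at(coding_pos)

    if not coding_pos.is_exonic or kind != "exon":
        off = abs(coding_pos.intron_offset)
        if kind == "intron" and off <= 2:
            cls = "canonical_splice"
        elif kind == "intron" and off <= SPLICE_REGION_MAX_OFFSET:
            cls = "splice_region"
        else:
            cls = "intronic"
        return BystanderEdit(window_position, coding_pos, c_label, cls, "")

    codon_index, frame = c_to_codon(coding_pos.base)
    ref_codon = t.codon_sequence(codon_index, frame)
    if not ref_codon.complete:
        logger.warning(
            "codon %d is incomplete in the modeled slice of %r; consequence of "
            "%s not classified", codon_index, t.name, c_label,
        )
        return BystanderEdit(window_position, coding_pos, c_label, "incomplete_codon", "")
    bases = list(ref_codon.bases)
    bases[frame - 1] = alt_c
    new_aa = translate("".join(bases))
    wt_aa = ref_codon.aa1
    assert wt_aa is not None
    if new_aa == wt_aa:
        cls = "silent"
    elif new_aa == "*":
        cls = "nonsense"
    elif codon_index == 1 and wt_aa == "M":
        cls = "start_loss"
    else:
        cls = "missense"
    p_label = f"p.{aa_three(wt_aa)}{codon_index}{aa_three(new_aa)}"
    return BystanderEdit(window_position, coding_pos, c_label, cls, p_label)


def codon_outcomes(
    t: MiniTranscript,
    guide: GuideCandidate,
    construct: EditorConstruct,
    variant: Optional[Variant] = None,
) -> list[CodonOutcomeSet]:
    """Combinatorial amino-acid outcomes per codon touched by a bystander.

    ``t`` is the wild-type transcript; edits are applied to the mutant
    allele (the sequence the editor actually sees).  For each codon
    containing at least one bystander substrate, all 2^k on/off subsets
    of its editable bases — the target edit included as a free choice —
    are translated; codons whose only reachable outcome is the wild-type
    amino acid are omitted.  Outcomes are ordered alphabetically.
    """
    mutant = t.apply_edit(variant.position, variant.alt) if variant is not None else t
    target_p, bystander_ps = editable_positions(guide, construct)
    _, alt_on_strand = construct.conversion
    ref_c, alt_c = _coding_strand_change(guide.strand, construct.conversion)

    # group exonic editable positions by codon
    by_codon: dict[int, list[tuple[int, CodingPosition]]] = {}
    has_bystander: set[int] = set()
    for p in [target_p] + bystander_ps:
        cpos = guide.span[p - 1]
        if not cpos.is_exonic or mutant.kind_at(cpos) != "exon":
            continue
        idx, _ = c_to_codon(cpos.base)
        if not mutant.codon_sequence(idx).complete:
            logger.warning(
                "codon %d incomplete in %r; omitted from outcome summary", idx, t.name
            )
            continue
        by_codon.setdefault(idx, []).append((p, cpos))
        if p != target_p:
            has_bystander.add(idx)

    out: list[CodonOutcomeSet] = []
    for idx in sorted(has_bystander):
        edits = by_codon[idx]
        wt_ref = t.codon_sequence(idx)
        assert wt_ref.complete and wt_ref.aa1 is not None
        mut_bases = list(mutant.codon_sequence(idx).bases)
        start = 3 * idx - 2
        outcomes: set[str] = set()
        positions = [cpos for _, cpos in edits]
        for r in range(len(positions) + 1):
            for subset in combinations(positions, r):
                bases = list(mut_bases)
                for cpos in subset:
                    bases[cpos.base - start] = alt_c
                outcomes.add(translate("".join(bases)))
        if outcomes == {wt_ref.aa1}:
            continue
        ordered = tuple(sorted(outcomes))
        label = f"p.{wt_ref.aa1}{idx}" + "/".join(ordered)
        out.append(CodonOutcomeSet(idx, wt_ref.aa1, ordered, label))
    return out


def bystander_report(
    t: MiniTranscript,
    guide: GuideCandidate,
    construct: EditorConstruct,
    variant: Variant,
) -> BystanderReport:
    """Full bystander annotation of one guide.

    Single-edit consequences are evaluated on the wild-type background
    (target assumed corrected); the codon outcome summary enumerates edit
    combinations on the mutant allele.  Also verifies that editing the
    target alone restores the wild-type base — and, where the codon is
    fully modeled, the wild-type amino acid.
    """
    target_p, bystander_ps = editable_positions(guide, construct)
    edits = tuple(
        annotate_edit(t, guide.span[p - 1], guide.strand, construct.conversion, p)
        for p in bystander_ps
    )
    outcomes = tuple(codon_outcomes(t, guide, construct, variant))

    # target restoration: conversion applied to the mutant allele must give
    # back the wild-type base (and amino acid, when the codon is modeled)
    ref_c, alt_c = _coding_strand_change(guide.strand, construct.conversion)
    restores = alt_c == variant.ref and t.get_base(variant.position) == variant.ref
    if restores and variant.position.is_exonic:
        idx, _ = c_to_codon(variant.position.base)
        wt_codon = t.codon_sequence(idx)
        if wt_codon.complete:
            mutant = t.apply_edit(variant.position, variant.alt)
            corrected = mutant.apply_edit(variant.position, alt_c)
            restores = corrected.codon_sequence(idx).aa1 == wt_codon.aa1
    return BystanderReport(edits, outcomes, restores)
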