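"""Stage 2: enumerate protospacer placements with a matching PAM.

For each position of the editing window, the protospacer is slid along
the *genomically contiguous* mutant sequence (placements may run from an
exon into an intron) so that the variant base sits at that window
position on the targeted strand; a candidate is emitted iff the
immediately adjacent PAM matches the construct's degenerate pattern.

Placements are confined to the exon/intron model proper: flank segments
stand for unknown context, so a protospacer or PAM that would overlap a
flank (or fall off the modeled slice entirely) is skipped with a warning
rather than partially matched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .amenability import EditStrategy, classify_variant
from .editors import EditorConstruct, Registry, iupac_match
from .errors import DomainError
from .transcript import CodingPosition, MiniTranscript, Variant

logger = logging.getLogger("bescreen")


@dataclass(frozen=True)
class GuideCandidate:
    """One protospacer placement for one construct.

    ``protospacer`` and ``pam`` are given 5'->3' on the targeted strand
    with the mutant allele included; ``span`` maps protospacer positions
    (index 0 = position 1) to coding coordinates of the base each position
    pairs with.
    """

    construct_name: str
    strand: str  # forward | reverse
    protospacer: str
    pam: str
    target_window_position: int
    span: tuple[CodingPosition, ...]
    contains_intronic: bool

    def __str__(self) -> str:
        return (
            f"{self.construct_name} [{self.strand}] {self.protospacer}+{self.pam} "
            f"(target at {self.target_window_position})"
        )


def _targeted_view(t: MiniTranscript, strand: str):
    """Sequence, per-base coordinates and kinds in targeted-strand order."""
    from .transcript import revcomp

    seq = t.genomic_sequence.upper()
    coords = t.coordinates
    kinds = t.segment_kinds
    if strand == "reverse":
        return revcomp(seq), tuple(reversed(coords)), tuple(reversed(kinds))
    return seq, coords, kinds


def enumerate_guides(
    t: MiniTranscript,
    variant: Variant,
    construct: EditorConstruct,
    strategy: EditStrategy,
) -> list[GuideCandidate]:
    """All placements of ``construct`` that put the variant in its window.

    The search runs on the mutant sequence (the editable substrate is the
    pathogenic allele).  Candidates are ordered by window centrality
    (|position - window midpoint|), ties broken 5'-most first; the order
    is deterministic.
    """
    if construct.editor_class != strategy.editor_class:
        raise DomainError(
            f"construct {construct.name} ({construct.editor_class}) cannot implement "
            f"a {strategy.editor_class} strategy"
        )
    if t.get_base(variant.position) != variant.ref:
        raise DomainError(
            f"transcript {t.name!r} carries {t.get_base(variant.position)} at "
            f"c.{variant.position}, expected ref {variant.ref}"
        )
    mutant = t.apply_edit(variant.position, variant.alt)
    seq, coords, kinds = _targeted_view(mutant, strategy.target_strand)
    n = len(seq)
    tgt_idx = mutant.index_of(variant.position)
    if strategy.target_strand == "reverse":
        tgt_idx = n - 1 - tgt_idx
    assert seq[tgt_idx] == strategy.mutant_base_on_target_strand, (
        "internal error: mutant base on targeted strand does not match strategy"
    )

    L = construct.spacer_length
    P = construct.pam_length
    lo, hi = construct.window
    out: list[GuideCandidate] = []
    for p in range(lo, hi + 1):
        start = tgt_idx - (p - 1)
        end = start + L - 1
        if construct.pam_side == "3prime":
            pam_lo, pam_hi = end + 1, end + P
        else:
            pam_lo, pam_hi = start - P, start - 1
        full_lo, full_hi = min(start, pam_lo), max(end, pam_hi)
        if full_lo < 0 or full_hi >= n:
            logger.warning(
                "%s: placement with target at window position %d exceeds the "
                "modeled slice of %r; skipped",
                construct.name, p, t.name,
            )
            continue
        if any(kinds[i] == "flank" for i in range(full_lo, full_hi + 1)):
            logger.warning(
                "%s: placement with target at window position %d overlaps unknown "
                "flank sequence of %r; skipped",
                construct.name, p, t.name,
            )
            continue
        pam = seq[pam_lo:pam_hi + 1]
        if not iupac_match(construct.pam_pattern, pam):
            continue
        span = tuple(coords[start:end + 1])
        out.append(
            GuideCandidate(
                construct_name=construct.name,
                strand=strategy.target_strand,
                protospacer=seq[start:end + 1],
                pam=pam,
                target_window_position=p,
                span=span,
                contains_intronic=any(not c.is_exonic for c in span),
            )
        )
    mid = (lo + hi) / 2
    out.sort(key=lambda g: (abs(g.target_window_position - mid), g.target_window_position))
    return out


@dataclass(frozen=True)
class ScreenMatrix:
    """Per-construct availability for one variant."""

    variant: Variant
    strategies: tuple[EditStrategy, ...]
    counts: dict[str, int]
    best: dict[str, Optional[GuideCandidate]]

    @property
    def available(self) -> list[str]:
        """Construct names with at least one candidate, registry order."""
        return [name for name, c in self.counts.items() if c > 0]


def screen_matrix(
    t: MiniTranscript,
    variant: Variant,
    constructs: Registry | Sequence[EditorConstruct],
) -> ScreenMatrix:
    """Candidate counts and best candidate per construct for one variant.

    Constructs whose editor class does not match any strategy for the
    substitution score zero.  Rows are reproducible across runs.
    """
    if hasattr(constructs, "values"):
        constructs = list(constructs.values())  # type: ignore[union-attr]
    strategies = classify_variant(variant.ref, variant.alt)
    counts: dict[str, int] = {}
    best: dict[str, Optional[GuideCandidate]] = {}
    for construct in constructs:
        cands: list[GuideCandidate] = []
        for strat in strategies:
            if strat.editor_class == construct.editor_class:
                cands = enumerate_guides(t, variant, construct, strat)
                break
        counts[construct.name] = len(cands)
        best[construct.name] = cands[0] if cands else None
    return ScreenMatrix(variant, tuple(strategies), counts, best)
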