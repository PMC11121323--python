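"""Reference fixtures and synthetic transcript/variant generators.

Two kinds of test substrate live here:

* :func:`fixture_AB` and :func:`fixture_C` reconstruct the two CRB1
  mini-loci on which the three worked case variants (c.2843G>A,
  c.2833G>A, c.2234C>T) sit, from their published protospacer+PAM
  context.  Unknown filler sequence is chosen so it cannot complete any
  registry PAM at the inspected offsets; flanks mark unknown context
  beyond the slice.
* :func:`random_transcript` and :func:`plant_amenable_variant` generate
  seed-deterministic junction-bearing transcripts with constructively
  planted (or denied, via :func:`scramble_pam`) guide placements whose
  ground truth is known at planting time, independently of the pipeline
  under test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .amenability import AMENABILITY_TABLE, EditStrategy, classify_variant
from .editors import IUPAC_SETS, EditorConstruct
from .errors import DomainError
from .transcript import (
    CodingPosition,
    MiniTranscript,
    Segment,
    Variant,
    complement,
)

# ---------------------------------------------------------------------------
# reference fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fixture:
    """A wild-type mini-locus plus the case variants it carries."""

    transcript: MiniTranscript
    variants: tuple[Variant, ...]


def fixture_AB() -> Fixture:
    """Two-exon CRB1 mini-locus carrying c.2833G>A and c.2843G>A (wild type).

    Exon A spans c.2827-c.2842 (codon 943 starts at c.2827), a short
    intron with canonical gt..ag follows, and exon B spans c.2843-c.2865.
    The intron interior and the flanks are filler (``c``/``cag`` repeats)
    chosen so they complete no registry PAM; the intron boundary sequences
    (``gtaggtagagt`` donor side, ``ttag`` acceptor side) are fixed by the
    published guide context.
    """
    t = MiniTranscript(
        name="CRB1-mini-AB",
        cds_start_coord=2827,
        segments=(
            Segment("flank", "cagcagcag"),
            Segment("exon", "CTTCAAGGATTTGAAT"),
            Segment("intron", "gtaggtagagt" + "cctcctcc" + "ttag"),
            Segment("exon", "GTATTGCAAATGCTGTTTTTAAT"),
            Segment("flank", "cccccc"),
        ),
    )
    return Fixture(
        transcript=t,
        variants=(
            Variant.parse("c.2833G>A", t.name),
            Variant.parse("c.2843G>A", t.name),
        ),
    )


def fixture_C() -> Fixture:
    """Single-exon CRB1 mini-locus carrying c.2234C>T (wild type).

    The exon spans c.2219-c.2241 in coding orientation; the reverse
    complement of its mutant allele is the published reverse-strand
    protospacer+PAM.  Codons 740 and 748 are truncated at the slice edges
    and flagged incomplete.
    """
    t = MiniTranscript(
        name="CRB1-mini-C",
        cds_start_coord=2219,
        segments=(
            Segment("flank", "cccccc"),
            Segment("exon", "CCATGTTTGTCCGAACGCTTCAA"),
            Segment("flank", "cccccc"),
        ),
    )
    return Fixture(transcript=t, variants=(Variant.parse("c.2234C>T", t.name),))


def fixtures() -> dict[str, Fixture]:
    """All bundled fixtures by transcript name."""
    fab, fc = fixture_AB(), fixture_C()
    return {fab.transcript.name: fab, fc.transcript.name: fc}


# ---------------------------------------------------------------------------
# random transcripts
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def random_transcript(
    n_exons: int,
    exon_len_range: tuple[int, int] = (60, 120),
    intron_len_range: tuple[int, int] = (30, 60),
    gc: float = 0.4,
    seed: int = 0,
    cds_start_coord: int = 1,
    name: Optional[str] = None,
) -> MiniTranscript:
    """Seed-deterministic random transcript with canonical gt..ag introns."""
    if n_exons < 1:
        raise DomainError("need at least one exon")
    if not (0.0 <= gc <= 1.0):
        raise DomainError(f"gc must be in [0, 1], got {gc}")
    for lo, hi in (exon_len_range, intron_len_range):
        if lo < 1 or hi < lo:
            raise DomainError(f"invalid length range ({lo}, {hi})")
    if n_exons > 1 and intron_len_range[0] < 4:
        raise DomainError("introns need length >= 4 for gt..ag dinucleotides")
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    for i in range(n_exons):
        if i > 0:
            ilen = int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
            interior = _random_seq(rng, ilen - 4, gc) if ilen > 4 else ""
            segments.append(Segment("intron", ("gt" + interior + "ag").lower()))
        elen = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
        segments.append(Segment("exon", _random_seq(rng, elen, gc)))
    return MiniTranscript(
        name=name or f"random-{seed}",
        cds_start_coord=cds_start_coord,
        segments=tuple(segments),
    )


# ---------------------------------------------------------------------------
# planted cases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedCase:
    """A transcript with a constructively planted (or denied) guide.

    Ground truth (`construct_name`, `strand`,
    `expected_target_position`) is recorded at planting time, never by
    running the enumeration under test.
    """

    transcript: MiniTranscript  # wild type, PAM installed
    variant: Variant
    strategy: EditStrategy
    construct_name: str
    strand: str
    expected_target_position: int
    expected_none: bool
    seed: int


def _with_genomic_bases(t: MiniTranscript, edits: dict[int, str]) -> MiniTranscript:
    """Rebuild a transcript with bases replaced at genomic indices."""
    genome = list(t.genomic_sequence)
    for idx, base in edits.items():
        genome[idx] = base.upper() if genome[idx].isupper() else base.lower()
    segments: list[Segment] = []
    at = 0
    for s in t.segments:
        seq = "".join(genome[at:at + len(s.sequence)])
        non_canonical = s.non_canonical
        if s.kind == "intron" and not non_canonical:
            low = seq.lower()
            # a planted PAM may legitimately clobber a splice dinucleotide
            non_canonical = not (low.startswith("gt") and low.endswith("ag"))
        segments.append(Segment(s.kind, seq, non_canonical))
        at += len(s.sequence)
    return MiniTranscript(t.name, t.cds_start_coord, tuple(segments))


def _concrete_pam(rng: np.random.Generator, pattern: str) -> str:
    return "".join(rng.choice(sorted(IUPAC_SETS[p])) for p in pattern.upper())


def plant_amenable_variant(
    t: MiniTranscript,
    construct: EditorConstruct,
    strategy_class: str = "ABE",
    seed: int = 0,
) -> PlantedCase:
    """Install a variant plus a matching PAM with known ground truth.

    Picks an exonic target safely inside the modeled slice, installs a
    wild-type allele whose substitution is amenable to ``strategy_class``
    on a randomly chosen strand, chooses a window position, and overwrites
    the PAM-adjacent sequence with a concrete PAM drawn from the
    construct's pattern.  The planted placement is then guaranteed to
    exist; whether enumeration finds it is for the caller to test.
    """
    rng = np.random.default_rng(seed)
    subs = [(ra, strand) for ra, (cls, strand) in AMENABILITY_TABLE.items() if cls == strategy_class]
    if not subs:
        raise DomainError(f"unknown editor class {strategy_class!r}")
    if strategy_class != construct.editor_class:
        raise DomainError(
            f"{construct.name} is {construct.editor_class}, cannot plant {strategy_class}"
        )
    (ref, alt), strand = subs[int(rng.integers(len(subs)))]

    L, P = construct.spacer_length, construct.pam_length
    lo, hi = construct.window
    p = int(rng.integers(lo, hi + 1))

    kinds = t.segment_kinds
    n = len(t)
    # candidate genomic indices (coding orientation) for the target base
    candidates = []
    for idx in range(n):
        if kinds[idx] != "exon":
            continue
        sidx = idx if strand == "forward" else n - 1 - idx  # targeted-strand index
        start = sidx - (p - 1)
        end = start + L - 1
        pam_lo = end + 1 if construct.pam_side == "3prime" else start - P
        pam_hi = pam_lo + P - 1
        flo, fhi = min(start, pam_lo), max(end, pam_hi)
        if flo < 0 or fhi >= n:
            continue
        if strand == "forward":
            span = range(flo, fhi + 1)
        else:
            span = range(n - 1 - fhi, n - flo)  # mirrored back to genomic order
        if any(kinds[i] == "flank" for i in span):
            continue
        candidates.append(idx)
    if not candidates:
        raise DomainError(
            f"transcript {t.name!r} too short to plant a {construct.name} placement"
        )
    tgt = int(candidates[int(rng.integers(len(candidates)))])

    edits = {tgt: ref}  # install the wild-type allele at the target
    # install a concrete PAM adjacent to the protospacer on the targeted strand
    pam = _concrete_pam(rng, construct.pam_pattern)
    sidx = tgt if strand == "forward" else n - 1 - tgt
    start = sidx - (p - 1)
    end = start + L - 1
    pam_lo = end + 1 if construct.pam_side == "3prime" else start - P
    for k, base in enumerate(pam):
        si = pam_lo + k
        gi = si if strand == "forward" else n - 1 - si
        edits[gi] = base if strand == "forward" else complement(base)
    planted = _with_genomic_bases(t, edits)

    variant = Variant(planted.coordinates[tgt], ref, alt, planted.name)
    (strategy,) = classify_variant(ref, alt)
    assert strategy.target_strand == strand
    return PlantedCase(
        transcript=planted,
        variant=variant,
        strategy=strategy,
        construct_name=construct.name,
        strand=strand,
        expected_target_position=p,
        expected_none=False,
        seed=seed,
    )


def scramble_pam(case: PlantedCase, construct: EditorConstruct) -> PlantedCase:
    """Replace the planted PAM with a non-matching string.

    Every constrained (non-N) PAM position is overwritten with a base the
    pattern disallows, so the planted placement can no longer match.
    """
    t = case.transcript
    n = len(t)
    tgt = t.index_of(case.variant.position)
    sidx = tgt if case.strand == "forward" else n - 1 - tgt
    start = sidx - (case.expected_target_position - 1)
    L, P = construct.spacer_length, construct.pam_length
    pam_lo = start + L if construct.pam_side == "3prime" else start - P

    edits: dict[int, str] = {}
    scrambled_any = False
    for k, letter in enumerate(construct.pam_pattern.upper()):
        disallowed = sorted(set("ACGT") - IUPAC_SETS[letter])
        if not disallowed:
            continue  # N position: any base matches, nothing to deny
        si = pam_lo + k
        gi = si if case.strand == "forward" else n - 1 - si
        edits[gi] = disallowed[0] if case.strand == "forward" else complement(disallowed[0])
        scrambled_any = True
    if not scrambled_any:
        raise DomainError(
            f"PAM pattern {construct.pam_pattern!r} is all-N and cannot be denied"
        )
    return replace(
        case, transcript=_with_genomic_bases(t, edits), expected_none=True
    )
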