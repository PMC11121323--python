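"""Junction-aware mini-transcript model with HGVS-style coding coordinates.

A :class:`MiniTranscript` models a genomically contiguous slice of a
protein-coding gene as an ordered run of segments — exons, introns, and
optional unknown "flank" padding at the two ends — all stored in coding
orientation.  Exonic bases carry ordinary CDS coordinates (``c.2843``);
intronic bases are addressed HGVS-style relative to the nearest exonic base
(``c.2842+5``, ``c.2843-2``).  The model is deliberately minimal: it knows
nothing about UTRs, genome builds, or full-length transcripts, but it is
sufficient to reason about codon frames, splice dinucleotides, and
genomically contiguous protospacer placements that may run from an exon
into an intron.

Case of the stored sequence is presentation only (exons render uppercase,
introns/flanks lowercase); every computation is case-insensitive.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterator, Literal, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .errors import DomainError, OutOfModelError, ParseError, ValidationError

SegmentKind = Literal["exon", "intron", "flank"]

_DNA = set("ACGT")
_IUPAC_DNA = set("ACGTRYSWKMBDHVN")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# ---------------------------------------------------------------------------
# sequence primitives
# ---------------------------------------------------------------------------


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string; tolerates IUPAC ambiguity codes.

    Case is preserved per character (an involution:
    ``revcomp(revcomp(s)) == s``).
    """
    bad = set(seq.upper()) - _IUPAC_DNA
    if bad:
        raise ParseError(f"non-nucleotide character(s) in sequence: {sorted(bad)}")
    return str(Seq(seq).reverse_complement())


def complement(base: str) -> str:
    """Complement of a single base, case preserved."""
    if len(base) != 1 or base.upper() not in _DNA:
        raise ParseError(f"not a single ACGT base: {base!r}")
    return base.translate(_COMPLEMENT)


def translate(codon: str) -> str:
    """Translate one codon with the standard nuclear genetic code.

    Returns the one-letter amino acid (``*`` for a stop codon).
    """
    if len(codon) != 3 or set(codon.upper()) - _DNA:
        raise ParseError(f"not a 3-base ACGT codon: {codon!r}")
    return str(Seq(codon.upper()).translate())


def aa_three(one_letter: str) -> str:
    """Three-letter amino acid name for a one-letter code (``*`` -> ``Ter``)."""
    return seq3(one_letter)


def c_to_codon(pos: int) -> tuple[int, int]:
    """Map a CDS coordinate to (codon index, frame).

    Frame is the 1-based position of the base within its codon:
    codon ``ceil(pos / 3)``, frame ``((pos - 1) mod 3) + 1``.
    """
    if pos < 1:
        raise DomainError(f"CDS coordinate must be >= 1, got {pos}")
    return math.ceil(pos / 3), (pos - 1) % 3 + 1


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

_C_POS_RE = re.compile(r"^(\d+)([+-]\d+)?$")


@dataclass(frozen=True, order=True)
class CodingPosition:
    """An HGVS-style c. coordinate: exonic base plus optional intron offset.

    ``intron_offset == 0`` means the position is exonic; a negative offset
    addresses bases upstream of ``base`` in the preceding intron
    (``2843-2``), a positive one bases downstream of ``base`` in the
    following intron (``2842+5``).
    """

    base: int
    intron_offset: int = 0

    def __post_init__(self) -> None:
        if self.base < 1:
            raise DomainError(f"CDS coordinate must be >= 1, got {self.base}")

    @property
    def is_exonic(self) -> bool:
        return self.intron_offset == 0

    def __str__(self) -> str:
        if self.intron_offset == 0:
            return str(self.base)
        sign = "+" if self.intron_offset > 0 else "-"
        return f"{self.base}{sign}{abs(self.intron_offset)}"

    @classmethod
    def parse(cls, text: str) -> "CodingPosition":
        """Parse ``"2843"``, ``"2843-2"``, or ``"100+1"``."""
        m = _C_POS_RE.match(text.strip())
        if not m:
            raise ParseError(f"malformed coding position: {text!r}")
        return cls(int(m.group(1)), int(m.group(2) or 0))


def parse_c_position(text: str) -> CodingPosition:
    """Parse an HGVS-style coding position string (``c.`` prefix optional)."""
    return CodingPosition.parse(text.removeprefix("c."))


@dataclass(frozen=True)
class CodonRef:
    """One codon of the modeled CDS.

    ``bases`` holds the three bases in coding order (codons may span an
    exon–exon junction); incomplete codons at the edges of the modeled
    slice use ``.`` for missing bases and carry no amino acid.
    """

    index: int
    bases: str
    complete: bool
    aa1: Optional[str]
    aa3: Optional[str]
    frame: Optional[int] = None  # frame of the base this ref was derived from


_VARIANT_RE = re.compile(r"^c\.(\d+(?:[+-]\d+)?)([ACGTacgt])>([ACGTacgt])$")


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant in CDS coordinates (coding strand)."""

    position: CodingPosition
    ref: str
    alt: str
    transcript_name: str = ""

    def __post_init__(self) -> None:
        ref, alt = self.ref.upper(), self.alt.upper()
        if ref not in _DNA or alt not in _DNA:
            raise DomainError(f"ref/alt must be single ACGT bases: {self.ref!r}>{self.alt!r}")
        if ref == alt:
            raise DomainError(f"ref and alt are identical: {ref}")
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)

    @property
    def label(self) -> str:
        return f"c.{self.position}{self.ref}>{self.alt}"

    @classmethod
    def parse(cls, text: str, transcript_name: str = "") -> "Variant":
        m = _VARIANT_RE.match(text.strip())
        if not m:
            raise ParseError(f"malformed variant label: {text!r}")
        return cls(CodingPosition.parse(m.group(1)), m.group(2), m.group(3), transcript_name)


# ---------------------------------------------------------------------------
# transcript model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """One exon, intron, or flank with its sequence in coding orientation.

    Flank segments stand in for *unknown* context beyond the modeled
    exon/intron slice: they are addressable (for windows and display) but
    guide placements never rely on them.
    """

    kind: SegmentKind
    sequence: str
    non_canonical: bool = False  # intron lacking gt..ag, declared explicitly

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron", "flank"):
            raise ValidationError(f"unknown segment kind {self.kind!r}")
        if not self.sequence:
            raise ValidationError("empty segment sequence")
        bad = set(self.sequence.upper()) - _DNA
        if bad:
            raise ValidationError(f"segment has non-ACGT characters: {sorted(bad)}")
        if self.kind == "intron" and not self.non_canonical:
            s = self.sequence.lower()
            if len(s) < 4 or not (s.startswith("gt") and s.endswith("ag")):
                raise ValidationError(
                    "intron lacks canonical gt..ag splice dinucleotides "
                    "(set non_canonical=True to allow)"
                )


@dataclass(frozen=True)
class _Layout:
    genome: str                     # presentation case: exon upper, intron/flank lower
    genome_upper: str
    positions: tuple[CodingPosition, ...]
    kinds: tuple[str, ...]
    pos_to_idx: dict[CodingPosition, int]
    cds_first: int
    cds_last: int


@dataclass(frozen=True)
class MiniTranscript:
    """A contiguous genomic slice of a coding transcript.

    Parameters
    ----------
    name:
        Free-text identifier.
    cds_start_coord:
        The CDS c. coordinate of the first base of the first exon segment.
    segments:
        Ordered segments in coding orientation.  Exons alternate with
        introns; flanks may appear only at the two ends, adjacent to an
        exon.  Exon coding coordinates are contiguous across introns.
    """

    name: str
    cds_start_coord: int
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = tuple(
            s if isinstance(s, Segment) else Segment(**s)  # type: ignore[arg-type]
            for s in self.segments
        )
        object.__setattr__(self, "segments", segs)
        if self.cds_start_coord < 1:
            raise ValidationError("cds_start_coord must be >= 1")
        core = [s.kind for s in segs if s.kind != "flank"]
        if not core or core[0] != "exon" or core[-1] != "exon":
            raise ValidationError("model must start and end (ignoring flanks) with an exon")
        for a, b in zip(core, core[1:]):
            if a == b:
                raise ValidationError("exon and intron segments must alternate")
        for i, s in enumerate(segs):
            if s.kind == "flank" and i not in (0, len(segs) - 1):
                raise ValidationError("flank segments may only appear at the two ends")
        if segs[0].kind == "flank" and len(segs) > 1 and segs[1].kind != "exon":
            raise ValidationError("a leading flank must be adjacent to an exon")
        if segs[-1].kind == "flank" and len(segs) > 1 and segs[-2].kind != "exon":
            raise ValidationError("a trailing flank must be adjacent to an exon")

    # -- layout -------------------------------------------------------------

    @cached_property
    def _layout(self) -> _Layout:
        segs = self.segments
        # first pass: exon coordinate ranges
        bounds: list[Optional[tuple[int, int]]] = []
        c = self.cds_start_coord
        for s in segs:
            if s.kind == "exon":
                bounds.append((c, c + len(s.sequence) - 1))
                c += len(s.sequence)
            else:
                bounds.append(None)

        def left_anchor(i: int) -> Optional[int]:
            for j in range(i - 1, -1, -1):
                if bounds[j] is not None:
                    return bounds[j][1]
            return None

        def right_anchor(i: int) -> Optional[int]:
            for j in range(i + 1, len(segs)):
                if bounds[j] is not None:
                    return bounds[j][0]
            return None

        genome_parts: list[str] = []
        positions: list[CodingPosition] = []
        kinds: list[str] = []
        for i, s in enumerate(segs):
            n = len(s.sequence)
            if s.kind == "exon":
                first, _ = bounds[i]  # type: ignore[misc]
                genome_parts.append(s.sequence.upper())
                positions.extend(CodingPosition(first + k) for k in range(n))
            else:
                genome_parts.append(s.sequence.lower())
                la, ra = left_anchor(i), right_anchor(i)
                if la is not None and ra is not None:
                    # intron: near half takes + offsets from the donor-side
                    # exon, far half - offsets from the acceptor-side exon
                    n_plus = (n + 1) // 2
                    positions.extend(CodingPosition(la, k) for k in range(1, n_plus + 1))
                    positions.extend(
                        CodingPosition(ra, -(n - n_plus) + k) for k in range(n - n_plus)
                    )
                elif ra is not None:  # upstream flank
                    positions.extend(CodingPosition(ra, -n + k) for k in range(n))
                else:  # downstream flank
                    assert la is not None
                    positions.extend(CodingPosition(la, k) for k in range(1, n + 1))
            kinds.extend([s.kind] * n)

        genome = "".join(genome_parts)
        pos_to_idx = {p: i for i, p in enumerate(positions)}
        if len(pos_to_idx) != len(positions):
            raise ValidationError("ambiguous coordinates: duplicate positions in layout")
        return _Layout(
            genome=genome,
            genome_upper=genome.upper(),
            positions=tuple(positions),
            kinds=tuple(kinds),
            pos_to_idx=pos_to_idx,
            cds_first=self.cds_start_coord,
            cds_last=self.cds_start_coord + sum(
                len(s.sequence) for s in segs if s.kind == "exon"
            ) - 1,
        )

    def __len__(self) -> int:
        return len(self._layout.genome)

    @property
    def genomic_sequence(self) -> str:
        """Full contiguous sequence, exons uppercase, introns/flanks lowercase."""
        return self._layout.genome

    @property
    def coordinates(self) -> tuple[CodingPosition, ...]:
        """Per-base CodingPosition in genomic order."""
        return self._layout.positions

    @property
    def segment_kinds(self) -> tuple[str, ...]:
        """Per-base segment kind in genomic order."""
        return self._layout.kinds

    @property
    def cds_range(self) -> tuple[int, int]:
        """First and last modeled CDS coordinate (inclusive)."""
        return self._layout.cds_first, self._layout.cds_last

    # -- base access ---------------------------------------------------------

    def index_of(self, pos: CodingPosition) -> int:
        """Genomic (0-based) index of a coding position."""
        try:
            return self._layout.pos_to_idx[pos]
        except KeyError:
            raise OutOfModelError(
                f"position c.{pos} is outside the modeled region of {self.name!r}"
            ) from None

    def kind_at(self, pos: CodingPosition) -> str:
        return self._layout.kinds[self.index_of(pos)]

    def get_base(self, pos: CodingPosition | int | str) -> str:
        """The base at ``pos`` in coding orientation, always uppercase."""
        pos = self._as_position(pos)
        return self._layout.genome_upper[self.index_of(pos)]

    def apply_edit(self, pos: CodingPosition | int | str, new_base: str) -> "MiniTranscript":
        """Return a copy with exactly one base replaced.

        Presentation case of the edited base follows the segment it sits in.
        """
        pos = self._as_position(pos)
        if len(new_base) != 1 or new_base.upper() not in _DNA:
            raise DomainError(f"replacement must be a single ACGT base: {new_base!r}")
        idx = self.index_of(pos)
        segs = list(self.segments)
        for si, s in enumerate(segs):
            if idx < len(s.sequence):
                b = new_base.upper() if s.sequence[idx].isupper() else new_base.lower()
                seq = s.sequence[:idx] + b + s.sequence[idx + 1:]
                segs[si] = Segment(s.kind, seq, s.non_canonical)
                break
            idx -= len(s.sequence)
        return MiniTranscript(self.name, self.cds_start_coord, tuple(segs))

    @staticmethod
    def _as_position(pos: CodingPosition | int | str) -> CodingPosition:
        if isinstance(pos, CodingPosition):
            return pos
        if isinstance(pos, int):
            return CodingPosition(pos)
        return parse_c_position(pos)

    # -- windows and codons ---------------------------------------------------

    def genomic_window(
        self, center: CodingPosition | int | str, left: int, right: int
    ) -> tuple[str, list[CodingPosition]]:
        """Contiguous genomic-order window of ``left + right + 1`` bases.

        Returns the (presentation-cased) sequence and the CodingPosition of
        every base.  A non-positive width returns an empty window.
        """
        if left + right + 1 <= 0:
            return "", []
        center = self._as_position(center)
        idx = self.index_of(center)
        lo, hi = idx - left, idx + right
        if lo < 0 or hi >= len(self):
            raise OutOfModelError(
                f"window [{-left}, +{right}] around c.{center} exceeds the modeled "
                f"region of {self.name!r}"
            )
        lay = self._layout
        return lay.genome[lo:hi + 1], list(lay.positions[lo:hi + 1])

    def codon_span(self, codon_index: int) -> tuple[CodingPosition, ...]:
        """The three CDS coordinates of a codon, in coding order."""
        if codon_index < 1:
            raise DomainError(f"codon index must be >= 1, got {codon_index}")
        start = 3 * codon_index - 2
        return tuple(CodingPosition(start + k) for k in range(3))

    def codon_sequence(self, codon_index: int, frame: Optional[int] = None) -> CodonRef:
        """Assemble a codon's bases across junctions; mark it incomplete if
        any base lies outside the modeled slice."""
        span = self.codon_span(codon_index)
        bases: list[str] = []
        n_present = 0
        for p in span:
            if p in self._layout.pos_to_idx:
                bases.append(self._layout.genome_upper[self._layout.pos_to_idx[p]])
                n_present += 1
            else:
                bases.append(".")
        if n_present == 0:
            raise OutOfModelError(
                f"codon {codon_index} lies entirely outside the modeled region"
            )
        complete = n_present == 3
        if complete:
            aa1 = translate("".join(bases))
            aa3 = aa_three(aa1)
        else:
            aa1 = aa3 = None
        return CodonRef(codon_index, "".join(bases), complete, aa1, aa3, frame)

    # -- serialization --------------------------------------------------------

    def to_config(self) -> dict:
        """Plain-dict form suitable for YAML/JSON round-tripping."""
        return {
            "name": self.name,
            "cds_start_coord": self.cds_start_coord,
            "segments": [
                {
                    "kind": s.kind,
                    "sequence": s.sequence,
                    **({"non_canonical": True} if s.non_canonical else {}),
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "MiniTranscript":
        try:
            segs = tuple(
                Segment(s["kind"], s["sequence"], bool(s.get("non_canonical", False)))
                for s in cfg["segments"]
            )
            return cls(cfg["name"], int(cfg["cds_start_coord"]), segs)
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed transcript config: {exc}") from exc

    @classmethod
    def from_fasta(cls, path: str, cds_start_coord: int, name: Optional[str] = None) -> "MiniTranscript":
        """Import a single contiguous exon from a one-record FASTA file."""
        records = list(SeqIO.parse(path, "fasta"))
        if len(records) != 1:
            raise ValidationError(f"expected exactly one FASTA record, got {len(records)}")
        rec = records[0]
        return cls(
            name or rec.id,
            cds_start_coord,
            (Segment("exon", str(rec.seq)),),
        )


def load_transcript(path: str) -> MiniTranscript:
    """Load a transcript model from a YAML or JSON config file."""
    import json

    import yaml

    with open(path) as fh:
        text = fh.read()
    cfg = json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
    return MiniTranscript.from_config(cfg)


def save_transcript(t: MiniTranscript, path: str) -> None:
    import json

    import yaml

    cfg = t.to_config()
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(cfg, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(cfg, fh, sort_keys=False)
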