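"""Stage 1: is a pathogenic SNV base-editable, by which editor, which strand?

Current base editors correct the four transitions (via ABE or CBE acting
on one strand or the other) and the two C:G<->G:C transversions (via
glycosylase editors, CGBE).  The mapping from an observed coding-strand
substitution to (editor class, targeted strand) is a fixed 6-entry table:
the editor must act on whichever strand carries its substrate base, and
its conversion must restore the wild-type allele after projection back to
the coding strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from .editors import CONVERSION_CLASSES, EditorConstruct
from .errors import DomainError
from .transcript import complement

#: (ref, alt) on the coding strand -> (editor class, targeted strand)
AMENABILITY_TABLE: dict[tuple[str, str], tuple[str, str]] = {
    ("G", "A"): ("ABE", "forward"),
    ("C", "T"): ("ABE", "reverse"),
    ("A", "G"): ("CBE", "reverse"),
    ("T", "C"): ("CBE", "forward"),
    ("G", "C"): ("CGBE", "forward"),
    ("C", "G"): ("CGBE", "reverse"),
}

CLASS_CONVERSIONS = {cls: conv for conv, cls in CONVERSION_CLASSES.items()}


@dataclass(frozen=True)
class EditStrategy:
    """Which editor class corrects an SNV, and on which strand."""

    editor_class: str  # ABE | CBE | CGBE
    target_strand: str  # forward | reverse (relative to coding orientation)
    mutant_base_on_target_strand: str
    corrected_base_on_target_strand: str

    def __post_init__(self) -> None:
        sub, prod = CLASS_CONVERSIONS[self.editor_class]
        if self.mutant_base_on_target_strand != sub or self.corrected_base_on_target_strand != prod:
            raise DomainError(
                f"{self.editor_class} converts {sub}->{prod}, not "
                f"{self.mutant_base_on_target_strand}->{self.corrected_base_on_target_strand}"
            )


def classify_variant(ref: str, alt: str) -> list[EditStrategy]:
    """Editing strategies able to revert a coding-strand ``ref>alt`` SNV.

    Returns an empty list for the six substitutions no current editor
    corrects.  Exactly one strategy exists per amenable substitution.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise DomainError(f"ref/alt must be single ACGT bases: {ref!r}>{alt!r}")
    if ref == alt:
        raise DomainError(f"ref and alt are identical: {ref}")
    hit = AMENABILITY_TABLE.get((ref, alt))
    if hit is None:
        return []
    editor_class, strand = hit
    if strand == "forward":
        mutant, corrected = alt, ref
    else:
        mutant, corrected = complement(alt), complement(ref)
    return [EditStrategy(editor_class, strand, mutant, corrected)]


def is_correctable_by(strategy: EditStrategy, construct: EditorConstruct) -> bool:
    """True iff the construct's conversion implements the strategy's class."""
    return construct.editor_class == strategy.editor_class
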