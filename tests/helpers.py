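"""Independent brute-force oracles used to cross-check the pipeline.

Deliberately written without reusing the placement logic from
``bescreen.guides``: the scanner slides every length-(spacer+PAM)
substring over both readings of the full modeled sequence and keeps
matches, rather than placing the protospacer around the target.
"""

from __future__ import annotations

from bescreen import EditorConstruct, MiniTranscript, Variant, iupac_match
from bescreen.transcript import revcomp


def brute_force_placements(
    t: MiniTranscript,
    variant: Variant,
    construct: EditorConstruct,
    strand: str,
) -> list[tuple[str, str, int]]:
    """All (protospacer, pam, target_window_position) for one strand.

    Scans every window of spacer+PAM length over the targeted-strand
    reading of the mutant sequence; keeps windows that lie entirely on
    exon/intron bases, whose PAM half matches, and whose protospacer half
    contains the variant base inside the editing window.
    """
    mutant = t.apply_edit(variant.position, variant.alt)
    seq = mutant.genomic_sequence.upper()
    kinds = list(mutant.segment_kinds)
    tgt = mutant.index_of(variant.position)
    if strand == "reverse":
        seq = revcomp(seq)
        kinds = kinds[::-1]
        tgt = len(seq) - 1 - tgt

    L, P = construct.spacer_length, construct.pam_length
    lo, hi = construct.window
    total = L + P
    hits = []
    for start in range(0, len(seq) - total + 1):
        chunk = seq[start:start + total]
        if any(k == "flank" for k in kinds[start:start + total]):
            continue
        if construct.pam_side == "3prime":
            proto, pam = chunk[:L], chunk[L:]
            proto_start = start
        else:
            pam, proto = chunk[:P], chunk[P:]
            proto_start = start + P
        if not iupac_match(construct.pam_pattern, pam):
            continue
        p = tgt - proto_start + 1  # 1-based protospacer position of the variant
        if lo <= p <= hi:
            hits.append((proto, pam, p))
    return hits
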