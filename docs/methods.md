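# Methods

## Transcript model and coordinates

A `MiniTranscript` is a genomically contiguous slice of a coding gene in
coding orientation: alternating exon/intron segments, with optional
`flank` segments at the two ends standing in for unknown context.
Exonic bases carry CDS coordinates contiguous from `cds_start_coord`;
intronic bases use HGVS-style offsets relative to the nearest exonic
base (the donor-proximal half of an intron counts `+1, +2, …` from the
last exon base, the acceptor-proximal half `…, -2, -1` toward the next
exon base; for odd intron lengths the extra base goes to the donor
side). Codon index and frame follow directly from the CDS coordinate
(`codon = ceil(c/3)`, `frame = ((c-1) mod 3) + 1`); codons may span an
exon–exon junction and are assembled across it in coding order. Codons
truncated by the slice edge are reported `incomplete` and excluded from
protein-level classification with a warning — they are never silently
translated.

Sequence case is presentation only (exons uppercase, introns/flanks
lowercase); all computation is case-insensitive. Reverse-strand views
are always computed on demand from the coding-orientation store, so a
strand bug cannot hide in duplicated state.

## Editor constructs

A construct is (PAM pattern, PAM side, spacer length, editing window,
base conversion). PAM matching is plain degenerate-IUPAC matching with
no gap between protospacer and PAM. Window positions are 1-based from
the protospacer 5′ end on the targeted strand for all constructs,
including the 5′-PAM CasMINI; any geometric offset is absorbed by the
window. Defaults: nSpCas9-ABE8e NGG/20 nt/window 4–8, nSaCas9-ABE8e
NNGRRT/21/3–13, KKH NNNRRT/21/3–13, CasMINI-ABE8e TTTR(5′)/20/3–8.
The Sa/KKH 3–13 and SpCas9 4–8 windows are the unique simple intervals
consistent with the worked bystander sets this package reproduces (they
include substrate adenines at protospacer positions 3, 7, 12, 13 and
5, 6, 9 while excluding position 14); the CasMINI parameters have no
worked example behind them and are flagged with a `confidence_note`.
All of this is overridable through a registry config file.

## Amenability

The (ref, alt) → (editor class, strand) table has exactly six amenable
entries: the editor acts on whichever strand carries its substrate, so
G>A is ABE/forward, C>T is ABE/reverse, A>G is CBE/reverse, T>C is
CBE/forward, and the two C:G↔G:C transversions map to CGBE. CGBE is
included for taxonomy completeness although no bundled case uses it.
Each `EditStrategy` self-checks the round trip (conversion applied on
the targeted strand, projected back to the coding strand, must equal
the wild-type allele).

## Guide enumeration

Enumeration targets the *mutant* sequence (the editable substrate is
the pathogenic allele); the wild-type sequence is used only for
consequence comparison. For each window position the protospacer is
placed around the target on the targeted-strand reading of the full
contiguous slice — placements legitimately cross exon–intron
boundaries, and a PAM may be fully intronic. Two skip rules, both
logged: placements extending past the modeled slice, and placements
overlapping `flank` bases. Flanks are *unknown* padding, so matching a
PAM or protospacer against them would manufacture evidence; a finite
fixture therefore answers "no PAM available" for exactly the sequence
it models. Candidates are ordered by window centrality, then
5′-most — the selection rule is an artifact convention, since a single
reported guide per construct does not pin one down.

An independent brute-force oracle (tests/helpers.py) slides every
spacer+PAM-length window over both strand readings and must produce the
identical candidate set; this equivalence is asserted on the fixtures
and on 50 seeded random transcripts.

## Bystander prediction

Substrate bases in the window other than the target are bystanders.
Single-edit consequences are evaluated on the wild-type background
(i.e. assuming the therapeutic edit succeeded): coding-strand rendering
of the change (a reverse-strand A→G appears as T>C), then silent /
missense / nonsense / start-loss by codon comparison, or splice-level
classes for intronic positions — |offset| ≤ 2 is a canonical splice
dinucleotide, 3–8 the splice region (a package convention; only the
±1/±2 class carries the "very likely splicing variant" weight), deeper
is plain intronic. Intronic bystanders are reported, not dropped, so
bystander counts include canonical-splice hits.

Because deamination of each window substrate is independent, per-codon
outcomes enumerate all 2ᵏ edit subsets on the mutant codon, with the
target edit as a free choice; the outcome set is compared against the
wild-type amino acid, and codons reachable only as wild type are
omitted. Outcome labels order amino acids alphabetically
(`p.L746L/P`); downstream comparisons should use the sets, not the
label strings, as orderings vary in the literature. k is bounded by 3
in practice (one codon), so the enumeration is trivially cheap.

## Synthetic data

`fixture_AB` and `fixture_C` reconstruct the two CRB1 mini-loci from
the published protospacer+PAM context: exon A c.2827–2842, a 23-nt
intron whose donor (`gtaggtagagt`) and acceptor (`ttag`) runs are fixed
by the printed guide tails, exon B c.2843–2865, and the single exon
c.2219–2241 whose mutant reverse complement is the published
reverse-strand guide. A 23-nt intron is biologically implausible but
fully determined by the printed sequence; the intron interior and the
flanks are filler chosen so they complete no registry PAM (`c`/`cag`
repeats). The fixtures model *slices*, not the real 12-exon transcript,
and deliberately make no claim about true exon numbering or genomic
coordinates.

`random_transcript(n_exons, exon_len_range, intron_len_range, gc,
seed)` builds seed-deterministic junction-bearing transcripts with
canonical gt..ag introns. `plant_amenable_variant` installs a variant
and a concrete PAM drawn from the construct pattern at a chosen window
position, recording ground truth constructively (never by running the
enumeration under test); `scramble_pam` overwrites every constrained
PAM position with a disallowed base, guaranteeing the planted placement
cannot match. A planted PAM may clobber a splice dinucleotide, in which
case the intron is transparently flagged non-canonical.

What passing on synthetic data does **not** show: real editing
efficiency, chromatin context, off-target behaviour, or splice-strength
changes — the model is purely sequence-combinatorial, with no
processivity or efficiency weighting, by design (see Non-goals below).

## Numerical/representational choices

- Coordinates 1-based inclusive throughout; protospacer positions
  1-based from the 5′ end.
- Reports are byte-stable: fixed column order, sorted JSON keys, no
  timestamps; a short SHA-256 digest of the registry settings is
  embedded so a report is traceable to its configuration.
- Problem sizes in the test suite and acceptance script (50 random
  transcripts for oracle equivalence, 100 planted + 100 scrambled
  trials, 2–3 exons of 60–120 nt) keep the whole suite around two
  seconds while exercising every junction/strand/PAM-side combination.
- All randomness flows through `numpy.random.default_rng(seed)`; the
  acceptance script derives per-trial seeds from `--seed` below 2³¹.

## Known limitations

- No editing-efficiency, processivity, or off-target scoring (Doench,
  CFD); no splice-strength models (MaxEnt, SpliceAI); no protein
  stability or pathogenicity prediction for bystanders.
- HGVS support is limited to exonic positions and intron offsets — no
  UTR (`*`/`-`) coordinates, duplications, or delins.
- Variant input is TSV (transcript_name, c_position, ref, alt); VCF
  ingestion would need a contig→transcript mapping layer that is out of
  scope here.
- The flank-exclusion rule means a variant close to the slice edge can
  be reported unplaceable simply because the model is short; extend the
  modeled slice rather than the flanks in that case.
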