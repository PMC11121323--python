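# bescreen

In silico screening of pathogenic single-nucleotide variants for
CRISPR **base-editing** amenability: which editor class can revert a
given SNV, on which strand, with which guide RNA, and at what cost in
unwanted **bystander edits**.

The package was built around three pathogenic *CRB1* variants causing
early-onset retinal degeneration — c.2843G>A p.(Cys948Tyr),
c.2833G>A p.(Gly945Arg), and c.2234C>T p.(Thr745Met) — and ships the
corresponding mini-locus fixtures, but every stage works on any
user-supplied transcript model and variant table.

## What it computes

For an SNV `ref>alt` on the coding strand of a transcript:

1. **Amenability** (`bescreen.amenability`). Current editors correct the
   four transitions and the two C:G↔G:C transversions. Each amenable
   substitution maps to exactly one (editor class, targeted strand)
   pair: e.g. G>A → ABE on the forward strand (the pathogenic A is the
   ABE substrate), C>T → ABE on the reverse strand. The strategy is
   validated by round trip: applying the conversion to the mutant base
   on the targeted strand and projecting back to the coding strand must
   restore `ref`.
2. **Guide enumeration** (`bescreen.guides`). For a construct with
   spacer length *L*, editing window *[w₁, w₂]* (protospacer positions,
   1-based from the 5′ end on the targeted strand) and PAM pattern *P*
   (IUPAC, 3′ or 5′ of the protospacer): for every window position
   *p* ∈ *[w₁, w₂]*, place the protospacer on the genomically contiguous
   mutant sequence so the variant sits at *p*, and emit a candidate iff
   the adjacent PAM matches *P*. Placements may run from an exon into an
   intron; placements that would overlap unknown flank padding are
   skipped, never partially matched.
3. **Bystander prediction** (`bescreen.bystanders`). Every other
   substrate base inside the window is a potential bystander edit,
   annotated at the c. level (coding-strand alleles), the protein level
   (silent / missense / nonsense / start-loss), and the splice level
   (intron offsets ±1/±2 → canonical splice site, ±3…±8 → splice
   region). Edits combine: per affected codon all 2ᵏ on/off subsets of
   its editable bases are translated, giving outcome sets such as
   Gln944 → {Gln, Arg} (written `p.Q944Q/R`).

Default registry (all ABE8e, A→G):

| construct | PAM | side | spacer | window |
|---|---|---|---|---|
| nSpCas9-ABE8e | NGG | 3′ | 20 | 4–8 |
| nSaCas9-ABE8e | NNGRRT | 3′ | 21 | 3–13 |
| KKH-nSaCas9-ABE8e | NNNRRT | 3′ | 21 | 3–13 |
| CasMINI-ABE8e | TTTR | 5′ | 20 | 3–8 |

All of it is configuration — see `bescreen.load_registry`.

## Worked example

```python
import bescreen as b

fx = b.fixture_AB()                      # CRB1 mini-locus, exons 2827-2842 / 2843-2865
variant = fx.variants[1]                 # c.2843G>A, p.(Cys948Tyr)
vs = b.screen_variant(fx.transcript, variant, b.default_registry())

print(vs.matrix.counts)
print(vs.displays)
rep = vs.bystanders["KKH-nSaCas9-ABE8e"]
for e in rep.edits:
    print(e.window_position, e.c_label, e.consequence_class, e.p_label)
```

prints

```
{'nSpCas9-ABE8e': 0, 'nSaCas9-ABE8e': 0, 'KKH-nSaCas9-ABE8e': 1, 'CasMINI-ABE8e': 0}
{'KKH-nSaCas9-ABE8e': 'TTAG[G>A]TATTGCAAATGCTGTTtttaat'}
3 c.2843-2A>G canonical_splice 
7 c.2845A>G missense p.Ile949Val
12 c.2850A>G silent p.Ala950Ala
13 c.2851A>G missense p.Asn951Asp
```

i.e. only the KKH construct has a usable PAM for this variant; its one
guide (uppercase protospacer, bracketed target, lowercase PAM) carries
four bystander adenines in the editing window, one of which destroys
the splice acceptor (c.2843-2A>G) and two of which are missense —
exactly why the safety of this particular strategy is limited.

The same pipeline is exposed as a CLI:

```
bescreen fixtures --out-dir demo
bescreen screen --transcript demo/CRB1-mini-AB.yaml \
                --variants demo/CRB1-mini-AB.variants.tsv
```

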