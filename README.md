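# pseudoscan

Reference-guided pseudogene detection, gene-loss phylogenetics and a
counting-based selection screen for exon-structured genes — with a
truth-logged sequence-evolution simulator so every stage can be validated
against known ground truth.

## The problem

Comparative genomics of gene loss asks, for one gene across dozens of
species: is the gene still intact in this genome, and if not, which
mutations killed it, when, and how often independently?  The motivating
case is an epithelial sodium channel (ENaC) subunit gene: a 12-exon core
region (exons numbered 2–13 by convention, with the start codon on exon 2
and the STOP on exon 13) that remains intact in terrestrial even-toed
ungulates but decayed repeatedly in lineages that returned to the sea.
Detecting that decay from genome assemblies means reconstructing each exon
against a trusted reference species, checking the splice dinucleotides
flanking every exon (donor canonically `GT`, acceptor `AG`, with rare
tolerated `GC`/`AC` variants), translating the assembled coding sequence,
and deciding whether the open reading frame survives.

`pseudoscan` implements that workflow as a tested Python library:

1. **gene_model** — reference exon/intron architecture, frames, translation
   (`N`-containing codons → `X`, never STOP), model validation.
2. **simulate** — evolves the reference locus along a rooted tree
   (Jukes–Cantor background substitution, intronic indels) and plants
   explicit, Dollo-inherited lesions: splice-site mutations, frameshifting
   and in-frame indels, premature STOPs, exon deletions, and in-frame exon
   fusions.  Every tip carries a complete truth log.
3. **mapping** — places each reference exon in a target locus by local
   alignment with affine gaps (match +2, mismatch −3, gap open −5, extend
   −2), enforcing colinear order, snapping boundaries, and reading the
   flanking splice dinucleotides.
4. **integrity** — turns hits into lesion records, detects in-frame
   "super exon" fusions (donor lost, retained intron length ≡ 0 mod 3,
   STOP-free read-through), scans for frame-preserving rescue splice
   sites, assembles the predicted CDS and issues the verdict:
   `INTACT` / `INTACT_FUSION` / `PSEUDOGENE` / `INCOMPLETE`.
5. **dollo** — canonicalises lesion signatures, places each shared
   signature at the MRCA of its carriers, and counts the minimum number of
   independent loss events under Dollo parsimony (gains only, no
   reversal): the count equals the number of maximal carrier-only clades.
6. **selection** — Nei–Gojobori (1986) counting dN/dS and a SLAC-style
   per-site screen over Fitch ancestral states.  For each sense codon the
   synonymous site count is  s = Σᵢ (synonymous non-STOP mutants at
   position i) / (non-STOP mutants at position i),  with n + s = 3;
   multi-difference codons average over all STOP-free substitution
   pathways; proportions are corrected with Jukes–Cantor
   d = −(3/4)·ln(1 − 4p/3), and ω = dN/dS.  Outputs carry a
   `method="NG86-counting"` tag — these are counting estimates, never
   likelihood fits.
7. **pipeline / cli** — orchestration, TSV/JSON reports (verdict matrix
   with codes I/F/P/U, lesion map, event placements, selection tables) and
   a thin `pseudoscan` command with subcommands
   `simulate | map | classify | events | dnds | report | all`.

## Worked example

`examples/` contains one short script per capability.  For instance,
`python examples/02_super_exon_fusion.py` plants a donor mutation plus a
99-nt STOP-free intron between exons 11 and 12 on the stem of a
two-species clade and prints:

```
Oa: INTACT_FUSION  fusion exon11+exon12, retained intron 99 nt -> 33 extra residues
   CDS length 2151 nt (+99 vs reference), ORF continuous: single terminal STOP
Ch: INTACT_FUSION  fusion exon11+exon12, retained intron 99 nt -> 33 extra residues
   CDS length 2151 nt (+99 vs reference), ORF continuous: single terminal STOP
Bt: INTACT
   CDS length 2052 nt (+0 vs reference), ORF continuous: single terminal STOP
```

The retained 99-nt intron contributes 99/3 = 33 residues to the protein
without disrupting the reading frame, so the two carrier species are
called intact-with-fusion rather than pseudogenes; the mutated donor is
kept in the lesion report but downgraded to non-disrupting.
`examples/03_loss_events_on_tree.py` shows three splice lesions shared by
a four-tip marine clade mapping to a single stem branch (one loss event),
and `examples/04_selection_screen.py` recovers ω ≈ 1.11 in a relaxed
foreground clade against ω ≈ 0.12 in a purifying background from counted
changes.

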