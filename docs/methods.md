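# Methods

This note documents the models, conventions and numerical choices behind
`pseudoscan`, and what the synthetic validation does and does not show.

## Gene model and coordinates

A gene is an ordered list of coding exons with an exon-numbering
convention borrowed from ENaC-subunit genes (exons 2–13; start codon on
the first modelled exon, STOP on the last).  Exon sequences are CDS-only;
introns are stored alongside so the simulator can emit full genomic loci.
Each exon records its phase (cumulative upstream CDS length mod 3) and the
expected flanking splice dinucleotides.  All coordinates are 0-based
half-open internally; TSV reports convert to 1-based inclusive.
Translation uses the standard nuclear code only — vertebrate nuclear genes
need no alternatives — and renders any codon containing `N` as `X`, which
never counts as a STOP, so assembly gaps cannot fabricate nonsense codons.
The configured start exon is authoritative: no upstream search for
alternative first exons is attempted, since regions upstream of the core
are variable and possibly alternatively spliced.

## Synthetic genomes

The simulator is first-class, tested code: it defines the conditions under
which every downstream claim is validated.

* **Reference construction.**  Default 12 exons of 80–250 nt.  Introns
  default to 150–600 nt — deliberately condensed, mirroring the compact
  intron structure reported for the δ-subunit gene relative to its
  paralogues.  Donors are `GT` (optionally `GC` at a configurable
  fraction, emulating the rare tolerated non-canonical donor); acceptors
  `AG`.  The concatenated CDS starts `ATG`, ends in exactly one STOP and
  is internally STOP-free; generation is rejection-sampled and
  deterministic per seed.
* **Background substitution** is Jukes–Cantor per branch: the count is
  Poisson(rate × branch length × eligible sites), positions uniform over
  unmasked sites.  Masked from background change: splice dinucleotides,
  the start and STOP codons, and planted-event footprints.  Proposals that
  would create an in-frame STOP in the *current* coding frame are
  rejected.  Scientifically this emulates purifying selection against
  nonsense mutations in a functional gene; practically it keeps the
  planted truth log unambiguous — every premature STOP in a tip is either
  planted or a deterministic consequence of a planted frame shift.
* **Background indels** (geometric lengths 1–10, insert/delete equally)
  are confined to introns and flanks, clear of the splice dinucleotides.
  Coding indels only ever enter as planted events, so indel truth is
  exact.  At the default settings used for validation the background
  indel rate is zero.
* **Planted events** are applied on a named branch after that branch's
  background noise and inherited by all descendants (no reversal — the
  simulation itself is Dollo-consistent).  Planted splice mutations are
  made *rescue-proof*: frame-preserving canonical dinucleotides within a
  ±45 nt window of the mutated boundary are scrubbed (GT→GC / AG→AC; a C
  in a codon can never form a STOP, so scrubbing is always safe), and a
  mutated donor whose intron happens to be a codon multiple is guaranteed
  an in-frame STOP so it cannot masquerade as a fusion.  Fusion events
  replace the intron with a sequence that keeps the intact `AG` acceptor,
  has length ≡ 0 (mod 3) and is STOP-free in all three frames including
  the junction codons.
* **Random streams** are split per branch from the master seed
  (`SeedSequence([seed, branch_index])`), so adding a planted event never
  changes background noise elsewhere, and two seeds differ in noise but
  not in planted-event coordinates.

The generator's scenario sampler plants events so each remains
individually attributable: one event per exon and per intron per lineage,
and no premature STOP (or fusion) downstream, in gene order, of a
frame-disrupting event on the same lineage — a shifted frame provably
hides a reference-frame STOP from any detector.  This is a property of the
*validation design*, not of the detector: on real data the classifier
still reports such downstream STOPs, flagged as secondary (below).

What the simulator does **not** emulate: codon-level selection (site-wise
ω), rate heterogeneity, large structural variation beyond single-exon
deletion, assembly artefacts other than N runs, and paralogous loci.
Passing recovery tests therefore demonstrates the correctness of the
detection logic under clean-to-moderately-divergent single-copy
conditions, not robustness to every assembly pathology.

## Exon mapping

Each exon is located by local alignment (biopython `PairwiseAligner`,
match +2, mismatch −3, gap open −5, gap extend −2 — BLAST-like values
appropriate for within-order mammalian divergence; all configurable).  A
hit is accepted when identity ≥ 0.6 over ≥ 60% of the exon.  Search
windows start at the previous hit's end minus a 50 nt look-back, so
placements are colinear by construction; ties resolve leftmost.  Accepted
hits are boundary-snapped to cover the full reference exon (local
alignment clips mismatching terminal bases; the snap restores them so
splice dinucleotides are read from fixed offsets) and re-aligned globally
to produce the gapped alignment used for lesion calling — with end gaps
emitted explicitly, so an indel at an exon edge remains visible.  Strand
is resolved by comparing summed best-exon scores on both strands using the
four longest exons (a speed choice; configurable to all exons); a locus
where neither strand yields one acceptable hit raises "no gene found".
Loci whose search windows contain N runs ≥ 50 nt mark the affected exon
unresolvable and the verdict INCOMPLETE-eligible.

## Lesion calling and verdicts

* **Splice classification:** donor `GT` / acceptor `AG` canonical,
  `GC` / `AC` tolerated non-canonical, anything else mutated; any `N`
  classifies as mutated with a low-confidence flag.
* **Indels** come from alignment gap runs; runs separated by ≤ 3 aligned
  columns are merged into one net event, because the optimal alignment of
  a single indel plus nearby substitutions is sometimes a split gap and
  the lesion of record is the net change.  Net length ≢ 0 (mod 3) is a
  disrupting frameshift; a codon-multiple indel is recorded as a
  non-disrupting structural note (it preserves the frame).
* **Premature STOPs** are scanned in the *observed* reading frame,
  tracking cumulative frame through upstream indels, fusions and missing
  exons.  A STOP whose frame position is inconsistent with the reference
  frame, or whose codon touches an indel junction, is flagged
  `secondary=True`: it is a consequence of that frame change, not an
  independent mutation.  Secondary STOPs still support a PSEUDOGENE
  verdict but are excluded from shared-lesion signatures and recovery
  scoring.  A STOP within the final 30 nt of the terminal exon is treated
  as the true STOP slightly shifted, not a lesion (terminal-exon length
  varies between species); the window is configurable.
* **Fusion:** called when an exon's donor is mutated, the intervening
  intron length is ≡ 0 (mod 3), and translation through the intron in the
  running frame meets no STOP; the incorporated residue count is
  intron length / 3.  A fusion downgrades the donor (and the downstream
  acceptor) lesion to non-disrupting but keeps it in the report.
* **Rescue scan:** a mutated splice site without a fusion is checked for
  the nearest canonical dinucleotide within ±30 nt whose use shifts the
  boundary by a codon multiple and introduces no new in-frame STOP.  This
  replaces an external splice-site predictor with a transparent
  dinucleotide criterion; a successful rescue likewise downgrades the
  lesion without deleting it.
* **Verdict order:** INCOMPLETE if any exon is unresolvable from assembly
  gaps; else PSEUDOGENE if any disrupting lesion survives
  fusion/rescue reconciliation or the assembled ORF is not continuous
  (no STOP before the terminal window, at least one inside it); else
  INTACT_FUSION if a fusion was called; else INTACT.  A pseudogene whose
  only disrupting evidence is splice mutations carries a `splice_only`
  confidence flag rather than a separate status.

## Dollo loss mapping

Two lesions share a signature when gene, exon, kind, position bucket and
observed sequence agree after canonicalisation.  Splice lesions match
exactly (tolerance 0 — "identical mutated donor" is the criterion for
shared ancestry); indel offsets are bucketed at width 3 nt to absorb
alignment jitter.  Bucketing uses floor(offset / tolerance): pairwise
distance tolerance is not transitive and cannot define a canonical form.
Under Dollo parsimony (the loss character is gained on a branch, never
reverted — matching the observation that freshwater-recolonising lineages
do not regain the gene), the minimum number of independent origins of a
signature, or of the pseudogene state itself, equals the number of maximal
subtrees whose tips are all carriers; the placement is the carriers' MRCA.
Polytomies are hard: an event cannot be split below an unresolved node,
which keeps counts conservative.  INCOMPLETE tips are pruned before
counting.  Correctness is checked against exhaustive search over gain-edge
subsets (including a gain on the stem above the root, for the all-carrier
case) on 500 random trees of ≤ 8 tips.

## Selection screen

The screen is an explicitly simplified counting analogue — no maximum
likelihood, no rate variation, no branch-site machinery — and every output
carries `method="NG86-counting"` so the numbers cannot be mistaken for
codeml/HyPhy results.  Site counts follow NG86 with the synonymous
fraction taken over non-STOP single-nucleotide mutants (n + s = 3 per
codon); pairwise differences average over all STOP-free substitution
pathways with equal weights (a codon pair whose every pathway crosses a
STOP is skipped and logged); proportions are Jukes–Cantor corrected, with
pN or pS ≥ 3/4 flagging the correction invalid.  ω is ∞ when dS = 0 <
dN and undefined when both are 0.  For tree-wide screens, nucleotide
ancestral states are reconstructed by Fitch parsimony (ties prefer the
parental state, then alphabetical — deterministic given the rooted tree;
gaps and Ns are fully ambiguous), per-branch codon changes are
pathway-averaged, and pooled (Nd/N)/(Sd/S) gives a foreground-clade versus
background ω.  The per-site screen tests each codon's nonsynonymous change
count against its neutral expectation n/(n+s) with an exact two-sided
binomial test; no multiple-testing correction by default (per-site p at a
stated α, the SLAC reporting convention), Benjamini–Hochberg available.
Fractional pathway-averaged counts are rounded to integers for the exact
test only.  Because low-count sites can never reach significance, the
per-site test is conservative: measured type-I error on neutral
simulations is far below α.

## Validation sizes and numerical choices

Recovery is scored on 25 random scenarios × 8 tips = 200 loci per
divergence condition (0 and 1% per site per unit branch length), with all
seven event kinds represented; these sizes give exact recovery a real
chance to fail while keeping a full validation run in the low minutes on
one CPU.  Matching is by (lesion kind, exon): sensitivity over planted
events, precision over primary predicted lesions plus fusion calls (a
planted fusion legitimately presents as both the fusion call and the
mutated-donor record).  The NG86 oracle check covers all 61 × 61 sense
codon pairs exactly; the Dollo oracle 500 random scenarios; the selection
calibration 50 neutral replicates (type-I ≤ α + 2·SE pooled) and 20
directional replicates (foreground ω must exceed background).  Determinism
is verified at byte level over every pipeline output; reports avoid
timestamps and absolute paths for this reason.

## Known limitations

No transcript-evidence channel (intron-spanning reads), so boundary calls
rest on genomic signal alone and out-of-frame pseudo-exon inclusion events
cannot be called.  Ordering of multiple lesions within one pseudogene
lineage is not modelled, only counted.  The selection screen's counting
estimates are biased at high divergence (Fitch under-counts parallel
changes) and the screen does not reproduce likelihood-based test
statistics.  Loss dating is out of scope: event placements are branches,
not times.
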