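# Methods

## The problem

Killer meiotic drivers of the poison–antidote type form a rapidly evolving
multicopy gene family: ~1.2-kb genes with five or six exons, present at
~20–24 loci of 0–3 tandem copies, flanked by LTR retrotransposon remnants,
exchanging sequence by nonallelic gene conversion, and carrying unstable
intragenic tandem repeats.  Standard short-insert sequencing cannot resolve
them; the package implements the mate-pair strategy that can, together with
the downstream evolutionary analyses.

## Mate-pair copy-number model

A mate-pair library is modelled as fragments of uniform length
$F \sim U[a, b]$ (defaults 5,000–8,000 bp), uniform start and strand, with
the two reads being the terminal $L = 150$ bp of the fragment.  Both reads
are reported on the fragment's forward strand and all downstream matching
is orientation-agnostic, because post-processing orientations of real
mate-pair chemistry vary by protocol; the true genomic strand is kept in
the read-origin truth table.  The expected pair count is
$\mathrm{coverage} \cdot G / 2L$ (drawn Poisson); sequencing errors are iid
substitutions (no indels — this keeps exact-recovery oracles exact).

Reads are matched to the family panel by shared k-mers: a read matches when
at least `min_kmer_frac` (default 0.05) of its k-mers (k = 15) occur in the
panel k-mer set built over both strands.  This tolerates the 5–10%
divergence actually separating paralogs with ≥99% sensitivity while
excluding unrelated reads; it is **not** a 20%-divergence matcher — at 20%
iid mismatches the expected number of clean 15-mers in a 150-bp read is
~4.8 against a threshold of 7, capping sensitivity near 25%, a limit of
any fixed-k scheme at these parameters.

Partner reads (the mates that did not match the panel) are placed by a
unique-k-mer-anchor mapper (k = 21): anchors that are unique in the
reference vote for a placement; multi-placement or repeat-only reads are
discarded; accepted placements must match the full read with ≤2
substitutions.

For a locus whose panel-matching span is $S$, partner starts are the
convolution of the matching-read positions (width ≈ S) with the insert
distribution (width $b-a$), giving flanking coverage mounds of expected
full-support width $W = S + (b-a) + 2L$.  `call_pileups` detects mounds as
maximal runs of depth ≥ `min_depth` (default max(3, 10% of the median
partner coverage)), merges runs closer than `merge_gap` (200 bp), and
reports each mound at its contiguous coverage ≥ 1 support: the detection
threshold rejects noise, while the reported width is the quantity the
analytic model predicts.  Widths measured only at the ≥ min_depth core
would systematically undershoot $W$ by roughly
$2 \cdot \mathrm{ramp} \cdot \mathrm{min\_depth}/\mathrm{plateau}$ (~500 bp
at 80×), which is why the support extension is the default
(`extend_to_support=False` restores literal threshold runs).

Adjacent pileups with an inner gap below `max_pair_span` are paired into a
locus (greedy, left to right); the pipeline derives `max_pair_span` as
2×`insert_max` from the library parameters, since the inter-pileup gap is
≈ $2a - S - 4L$.  Copy number comes from the widest flanking pileup via
midpoint boundaries between the analytic anchors $W(n)$ for $n$ tandem
genes ($S(n) = n \cdot \mathrm{gene} + (n-1)\cdot\mathrm{LTR}$); with the
published real-data geometry the anchors are ~2.2/4.4/7.5 kb and the
boundaries 1.1/3.3/5.95 kb.  Anchors can be recalibrated from known
single-gene control loci (`CopyNumberCalibration.recalibrated`).  Widths
beyond the three-gene anchor report 3 with a flag — wider tandem arrays
exceed the insert and are unresolvable by this design.  Flank widths
disagreeing by >1.5 kb, or a second right-flank candidate within pairing
range of the same left pileup, raise the `complicated` flag.

Loci inside larger segmental duplications are caught by a window-median
coverage scan over all reads mapped to a reference lacking the duplication.
One extra copy doubles expected coverage; the decision threshold defaults
to 1.75× the genome median because the idealized 2.0× signal is always
eroded a little by junction and repeat-ambiguity losses.

## Targeted assembly

Orange bait regions are the flanking pileups padded by 2 kb, clipped to
never enter the locus, minus annotated repeats.  Green subtraction regions
run from 15 kb beyond the orange edge to within 500 bp of the locus, and
are *also* repeat-masked and masked for every other called family locus:
a dispersed LTR copy or a paralog inside green would subtract the locus's
own reads and hole the assembly.  Pairs with ≥1 orange-matching read are
recruited; of those, individual reads matching green are dropped.  The
candidate set is optionally subsampled (default cap 2,600 reads ≈ 40× of
one locus) to bound assembly cost.

The assembler is a deterministic greedy overlap–layout–consensus: candidate
overlaps are seeded by shared 24-mers over both strands, verified
(≥ `min_overlap` = 40 bp at ≤ `max_mismatch_frac` = 2% mismatches), and
merged longest-first with ties broken by mismatch count and read index;
every merge is re-verified and re-measured at the contig level, and
consensus is per-column majority over base counts (ties resolved A<C<G<T).
The 2% ceiling is what keeps ~5%-diverged LTR copies and ~8%-diverged
paralogs from collapsing while accepting true overlaps at 0.2% sequencing
error.  Contigs are stitched between the flank sequences on ≥100-bp
overlaps; a missing join becomes an N-run sized from the expected
flank-to-flank span; ambiguous orders raise an error listing the
alternatives rather than guessing (the manual-curation cases of the
original protocol).

## Annotation and classes

The best exemplar is chosen by global alignment (match +1, mismatch −1,
gap −5/−0.5, free end gaps); exon boundaries, repeat regions and the start
codon are projected through the alignment.  Identity is matching columns
over the shorter sequence length — normalising by aligned columns only
would score unrelated sequences spuriously high under free end gaps.
Pseudogenes: internal stop in the projected CDS, or an exon with a net
indel not divisible by 3 ("exon 4" may be absent entirely; five-exon genes
are normal).  Class 1 requires a codon-aligned ATG within ±30 nt of the
exon-2 start in the antidote frame (the window quantifies "just upstream or
near the beginning of exon 2"; no number is published) *and* transcript
evidence for an exon-1-skipping isoform that is true or unknown — the
evidence is an input flag, never computed.  Class 3 overrides at <55%
whole-CDS identity to every exemplar.  Synteny naming: at matched loci the
most-similar gene inherits the reference name; extras get fresh numbers in
genome order after the reference maximum; ties warn and fall back to
genome order.

## Four-gamete conversion scan

Eight segments per gene: a 133–289-bp upstream region, intron 1, and exons
1–6 with the exon-3/6 repeat regions excised (repeat copy-number variation
must not masquerade as divergence).  Clade assignment takes a supplied tree
or builds neighbour joining (scikit-bio) from p-distances with pairwise gap
deletion, then splits at the internal edge of maximal length with ≥2 genes
on each side; label A anchors to the alphabetically first gene.  Segments
whose clades have <2 members are excluded; genes unassigned in a segment
are dropped pairwise.  A segment pair is positive iff all four clade
combinations occur among shared genes (<4 shared genes: not evaluable).

Two facts worth stating precisely: a *single* discordant gene yields only
three combinations and is correctly negative (stepwise mutation explains
it); and in the minimal 4-gene two-clade design a whole-segment conversion
is nonetheless always detected, because conversion copies the donor's
segment verbatim, pinning recipient to donor in that segment's tree, and
the two-clades-of-two constraint then forces an unconverted gene across,
supplying the fourth combination.

## NG86 diversity

Site counts: each of a codon's 9 single-base changes contributes 1/3 site,
synonymous or nonsynonymous by the standard code; changes to stops are
excluded from the opportunity.  Pair differences: averaged over all minimal
substitution pathways avoiding stop intermediates (all pathways, with a
warning path, in the never-observed case that none avoids stops).  Per pair,
$p_N = N_d/N$ and $p_S = S_d/S$ over codons gap-free in both sequences
(pairwise deletion, the DnaSP-style default); $\pi_N, \pi_S$ are means over
pairs.  Raw proportions are the default and Jukes–Cantor is an option,
since the published analysis does not state which its software applied; at
the within-population divergences involved (<3%) the two differ by <2%.

The population simulator plants a target ratio $r$ by proposing uniform
non-stop single-base changes and accepting synonymous ones always,
nonsynonymous ones with probability $r$; because NG86 normalises by the
same mutational opportunity, the expected estimate equals $r$.  Defaults
(50 sequences × 300 codons, Poisson(15) changes per sequence) give a
single-replicate SD of ~5% on the ratio; the acceptance harness averages
6 replicates.

## Hotspot enrichment

Distances are measured in bp from each end of a locus's coding span to the
nearest covered base of a hotspot interval on the same chromosome; a
chromosome side with no hotspot yields +∞ and the point is excluded (the
published analysis had one such end, leaving 47 points for 24 loci).
Threshold tables are tested three ways — Pearson chi-square, Yates
continuity-corrected chi-square, and a two-sided exact Fisher test computed
by direct hypergeometric summation (every table with probability ≤ the
observed one, with 1e-7 relative tolerance against float ties) — because
the published table does not name its test.  On the printed counts the
Fisher p (0.0012 at the 1-kb threshold) is the closest to the published
0.0015.  An expected-count <5 warning is attached where relevant.

## What the generator emulates, and what it does not

Planted: 0–3 tandem genes per locus (multinomial weights 0.1/0.5/0.3/0.1,
mean 1.4 genes/locus, or explicit counts); per-branch iid divergence on a
star phylogeny (default 4%/branch; optional two-subfamily mode adds a deep
6% split, matching the two major clades visible in real segment trees);
LTR copies individually diverged at 5% (identical copies would make exact
assembly formally impossible — a repeat longer than the read length — and
are also unrealistic); dispersed LTR copies in the unique flanks;
conversion events (Poisson, 0.5/gene) copying 100–2,000-bp tracts between
equal-length paralogs, with class/pseudogene truth re-derived afterwards
(a tract can move a poison ATG or repair a planted stop); repeat
copy-number variation (1–5 exon-3 units, 1–4 exon-6 units); 15%
pseudogenes (premature stop or 1-bp frameshift); 25% five-exon genes.
Unique flanks default to 20 kb because flanking pileups extend
`insert_max` ≈ 8 kb beyond each locus and adjacent-locus pileups must stay
separable (>2×`insert_max`).

Not emulated: indel sequencing errors, quality-score profiles, chimeric
junction-spanning mate pairs, GC bias, transposon insertions near loci (the
main cause of real "complicated" pileups), unequal-length conversion
partners, and real intron/splice-site sequence (annotation is projection-
based, not ab initio).  Passing tests therefore demonstrate correctness of
the algorithms under a clean library model, not robustness to every
real-data artifact; the SAM input path exists so real alignments can feed
the same pileup machinery.

## Problem sizes and numerical choices

The study-scale runs use a 24-locus, ~570-kb genome at 80× (≈150k pairs) —
small enough to iterate on while preserving the geometry that matters
(insert-to-flank ratios, paralog divergence).  Determinism: every sampler
takes a seed; greedy assembly order, clade-label anchoring, DP traceback
(smallest end cell, diagonal-preferring) and consensus tie-breaks are all
fixed and documented.  Degenerate inputs raise errors rather than guessing
(empty panels, zero-coverage genomes, fully masked bait regions, ambiguous
stitches).

## Known limitations

- Copy number saturates at 3; wider arrays flag `gt3_possible`.
- The four-gamete scan cannot identify donor/recipient direction, nor
  detect conversion between segments that leaves clade membership intact.
- Repeat unit counts from wraparound alignment can trade a terminal
  mismatch for a truncation, so `n_full_units` is conservative on highly
  degenerate units; `total_bp` is the stable statistic (and the one the
  original analysis reports).
- The greedy assembler is for single-locus read sets (thousands of reads),
  not genomes; repeats diverged <2% from each other can still collapse.
- p-distance NJ clade splits may differ from maximum-likelihood trees at
  weakly supported genes; supplied newick trees take precedence when given.
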