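# drivefam

Computational dissection of a multicopy **killer-meiotic-drive gene
family** in fission yeast from mate-pair sequencing.

Poison–antidote drive genes (~1.2 kb, 5–6 exons) occur at ~20–24 loci of
0–3 tandem copies, flanked by LTR retrotransposon remnants and near-identical
to one another — short-read assemblies collapse them.  `drivefam`
implements the full analysis chain that works around this:

- **Locus discovery and copy number** — read pairs with one mate matching a
  family-gene panel are collected; the *partner* mates map to unique flanking
  sequence and pile up on either side of each family locus.  For uniform
  inserts on $[a,b]$ and read length $L$, a locus of span $S$ produces
  pileups of expected width $W = S + (b-a) + 2L$, so tandem copy number is
  read off the widest flanking pileup via midpoint decision boundaries
  between $W(1), W(2), W(3)$.  Larger segmental duplications are caught by a
  ~2× coverage scan.
- **Targeted assembly** — unique "orange" bait regions under the pileups
  recruit read pairs, wider "green" regions subtract flank-derived reads,
  and the candidates are assembled with a deterministic greedy
  overlap–layout–consensus assembler, then stitched between the flanks.
- **Annotation and classification** — exon structures are projected from
  exemplar genes through global alignment; pseudogenes are flagged
  (premature stop / frameshift); intact genes with an in-frame ATG within
  ±30 nt of the exon-2 start (the poison-isoform start) are Class 1
  (putative drivers), those without are Class 2 (putative antidote-only
  suppressors), and genes under 55% identity to every exemplar are Class 3.
  Genes are named across isolates by genomic synteny.
- **Nonallelic gene conversion** — genes are cut into eight segments
  (upstream region, intron 1, exons 1–6 with the repeat regions excised);
  per segment, genes are split into two major clades (supplied trees or
  internal neighbour joining on p-distances), and every segment pair gets a
  **four-gamete test**: observing all four clade combinations implies
  recombination between the segments.
- **Intragenic repeats** — the 33-bp (exon 3) and 21-bp (exon 6) degenerate
  tandem repeats are quantified by wraparound dynamic programming against
  the consensus unit, yielding repeat-derived bp, unit decompositions and
  position-frequency matrices.
- **Diversity** — Nei–Gojobori (NG86) $\pi_N/\pi_S$ with stop-excluded site
  counts and stop-avoiding pathway averaging, plus segregating sites and
  haplotype counts.
- **DSB-hotspot proximity** — distances from locus CDS ends to the nearest
  meiotic double-strand-break hotspot, threshold contingency tables, and
  enrichment by Pearson/Yates chi-square and an exact Fisher test computed
  by hypergeometric summation.

A first-class **synthetic-genome generator** (`drivefam.simulate`) plants
all of this structure — tandem genes, diverged LTR copies, conversion
tracts, repeat-count variation, 150-bp mate pairs spanning 5–8 kb inserts —
with exact ground truth, so every step is scored against a known answer.

## Worked example

```python
from drivefam.simulate import FamilyParams, MatePairParams
from drivefam.workflow import discovery_chain
from drivefam.pipeline import score_copy_numbers

fam = FamilyParams(n_loci=24, locus_gene_counts=[0, 1, 2, 3] * 6, seed=1)
run = discovery_chain(fam, MatePairParams(coverage=80), read_seed=2)
rep = score_copy_numbers(run["truth"], run["calls"])
print(len(run["pairs"]), "read pairs,", len(run["calls"]), "loci called,",
      f"accuracy {rep['accuracy']:.1%}")
```

prints

```
150662 read pairs, 18 loci called, accuracy 100.0%
```

24 truth loci, 18 calls: the six zero-gene loci produce no family-matching
reads and hence no pileups — their copy number of 0 is called by absence —
while all 1/2/3-copy loci are recovered exactly.  The same run's pileup
widths average ~4.2/5.7/7.2 kb for 1/2/3-gene loci, bracketing the analytic
$W(n)$ anchors of 4.5/6.05/7.6 kb for this insert geometry.

The numbered scripts under `analysis/` run each stage of the study in order
(discovery, targeted assembly, annotation and synteny naming, four-gamete
conversion scan, repeat quantification, diversity, hotspot enrichment) and
write their tables under `results/`.

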