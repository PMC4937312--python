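# Methods

## System model

The package models a single-gene *trans*-silencing reporter system: an
endogenous five-intron gene on a macronuclear scaffold, a truncated
transgene built from it, and the small-RNA/long-RNA/ChIP readouts used to
characterise silencing.

**Gene and transgene geometry.** Coordinates are 0-based half-open
internally; GFF3 export is 1-based inclusive, BED export 0-based half-open.
A `GeneModel` stores exons in reference coordinates plus the genomic
sequence of its span. A `TransgeneSpec` lists deletions and
foreign-fragment replacements in gene-local coordinates plus a
linearization offset (seeded random filler representing plasmid sequence
retained downstream of the insert). `build_transgene` produces the edited
sequence together with a segment map that is invertible on parent-derived
intervals; artificial junctions are the abutments of non-adjacent parent
coordinates and foreign inserts flanked by parent sequence on both sides.

**Region partition.** `derive_regions` marks parent intervals present in
the construct `primary_capable` and absent intervals `secondary_only`
(disjoint and jointly covering the gene span — verified invariant); foreign
inserts become `foreign` regions on the transgene. A 5' sub-region (the
ND-5' analogue) runs from the transcription start to the first intron; it
is additionally clipped at the first transgene-absent interval so that it
is always transgene-shared. In the default geometry the first deletion
(173–529) starts before the first intron, so clipping keeps the sense-bias
contrast of this sub-region interpretable; without it the sub-region would
mix primary and secondary sequence.

## Synthetic data generator

The generator defines the study conditions; every default below is fixed in
the packaged `data/default_config.yaml` and was chosen from the magnitudes
the system is described with, not fitted to any test outcome.

**References.** One 20 kb scaffold at 72% A+T (the macronuclear composition;
high AT also keeps accidental multi-mapping negligible), with the 1,500 nt
gene (exons 560/175/175/145/145/175, five 25 nt introns with canonical
GT…AG boundaries) embedded at offset 10,000. The default transgene is the
pTI-/− analogue: deletions (173, 529) and (1340, 1500) plus 120 nt of
linearization filler; a pTI-/−K28 analogue is available by adding a
replacement entry. An antisense intron (gene-local 640–665; GT…AG on the
bottom strand) is planted inside exon 2. Auxiliary references: a 2 kb
structural-RNA surrogate (round-1 contaminant), the spliced mRNA (the
coding-sequence annotation used in round-2 mapping), and a 1.2 kb CDS per
feeding gene.

**Small-RNA classes** (per sample, defaults in parentheses): primary reads
from the transgene insert (10,000), exon–exon junction reads from the
spliced mRNA with ≥5 nt overhangs (1,500), intron-overlapping genomic reads
(1,500), secondary reads confined to secondary-only regions (derived, see
below), background reads from the scaffold outside the gene (150,000),
structural contaminants (10,000) and feeding reads from the sample's fed
gene CDS (15,000). Background dominates the library so that the
transgene-derived classes are a realistic single-digit percentage of the
genome-mapped total. Lengths are drawn from a 17–25 nt distribution with
0.70 mass at 23 nt. Antisense fractions: 0.90 in the transgene body, 0.25
in the 5' sub-region (the observed sense bias), 0.95 for secondary and
junction reads (their stricter antisense bias), 0.50 for intron reads
(no clear bias). Quality strings are constant; the analysis never uses
qualities. No sequencing-error or adapter model is included — reads are
exact substrings (or reverse complements) of their origin.

**Secondary-abundance calibration.** The configured secondary fractions
(ND-1: 0.05, ND-2: 0.01) are defined on the quantity the study reports:
23 nt antisense per-base coverage relative to the transgene-covered region.
After drawing the primary and intron classes, the generator counts the
realized mappable 23 nt antisense reads (primary reads spanning an
artificial junction do not map to the endogenous locus and are excluded),
converts to per-base coverage over the parent-derived length, and plants
`round(f · coverage · region_length / 23)` antisense 23-mers per secondary
region, plus proportionally many reads drawn from the length/strand
distribution conditioned on *not* being a 23 nt antisense read. This makes
the configured fraction hold in expectation rather than drift with junction
losses.

**Knockdown samples** are exact thinnings of the control draw: RNG draws
are consumed in a fixed order independent of the multipliers, and each read
is kept with the probability of its class multiplier. The default knockdown
sample reduces all transgene-derived antisense classes (primary, junction,
intron) by 0.2, sense classes by 0.5 and secondary classes by 0.3/0.5 —
a uniform antisense factor means the region-level 23 nt antisense fold
change equals the configured multiplier.

**Long reads** (20,000 × 100 nt): each sense read draws an independent
retention indicator per intron (default 0.10) and is sampled uniformly from
the resulting isoform. A configurable fraction (0.15) is antisense
(bidirectional transcription): reverse-complement reads that retain all
sense introns and splice the planted antisense intron with probability 0.8.

**ChIP Ct table.** Percent-input truths are planted per
(sample, antibody, locus) so that the fully normalized chain (percent input
→ H3 at the locus → reference promoter) takes preset values, including a
4-fold H3K27me3 gain at the 3'-CDS in the transgenic sample. Ct values are
generated by inverting the percent-input formula at amplification
efficiency 2, with small log-normal biological (σ = 0.02 log2 units) and
technical (σ = 0.02 cycles) noise over 3 × 3 replicates.

**Reproducibility.** Each generator stage draws from its own
`SeedSequence((seed, stage))` stream, so adding a stage never perturbs
earlier outputs and identical seeds give byte-identical files.

**What the generator does not emulate** — sequencing errors, adapters,
quality variation, PCR duplication, expression heterogeneity across loci,
piRNA-like populations, genome-wide multi-mapping. Passing tests therefore
demonstrate the correctness of the analytical machinery under the stated
statistical structure, not robustness to platform artefacts in real data.

## Analysis machinery

**Exact matching.** Reads with ambiguous bases are skipped with a warning.
Matching is zero-mismatch on both strands against every reference; an
internal 17-mer position index accelerates lookup and is property-tested
against a naive sliding-window scan. Multi-mapped reads are counted at
every matching locus and carry their multimap count (NH tag in SAM);
reverse-strand reads are stored reverse-complemented with flag 16.

**Two-round mapping and T/K bookkeeping.** Round 1 removes structural
contaminants; round 2 maps to the scaffold, CDS annotation, transgene and
feeding-gene references. T counts reads with a genome-reference hit after
exclusions; K counts reads hitting the sample's knockdown-gene CDS
(membership by exact match to the CDS reference). A library with T ≤ K is
rejected as degenerate. M is computed once per invocation over all supplied
samples.

**Region counting.** An alignment is counted in every region it overlaps by
≥1 nt; sense/antisense is resolved against the region's annotated coding
strand (also for minus-strand genes). Reports are sorted by (reference,
start, strand, read id) for deterministic output. Note that the ≥1 nt rule
lets reads overlapping a region boundary (e.g. intron-5 reads reaching into
the 3' secondary region by a few bases) count in both regions; per-base
coverage measures are essentially unaffected, raw counts of short regions
adjacent to high-coverage features are slightly inflated.

**Junction/intron classification.** A junction read matches the spliced
mRNA across an exon–exon boundary with ≥4 nt on each side *and* has no
exact genomic match (mirroring the 4 bp splice-rate convention; the genomic
exclusion prevents double assignment near intron boundaries). An intron
read matches the genomic sequence overlapping an intron by ≥1 nt. The two
classes are disjoint by construction.

**Long-read alignment.** Model-guided enumeration of all 2ⁿ retain/splice
isoforms (n ≤ 8) on both strands with ≤1 mismatch, rather than general
spliced alignment: the analysis only ever classifies reads against
annotated introns, and de-novo discovery is delegated to the
antisense-intron scan. Search is exact-first (any exact hit makes mismatch
seeding moot); the ≤1-mismatch fallback seeds with read halves (one half of
a 1-mismatch read is always exact). Candidates are collapsed by genomic
blocks; ties break by fewer mismatches, then fewer gaps, then leftmost
start, then plus strand. The tie-break by fewer gaps also resolves reads
ending 1–4 bp inside a retained intron whose incursion happens to match the
next exon: the ungapped interpretation wins. Equivalence with an exhaustive
all-isoform, all-offset search is asserted in the test suite.

**Splice classification.** Per intron: *spliced* iff the alignment has a
gap exactly at the intron (which implies ≥1 nt on both flanking exons);
*un-spliced* iff aligned blocks extend more than 4 bp into the intron from
a boundary; 1–4 bp incursions without a gap, or reads touching only one
flank, are excluded from both counts ("more than four basepairs" is read
strictly: 5 bp triggers un-spliced). The long-read length filter is
likewise strict (>60 nt kept).

**Splice-rate estimator.** Read-level candidate counting is biased toward
un-spliced calls because the two outcomes have different start-position
footprints: a spliced candidate requires the read to cross the junction
(L−1 eligible starts for read length L), while an un-spliced call arises
from any >4 bp incursion from either boundary (L+I−9 eligible starts for
intron length I) — a ≈17% over-weighting at L=100, I=25. The reported
`splice_rate` therefore normalizes each class count by its footprint,
estimating the fraction of *transcripts* spliced at the intron; the plain
read-count fraction is kept alongside as `splice_rate_raw`. Per-intron
rates and their unweighted mean are both reported. Pipeline splice rates
use coding-strand alignments only; antisense (nascent) reads retain sense
introns by construction and are analysed by the antisense-intron scan.

**Antisense introns.** For reads that fail isoform alignment, a seeded
split-alignment looks for a single gap of 18–35 nt whose boundaries read
GT…AG on the read's strand and that does not coincide with any sense
intron; candidates are reported with supporting-read counts and whether
supporters retain the sense introns they overlap.

**Fold changes** are reported as normalized ratio and log2; zero control
counts propagate as NA with a warning rather than being patched with a
pseudocount (an optional pseudocount exists but defaults off).

**ChIP chain.** percent input = 100 · 2^(Ct_input − log2(1/f) − Ct_IP) at
fixed efficiency 2 and input fraction f (default 0.10); modification
signals divide by H3 percent input at the same locus and then by the same
quantity at the reference promoter. Technical replicates are averaged on
the Ct scale (geometric mean of quantities), biological replicates on the
enrichment scale (mean, SD; SD is NA for a single replicate). The chain is
invariant to adding a constant to all Ct values of a sample.

## Problem sizes and tolerances

Simulated scales are chosen so all stochastic checks sit several standard
errors inside their tolerance bands: splice-rate anchors use 20,000–30,000
reads of 100 nt (≥1,500–2,300 candidates per intron; binomial SE of the
per-intron rate < 0.8 pp, of the five-intron mean < 0.4 pp); the default
small-RNA cohort has ≈188,000 reads per sample, giving ≈120 planted 23 nt
antisense reads in ND-1 (the secondary/primary ratio is calibrated, so its
residual spread is well under 0.1 pp) and ≈1,100 23 nt antisense reads in
the knocked-down transgene region (fold-change SE ≈ 0.007). The knockdown
fold-change check allows 0.2 ± 0.03: two binomial σ plus the analytically
expected total-count-scaling composition shift (the knockdown's T−K is
≈6% smaller than the control's at default composition, inflating the
normalized ratio by the same amount).

## Known limitations

* The exact matcher and isoform aligner are O(reads × references) Python
  with string-search inner loops — appropriate for single-gene reporter
  systems and the simulated scales here, not for genome-wide libraries.
* Isoform enumeration is capped at 8 introns (256 isoforms).
* Percent input assumes perfect amplification efficiency; no dilution-series
  efficiency estimation is provided.
* The antisense-intron scan finds a single gap per read and requires exact
  flanking matches (seed length 18); it is a targeted detector, not a
  general spliced aligner.
* Secondary regions shorter than the read length cannot receive planted
  reads; region boundaries adjacent to introns closer than one read length
  will pick up straddling intron-class counts (see region counting above).
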