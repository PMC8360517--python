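# Methods

`paratyper` genotypes families of highly homologous, copy-variable genes
from short paired-end reads. The canonical instance is the human KIR
complex: ~13-15 genes and pseudogenes on 19q13.42 with 50-95% pairwise
sequence identity, extensive allelic polymorphism, and haplotypes that vary
in gene content (absence, duplication, fusion). Reads of 100-250 bp are
shorter than the shared sequence tracts between paralogs, so a read's best
alignment often does not identify its source gene; naive pipelines produce
spurious SNPs and wrong genotypes. The package addresses this with three
ideas: (i) unique-read counting against a *multi-allele* per-gene reference
for copy number, (ii) iteratively *genotype-matched* alignment references
for allele calling, and (iii) a truth-labeled simulator that makes every
misaligned read traceable.

## Database model and preprocessing

An allele database holds, per gene (or *major allelic group*, a set of
alleles treated as an independent gene throughout alignment and
genotyping), full-length allele sequences over `{A,C,G,T,N}` with a
per-position characterization state, a gene-level multiple sequence
alignment (MSA), and exon/intron/UTR feature intervals. Many curated
alleles are characterized for exons only; the unknown remainder is `N`.

**Imputation.** For each allele and each uncharacterized MSA column, if all
rows characterized at that column carry one symbol (a base *or a gap* —
deletions are a characterized state), the allele receives that symbol,
flagged *imputed*; otherwise it stays `N`. Columns with no characterized
row are reported. Imputed positions are tracked separately from native
ones because the two genotyping stages treat them differently (below).
Imputation is idempotent and never touches characterized positions
(property-tested).

**UTR extension.** Allele UTRs (natively ~250 bp 5' / ~500 bp 3' in the
KIR-style input) are padded to 1000 bp from a single per-gene×group donor
sequence (an explicit donor FASTA, or the longest fully characterized
allele of the group). The appended sequence is the donor's outermost
portion, so position *k* upstream of the gene start is the same base in
every allele of a group; exon bytes and the MSA stay consistent. Extension
restores alignment depth over exon 1 and regulatory regions.

**Minimized reference.** Aligning against every described allele is
accurate but slow, so a diverse subset (default 5 per gene/group) is
selected: candidates are (nearly) fully characterized alleles; the most
complete seeds the set; the rest are added greedily maximizing the minimum
pairwise Hamming distance over MSA columns; ties break lexicographically,
so the set is deterministic. Configured *sequestration* alleles —
cross-mapping-prone alleles such as gene-conversion carriers — are
force-included so that their reads have a correct home.

## Alignment and depth tables

The built-in aligner indexes every reference position's 31-mer and queries
read seeds at stride 10; candidate diagonals are verified by vectorized
ungapped mismatch counting with a cap (default 6 per 150 bp read; 10 for
the permissive extractor). Reference `N` matches any base at zero penalty.
*Exhaustive* mode records **every** placement within the cap — the basis of
unique-read classification — while *best* mode keeps the top-scoring
placement set. Seeding at stride 10 with k=31 is provably complete for ≤3
mismatches on 150-200 bp reads (pigeonhole over overlapping seeds) and
near-complete at sequencing error rates beyond that; the suite checks exact
equivalence with a sliding-window scan at cap 3. The aligner is ungapped by
design: the packaged simulator is substitution-only, alleles with
insertions/deletions relative to their group are handled through MSA
projection (below), and a SAM adapter imports placements from any external
aligner when gapped alignment of real data is needed.

A read is *unique* to a group iff all its recorded placements lie on that
group's alleles; otherwise it is cross-mapping. Per group, each read's
best placement is projected onto the *group frame* — the columns of the
extended gene MSA, spanning −1000 (5'UTR) through gene end +1000 — and
accumulated into a depth table with independent counters for A, C, G, T,
deletion (frame columns where the placed allele has a gap) and insertion.

## Copy number

For each sample, the unique-read count of each group is divided by that of
the framework gene (assumed present at two copies in every individual).
Across a batch (floor: 10 samples) these ratios cluster by copy number.
Automatic thresholding sorts the ratios and splits at gaps exceeding
`max(0.015, 0.1·largest_gap, min(5·median_gap, 0.25))`; cuts sit at gap
midpoints. Copy labels anchor at ratio ≈ 0 for copy 0; with multiple
positive clusters the smallest positive center is taken as one copy-unit
(so heavily cross-mapping genes, whose per-copy increment is far below the
nominal 0.5, are still labeled correctly); a lone cluster falls back to the
framework-relative expectation of 0.5 per copy and is flagged, as are
low-separability genes — the automated analog of flagging a gene for
manual thresholds, which can be supplied as overrides with `manual`
provenance. A ratio equal to a cut goes to the higher interval. Copies are
capped at 4 by default. For a complementary pair of allelic groups whose
locus carries a fixed total, `paired_gene_fallback` sets the undeterminable
member from the clean one (`copy_a = total − copy_b`).

## Virtual probes

A probe is a 20-50 nt sequence unique to a target allele/group, verified by
exact substring scan over the full database. A probe *hits* when ≥10
distinct read sequences contain it (either strand). Hits can fire
reference-refinement rules: the named allele is added to the alignment
reference, and within a precedence group multiple simultaneous hits
collapse to the group's single precedence allele. Probe tables are data
(TSV), not code.

## Genotype determination

Depth tables are thresholded into SNP tables: positions with total depth ≥
8 (initial) / 20 (final); at each position up to three variants whose depth
is ≥ 0.25 of the maximum-depth variant. Homozygous calls (one variant) are
scored against every allele of the group (mismatch 1, match 0); alleles
within a buffer of the best score (4 initial / 1 final) are retained. All
allele multisets of size equal to the copy number (capped at 3) are then
scored: per heterozygous position, the mismatch contribution is the
symmetric-difference count between the called variant set and the variants
the combination offers; component homozygous scores are added; minimal
combinations win. In the final stage only score-0 combinations are
accepted — any mismatch leaves the gene *unresolved* rather than forcing a
wrong call.

The two stages differ deliberately. The initial stage compares against the
imputed+extended sequences, counts uncharacterized positions as full
mismatches, and scores all allele-differentiating positions. The final
stage compares against the *native* characterization only (imputed and
donor-extended positions count as uncharacterized), counts uncharacterized
as matches, and scores exonic positions only — where nearly every allele is
natively characterized — yielding a 5-digit (exonic-resolution) call.
Resolution handling: combinations are scored over concrete (7-digit)
alleles; if the best set is not unique it is collapsed by 5-digit name
truncation, and calls are reported resolved at 7 or 5 digits accordingly.

**Iterative workflow.** (1) A gene-content-matched reference (minimized
alleles of present genes; framework always) is aligned exhaustively;
unique reads give initial calls. (2) Two genotype-matched rounds: the
reference is the current typings including ambiguity, plus countermeasures
against self-perpetuating reference bias — any group whose typing does not
perfectly match its aligned SNPs gets its five minimized alleles injected
(anti-stuck); groups represented only by partially characterized sequence
gain a fully characterized allele; probe refinement rules apply. Perfect
unambiguous typings are *locked* and skipped in later intermediate rounds.
(3) The final reference combines locked typings with the most congruent
typing of each unlocked group across all rounds (fewest SNP mismatches,
ties to the later round); a best-placement alignment is made and **all**
aligned reads (not unique-only) feed the final 5-digit determination.
Formatting pads copy-0/1 genes with `null` tokens, merges configured
allelic-group pairs into one column, and renders ambiguity as a sorted
`|`-separated list.

## Synthetic families and simulation

The packaged family emulates the salient structure of the real database at
desk scale — the numbers below are the package's fixed study conditions
(family seed 20210):

* 10 groups / 9 genes of 3.6 kb extended length (1.6 kb body of 4 exons,
  1000 bp UTRs): a framework gene (`FRW1`), a distinct fully characterized
  gene (`DST1`), a presence/absence- and duplication-variable distinct gene
  (`CNV1`), a split locus `DLX` with groups `DLA`/`DLB` at 97% identity,
  sibling pairs at 95% (`HSA`/`HSB`) and 92% (`GXA`/`GXB`), and a
  pseudogene `PSG` that mirrors HSA's alleles outside a 200 bp unique
  block — it shares 82% of its distinct 150-mers with its neighbors,
  reproducing the published hotspot regime, and is copy-determinable only
  through its unique block.
* 8 alleles per group: six exonic classes (distinct 5-digit names, one
  exonic + one intronic tag each), two non-coding 7-digit variants, three
  private substitutions per allele. 3 of 8 alleles per group are masked to
  exons-only (none for `DST1`/`FRW1`). `GXA*0060101` carries a 400 bp
  conversion tract copied from GXB — under a single-sequence reference its
  reads misalign to GXB as spurious unique reads, which is why it is
  sequestered into the minimized set.
* 11 haplotype templates with gene absence, duplication and a large
  deletion haplotype; every template carries the framework gene and exactly
  one of `DLA`/`DLB`. A sample is two templates drawn uniformly with
  replacement; alleles are drawn without replacement per group; remaining
  uncharacterized stretches are patched from a random fully characterized
  allele of the same group before read generation.
* Reads: 150 bp pairs at 50× per allele copy, fragment length normal
  (median 200, sd 40, clipped to [150, 400]), per-cycle substitution rate
  ramping logistically from 0.2% to 0.6% (an analytic stand-in for
  empirical instrument quality profiles; indel errors off). Read names
  encode `sample|allele|fragment`, so truth is recoverable from any read
  and misalignment flows can be tabulated exactly.

What the simulator does *not* emulate: intergenic/haplotype backbone
sequence (reads are drawn per allele), indel sequencing errors, base-quality
variation, novel (undescribed) alleles, and coverage biases such as GC
effects. Consequently, passing recovery tests demonstrates the method's
logic under faithful homology/structure conditions, not robustness to
library artifacts or novel variation on real cohorts — the published
validation of those aspects used real reference cohorts that require
private data.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open internally, 1-based closed in file
interfaces. Determinism throughout: all randomness flows from explicit
seeds; selection and scoring ties break lexicographically; identical
config+seed reproduces byte-identical FASTQ and TSV. Copy >3 groups are
scored at the copy-3 cap with a warning; copy-0 groups skip alignment and
emit null genotypes; groups with copy >0 but no aligned reads are reported
unresolved with a reason. Empty inputs yield empty, well-formed outputs.

## Problem sizes

The default cohort used by the test suite and the acceptance script is 50
samples (~10-11k read pairs each at 50×), processed end to end in roughly
7-8 minutes on one CPU; the toy instances behind the oracle tests
(sliding-window alignment scan, brute-force combination enumeration,
k-mer set intersection) are sized so each oracle runs in seconds.
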