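# Methods

`pausescape` re-implements, as tested library code plus analysis drivers,
three genomic/morphometric analyses around CHD7 loss in neural
differentiation: (1) an RNAPII pausing-index meta-analysis over genes ranked
by CHD7 occupancy, (2) an integrated differential chromatin-accessibility /
nascent-expression analysis with "doubly significant" gene classification,
and (3) Sholl-based neurite morphometry. A synthetic-data module generates
inputs with the exact statistical structure these analyses assume, with
recorded ground truth, so every stage is exercised without external
sequencing data.

## Coordinate and coverage conventions

All interval arithmetic is 0-based half-open (BED convention); 1-based
formats are converted at the file boundary. Coverage tracks store read
5'-end counts per base, so "reads in a region" is an exact array sum and
RPKM — reads / (region kb x mapped reads / 10^6) — is testable by
construction. Chromosome names match verbatim (no "chr" aliasing). SWC
traces parse z and radius but ignore them: the morphometry is planar,
matching 2-D image tracing.

## Pausing-index pipeline

Genes first pass an expression filter (FPKM >= 1.0 and length > 750 bp,
boundaries as stated), then an RNAPII-binding filter (TSS-window RPKM > 1.6
and body-window RPKM > 0.5, both strict). Windows are taken in transcription
direction: the TSS window spans -50..+200 bp around the TSS and the body
window +500 bp to the TTS; on the minus strand both windows mirror exactly.
Strand-awareness is the only defensible reading of "-50/+200 around the
TSS" even where descriptions omit strand.

Surviving genes are ranked by CHD7 occupancy, measured as RPKM over the full
annotated gene territory ("throughout the gene body" read as the whole gene;
a `chd7_occupancy_region="body_window"` option restricts to the +500..TTS
window instead). Ties break by `gene_id` for reproducibility. The top and
bottom `k = 500` genes form the high- and low-CHD7 groups; the pausing index
is TSS RPKM / body RPKM per gene, and the groups are compared with a
two-sided two-sample Wilcoxon rank-sum test.

Metagene profiles average each gene's TSS->TTS coverage into 150 equal-width
bins (transcription direction), normalize each gene's bin vector to mean 1,
then average across genes. Normalization is selectable
(`per-gene-mean` (default) | `per-gene-sum` | `none`); per-gene mean
normalization keeps deep genes from dominating the average while preserving
profile shape. Genes with zero total coverage are excluded from the average
and reported via a warning. The analysis driver runs the pipeline per RNAPII
track and averages bin profiles across tracks, mirroring a meta-analysis
over several ChIP-Seq datasets.

## Differential counts and integration

The common ATAC peak set is the coalesced union of the two genotype peak
sets; book-ended (touching) intervals merge by default (bedtools semantics,
switchable). Read starts are counted per replicate inside each merged peak;
overlapping peaks are a hard error because assignment would be ambiguous.

Normalization uses median-of-ratios size factors (per-feature geometric-mean
reference; the median ratio over features positive in every sample).

The differential test is a deliberately simplified negative-binomial Wald
test, not a DESeq2 clone: per-feature method-of-moments dispersion
(var = mu + alpha mu^2) pooled across groups with a 1e-8 floor, moderated by
taking the elementwise maximum with the across-feature median dispersion;
log2 fold change log2((mu2 + 0.5)/(mu1 + 0.5)) on normalized group means
(pseudocount 0.5 keeps the ratio finite and is configurable); delta-method
standard error; two-sided normal p; Benjamini-Hochberg FDR across all tested
features. The moderation step exists because with three replicates per group
the raw per-feature moment estimate is noisy enough to inflate the null
rejection rate to ~11% at alpha = 0.05; sharing dispersion information
across features — the same idea DESeq2 implements with empirical-Bayes
shrinkage — restores ~5% while leaving the normal reference intact
(verified against a known-dispersion simulation, which is calibrated at
5.1%). There is no outlier refitting and no fold-change shrinkage.

Peak annotation assigns each peak the gene whose TSS is nearest the peak
midpoint (ties -> smaller `gene_id`) and exactly one class with precedence
promoter > exon > intron > downstream > distal_intergenic. The promoter is
1000 bp upstream to 1 bp downstream of the TSS in transcription direction;
downstream means within 3000 bp past the TTS. 5'/3' UTRs are collapsed into
the exon class. Promoter-class peaks are paired with their gene's expression
result — one record per peak, so a gene with several promoter peaks (several
isoform TSSs) contributes several records. A pair is "doubly significant"
iff both FDRs are < 0.05, concordant iff the two log2 fold changes share a
sign. Kendall's tau-b (tie-corrected, normal-approximation p) measures the
association between the two fold-change axes over all peak/gene pairs (a
per-gene collapse is a caller-side groupby; all pairs is the default).
GO-style enrichment is a hypergeometric upper tail per term against the
expressed-gene background with Bonferroni correction over the terms tested;
the term map is caller-supplied.

## Morphometry

Sholl circles are centered on the soma at radii 10, 20, ... um, out to the
largest multiple of the step reachable by the arbor (a farther circle can
never be crossed; the worked convention counts a straight 35-um neurite as
crossings (1,1,1) at radii 10/20/30). Crossings are analytic circle-segment
intersection points: a quadratic in the segment parameter, roots counted in
(0, 1] so a node exactly on a circle is attributed once (to its incoming
segment), and a tangent touch counts once. A dense-sampling oracle
(0.01-um steps along each segment) verifies this exactly on random traces.

Scalar metrics: longest neurite = maximum root-to-tip path length; total
length = sum of segment lengths; primary neurites = soma children; "total
number of neurite branches" is implemented as the branch-point count
(non-soma nodes with >= 2 children) — terminal-branch counting is the other
reading of that phrase and can be derived from the trace, but branch points
is the reported column. Scalar metrics use unpaired two-sided t-tests; Sholl
curves use a balanced two-way fixed-effects ANOVA (genotype x radius with
interaction). Whether the original Sholl ANOVA treated radius as a repeated
measure within neuron is not stated; the fixed-effects implementation is an
approximation that ignores within-neuron correlation.

## Statistical primitives

All tests are two-sided. The Wilcoxon rank-sum test uses midranks,
enumerates the permutation distribution exactly for combined n <= 12, and
otherwise uses a normal approximation with tie-corrected variance and
continuity correction. Kendall's tau-b uses the standard tie-corrected
variance for its normal-approximation p (no exact permutation). The
hypergeometric upper tail is summed in log space. Holm-Sidak and BH
adjustments are step-down/step-up with enforced monotonicity, capped at 1,
returned in input order. The two-way ANOVA accepts balanced designs only;
unbalanced data is a hard error rather than a silently different
sum-of-squares type.

## Synthetic data: what it emulates and what it does not

Coverage tracks use a Poisson read-start model: independent Poisson counts
per base at rate lambda_tss inside the TSS window and lambda_body over the
rest of the gene territory, so the expected pausing index is exactly
lambda_tss/lambda_body and RPKM estimates concentrate around
lambda x 10^9 / total_reads. Defaults place 1000 genes (lengths
1.5-4 kb, >= 2 kb gaps, random strand, 1-5 exons) in two equal CHD7 groups
with (lambda_tss, lambda_body) = (6, 4) and (6, 1) — true pausing indices
1.5 (high CHD7) and 6 (low CHD7), TSS depth >= 5 reads/bp — and CHD7
occupancy 5.0 vs 0.2 reads/bp over gene bodies.

Count matrices are negative binomial (dispersion alpha = 0.05, base mean
100) for two genotypes x 3 replicates, the replicate structure of the
modeled experiments; a fraction (default 0.3) of genes receives a
shared-sign log2 fold change of magnitude 2 in both assays, each gene's
promoter peak placed inside [TSS-1000, TSS+1). The NB choice for the
nascent-RNA counts is an assumption of this emulation (it is what the
differential machinery models), not a claim about any original dataset.

Neurons grow as planar binary-branching trees: primary neurites (2-4)
leave the soma at jittered evenly spaced headings; segments draw lengths
uniformly from 10-40 um, perturb heading, and branch with probability 0.3
(genotype comparisons use 0.6 vs 0.2) down to depth 4. Self-intersection is
allowed; Sholl counts are well-defined regardless.

None of the generators model fragment-length, GC or mappability bias,
read-level error, isoform structure beyond exon blocks, or 3-D arbors.
Passing tests therefore demonstrate correctness of the *computations* under
the stated models — filters, window arithmetic, ranking, test statistics,
geometry — not robustness to artifacts of real sequencing or imaging data.

Every generator is deterministic given its seed; independent per-generator
streams (seeded via a stable CRC of the stream name) keep one stage's draws
from shifting another's.

## Problem sizes and numerical choices

The shipped drivers and checks use 1000 genes for the pausing analysis
(500 per CHD7 group), 2000 features for the count analyses, and 20 neurons
per genotype — sizes chosen so each simulated analysis carries the designed
effect structure at desk scale while every run completes in seconds.
Degenerate inputs fail loudly rather than silently: zero-total-read tracks,
genes shorter than the body offset, overlapping count peaks, unbalanced
ANOVA cells, constant Kendall inputs and zero-variance unequal-mean t-tests
are all errors.

## Known limitations

- The differential stage approximates, but is not, DESeq2: no trended
  dispersion prior, no LFC shrinkage, no Cook's-distance outlier handling.
- Kendall's p is asymptotic; for n < ~10 prefer the exact Wilcoxon-style
  enumeration (not implemented for tau).
- The Sholl ANOVA ignores within-neuron correlation across radii.
- Genome-scale published figures (e.g. 121,161 combined peaks, 6,122
  differentially expressed genes, tau = 0.11) derive from raw sequencing
  data that is not modeled here; the simulations mirror the *direction and
  structure* of those findings, not their magnitudes.
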