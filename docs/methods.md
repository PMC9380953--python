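# Methods

`blastomics` reimplements, as a tested library, the analysis stack used
to compare spindle-transfer (ST) blastocysts against ICSI-fertilized
controls with single-cell triple omics: transcriptome (UMI counts), DNA
methylome (per-CpG bisulfite counts with lambda spike-ins), and genome
(copy number from two independent layers). This note records the models,
the parameters that matter, and the choices made where the procedure was
genuinely open.

## Transcriptome preprocessing

Cells detecting fewer than `min_genes` genes (default 4,000; a gene is
detected when its UMI count is > 0) are removed. Counts are normalized to
`ln(TPM/10 + 1)`, where TPM is counts-per-million of the cell's total
UMIs — UMI counts already count transcripts, so no gene-length term
enters. Genes are then kept only when their normalized value exceeds 1 in
strictly more than 3 cells. Both strictness choices follow the rule's
wording ("fewer than", "more than"); the boundary cases are pinned by
tests. Pipeline order is fixed: cell QC → normalize → gene filter.
Mitochondrial fraction is not a filter criterion (no threshold is
defined for it); embeddings (PCA → t-SNE/UMAP) are delegated to scanpy
with the only owned contract being determinism under a fixed seed.

## Lineage assignment and scores

Cells are partitioned into three clusters (Leiden on the PCA neighbor
graph, searching the resolution for exactly three communities; k-means
fallback). Each cluster takes the lineage whose high-confidence marker
set — SOX2/NANOG/POU5F1 (EPI), GATA4/SOX17/FOXA2 (PE), GATA2/GATA3/CDX2
(TE) — has the highest mean expression over the cluster; exact ties are
an error requesting manual curation rather than a silent coin flip.

Lineage-specific signatures come from one-vs-rest two-sided Wilcoxon
rank-sum tests on genes detected in ≥ 25% of cells on either side;
signature membership requires Bonferroni-adjusted p < 0.05 and positive
log2 fold change (thresholds for the signature search are not pinned by
the study's DEG rule, which applies to the ST-vs-ICSI contrast; these
defaults are Seurat-conventional and configurable). A cell's raw lineage
score is the mean normalized expression of the signature genes; scores
are min–max rescaled per lineage across all cells onto [1, 100] via
`x → 1 + 99·(x − min)/(max − min)`, and ternary coordinates divide each
scaled score by the sum of the three. Rescaling across all cells (not
within treatment arms) keeps the two arms comparable on one scale.

## Group comparison

DEGs per lineage: two-sided Wilcoxon rank-sum on genes detected in
≥ `min.pct` (0.25) of either group's cells, Bonferroni correction over
the tested genes, and a call only at |log2FC| > 1 with adjusted
p < 0.01. The fold change uses back-transformed means with a pseudocount
of 1, `log2((mean(e^x − 1) + 1)/(mean(e^y − 1) + 1))` (Seurat-style); the
originating rule does not define its FC formula, so a ln-scale
mean-difference variant is available via `fc_method`. For groups of ≤ 8
cells each the Wilcoxon p-value is computed by full enumeration of the
permutation null (valid under ties); larger groups use the tie-corrected
normal approximation with continuity correction.

Regression similarity fits per-gene mean(ST) against mean(ICSI) over
commonly expressed genes (detected in ≥ 1 cell of each group within the
lineage) and reports R². Down-sampling repeats this after sampling cells
without replacement per group.

Embryo sex: Mean_X and Mean_Y are the mean normalized expression of the
X- and Y-linked gene sets (taken from the gene annotation) over the
embryo's cells; Mean_X/Mean_Y > 2 is female, ≤ 2 male. Mean_Y = 0 gives
an infinite ratio (female), including the degenerate case where no
Y-linked gene survives gene filtering because every embryo is female.

Sex-ratio simulation: the ST arm is re-composed by keeping all of its
male embryos and adding n female embryos; the DEG test is rerun within
TE against the full control arm and the fraction of DEGs that are X/Y
linked is averaged over replicate draws of the female subset. Varying the
female count (the abundant sex) is the only composition scheme feasible
when males are scarce, and it reproduces the qualitative optimum at the
composition closest to the control arm's sex ratio.

## Methylome

Per-cell QC requires a lambda spike-in conversion ratio strictly above
99% (every methylated lambda read is a conversion failure) and ≥ 2×10⁶
CpG sites covered by ≥ 1 read; on the synthetic toy genome the site floor
scales with the simulated genome (see below). The per-cell level is the
unweighted mean of site levels C/(C+T); the per-embryo level is the
unweighted mean of its cells' levels.

Tile methylation pools raw read counts of all member cells into 300-bp
tiles (0-based, half-open, aligned to multiples of 300) — a
read-weighted level, deliberately not a mean of cell levels. A tile
covered in both groups with pooled depth ≥ 5 reads per group (a floor
added here; without it single-read tiles satisfy any threshold rule) is a
DMR when its level is < 10% in one group and > 40% in the other. DMR
frequency per element class = (DMRs overlapping ≥ 1 element) / (number of
elements). Metaprofiles scale each feature body onto 100 bins with 50
bins per 15-kb flank, reversing minus-strand features.

Pseudotime joins the study cells' tile matrix with staged reference
samples, keeps tiles covered in ≥ 80% of samples, mean-imputes the rest,
and reads PC1 as pseudotime ("tiles covered by at least one sample"
leaves missing entries PCA cannot consume; the coverage threshold and
imputation are the configurable resolution). The PC1 sign is fixed so the
earliest reference stage is farthest from the reference blastocysts:
pseudotime decreases along global demethylation, and a methylation-
retaining (delayed) group shifts toward earlier stages, tested one-sided
by rank sum.

## Copy number from expression

Per gene, the CNV score is the mean relative expression of the 50 genes
upstream and 50 downstream (same chromosome, truncated at ends, self
included), then divided per gene by the mean score across all cells —
all cells are the reference baseline, as no designated normal cells
exist. Smoothing operates on the linear scale `e^x − 1` of the
normalized values: a ratio of ln-scale window means compresses a 1.5×
dosage to ~1.05–1.15 depending on expression magnitude and admits no
fixed calling threshold, while linear ratios sit at ~1.5/0.5 regardless
of depth. Calls: per cell and chromosome, the longest contiguous run of
genes beyond the gain (1.15) or loss (0.85) threshold, at least 20 genes
long; kept when its bp span exceeds 60% of the chromosome (gene-count
fraction available via `span_units`) and ≥ 3 cells in the cohort carry a
same-direction call on that chromosome; an embryo-level CNV additionally
needs ≥ 3 supporting cells in that embryo. Cells without retained calls
are euploid; CNV frequency is the per-embryo aneuploid fraction. The
gain/loss thresholds are not pinned by any published value and are
required, documented configuration. Sex chromosomes are excluded from
calling by default: under all-cell-mean normalization, sex dosage — not
aneuploidy — produces whole-X/whole-Y deviations in every cell of the
minority sex.

Dosage integration stays on the ln scale: each chromosome's mean
normalized expression is divided by the cell's mean over its copy-2
chromosomes, so euploid chromosomes sit at 1 and gains/losses show the
(log-compressed) shift.

## Copy number from bisulfite read depth

Reads are counted in consecutive 1-Mb windows. Cells whose median
per-window count is below 500 are removed, then windows whose median
per-cell count (over surviving cells) is below 500. Each cell is divided
by its total read count; each window by its median over control cells
(a named control embryo, every cell, or — by default — the embryo whose
cells have the flattest depth-normalized profiles); the result is scaled
so the control median sits at copy 2. Rounding raw ratios (≈ 1) would
collapse copies 2 and 3, so the scale-to-2 step precedes smoothing:
each window becomes the nearest integer of the mean over the surrounding
100 windows (50 per side, self included, truncated at chromosome ends;
.5 rounds away from zero). Cross-layer concordance compares
chromosome-level states (modal copy vs expression calls) on shared
cells, excluding sex chromosomes (expected copy differs by sex).

## Synthetic cohorts

The generator emulates the study's statistical structure on a toy genome
of five 30-Mb autosomes plus an 8-Mb X and 5-Mb Y, with sex chromosomes
gene-poor (0.5× and 0.15× autosomal density) as in real genomes.
Defaults: 8 embryos per arm × 30 cells, 2,000 genes, lineage mix
15/10/75% (EPI/PE/TE), ~190,000 UMIs per cell, negative-binomial counts
with variance μ + 0.1·μ² (no generative model is prescribed by the
study; NB is the standard UMI model). Lineage identity acts through 40
high-confidence markers at 5× plus a diffuse 300-gene program at 2× —
real lineages differ in thousands of genes, and without the program the
handful of X/Y-linked genes would dominate transcriptome distance and
clustering would split by sex. Females carry 2× X dosage and silent Y;
males express both at comparable means, guaranteeing the Mean_X/Mean_Y
rule separates. Aneuploidy is planted as mosaic blocks: an affected
embryo shares one whole-autosome event (copy 1 or 3) across ≥ 3 of its
cells, as mitotic-origin mosaicism clusters within embryos — which also
makes the ≥ 3-cell denoising rule satisfiable at the default 20% (or the
evaluation's 5%) aneuploid fraction. The two arms can be given different
female fractions to emulate the compositional sex imbalance that
confounds sex-linked DEG calls.

The methylome layer covers a contiguous region at the start of each
chromosome (default 60 kb → 200 tiles/chromosome, 5 CpGs per tile,
Poisson depth with mean 2 reads/site/cell). Baseline tile levels are
Beta(1.5, 3.5) (mean ≈ 0.3, blastocyst-like); CGI tiles are Beta(1, 19)
(≈ 0.05); planted DMR tiles alternate (ST 0.50 / ICSI 0.05) and the
reverse; the TE-ST offset (default +0.024, matching the scale of the
reported group difference) shifts non-DMR TE tiles in the ST arm.
Lambda spike-ins are Binomial(depth, 1 − conversion) at conversion
0.995. Bin counts are Poisson around 1,000 reads/window scaled by
copy/2, sex-chromosome dosage, and a lognormal per-cell depth factor.
All randomness derives from one root seed through
`numpy.random.SeedSequence.spawn`; equal seeds give byte-identical
cohorts.

What the generator does **not** emulate: doublets and ambient RNA,
read-level bisulfite error profiles, GC/mappability bias in bin counts,
sub-chromosomal CNV breakpoints, and biological covariance between the
layers beyond the planted truth. Passing tests therefore demonstrate
that each procedure recovers the signals it is defined to recover under
its stated noise model — not robustness to artifacts absent from the
simulation.

## Problem sizes and numerical choices

The test suite and the acceptance script size their cohorts at desk
scale: the CNV-recovery cohort is 10 embryos/arm × 30 cells with 5%
aneuploid cells; DEG error control uses 20 seeded null cohorts of 120
cells each; sexing uses 20 cohorts of 6 embryos; the methylome blocks
use 50–100 tiles per chromosome at deep (10×) site coverage where the
check is about thresholds rather than sampling noise. QC floors that are
absolute numbers on the human genome scale with the toy genome
(`RunConfig.toy()`: 1,000 detected genes, 3,000 covered CpGs); every
relative threshold and analysis rule is unchanged. Degenerate inputs are
errors, not silent results: zero-total cells at normalization, constant
raw lineage scores at rescaling, constant group means at regression,
all-removed matrices at the median filters. Exact-oracle comparisons
(brute-force DMR scan, window means, median filters, rank-sum
enumeration) hold to 1e-12.
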