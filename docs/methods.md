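# Methods and design notes

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical decisions a maintainer would want to know.

## Synthetic study design

The generators emulate the design of the real study: two cell types
(PGC, soma) × five stages (256-cell, high, dome, 10-somites, prim-5) ×
two replicates, on a scaled-down genome of 25 numbered chromosomes plus
a mitochondrial contig (1 Mb and 17 kb by default). One integer seed
determines every output; each generator draws from an independent child
stream of that seed, so adding a generator never perturbs the others.

**Transcriptome.** Genes belong to five classes (default mixture:
maternal 35%, zygotic 20%, maternal-zygotic 25%, germ-plasm-stabilized
5%, housekeeping 15%). Class trajectories are relative-expression
multipliers over the stage series: maternal transcripts decay,
maternal-zygotic and housekeeping stay level, zygotic genes start below
2 TPM and rise ten-fold at the second stage, and germ-plasm-stabilized
transcripts persist in PGCs while decaying sharply in soma after the
onset of zygotic transcription. Zygotic baselines are drawn in true TPM
units against the known stage-1 library total, so the "below 2 TPM
before activation" property holds by construction rather than on
average. Counts are negative binomial with variance μ + αμ² and a
single dispersion α = 0.05 shared across genes (α = 0 gives Poisson);
library size defaults to 10⁶. ERCC-like spike-ins (92 species,
log-uniform over six orders of magnitude, the shape of the real mix)
are appended with Poisson counts proportional to concentration ×
length, totalling ~2% of the library.

**Introns.** Per gene, stage and intron, a total read weight
W ~ Poisson(60) splits binomially into intronic depth D (probability =
the gene's nascent fraction at that stage) and spliced support
S = W − D, with SS5 = S and SS3 a thinned copy, so the realized IR
ratio D/(max(SS5,SS3)+D) = D/W has expectation equal to the nascent
fraction. Nascent fractions rise after the first stage for all
zygotically transcribed classes (0.5 for zygotic and
germ-plasm-stabilized, 0.3 maternal-zygotic, 0.15 housekeeping) and
stay at 0.02 for purely maternal transcripts.

**ATAC.** Background fragments are uniform over the numbered
chromosomes (200,000 per sample by default; ~3% placed on the
mitochondrial contig and ~5% given mapping quality below 10 to exercise
the filters). Planted 400-bp elements receive Poisson extra fragments
at 10× the local background rate in the samples where their class is
active: `pgc_open`/`soma_open` in both replicates of the matching cell
type, `shared` everywhere, and `irreproducible_noise` in one randomly
chosen replicate of one cell type only — the structure the IDR step
exists to remove.

**Methylation.** Promoter-like regions sit at 5% methylation in both
cell types; enhancer-like regions stay at 80% in PGCs and fall linearly
to 20% across the assayed stages in soma. CpG sites are a property of
the region (the same positions are surveyed in every sample, as in a
real bisulfite assay); coverage is Poisson(15), so a tail of sites
falls below the 6-read cutoff, and methylated counts are binomial
around the region trajectory.

**Granules.** Each cell is a 96×96 mask with a rectangular nucleus and
2–5 axis-aligned square granules placed either flush against a nucleus
edge (with probability 0.7 for control, 0.2 for the knockdown-like
condition) or detached by more than one pixel. Axis alignment makes
the expected contact ratio exact: side / total granule area for a flush
granule, 0 for a detached one.

**What the synthetic data does not emulate.** Sequence content and
mappability, GC and fragment-length biases, per-gene dispersion
variation, spatial autocorrelation of methylation, partial (less than
full-side) granule contact, and irregular hand-drawn region shapes.
Passing tests therefore demonstrate that the *computations* are correct
and calibrated under their stated models, not that the models capture
every property of the real assays.

## Expression

Size factors are median-of-ratios against the per-feature
geometric-mean pseudo-reference, using only features nonzero in every
sample, then rescaled to geometric mean exactly 1 so factors are
comparable across subsets. The zygotic rule uses strict inequalities
(TPM < 2 before activation, strictly rising after); ties are
not-zygotic. ERCC RPKM uses the whole table's column sum (spike-ins
included) as the denominator, and calibration is plain OLS in
log10–log10 space on spike-ins with RPKM ≥ 1; inversion
(y − a)/b exposes absolute-concentration prediction.

The differential test is deliberately simpler than a full
shrinkage-based GLM: per-feature Wald z under a negative-binomial model
whose single dispersion is estimated by a through-origin regression of
(pooled within-group variance − q·mean(1/s)) on q², pooled across all
features — with thousands of features the shared dispersion is nearly
noiseless, so the known-variance z test calibrates (null type-I error
≈ 0.05 at nominal 0.05 with 3 + 3 samples). The fold change uses a
pseudocount of 0.5 to handle zero means; BH is the multiple-testing
correction throughout. Irreproducible single-replicate signal is not
this test's job to catch at n = 2: in the pipeline, differential
accessibility runs on the IDR-filtered element set, mirroring the
analysis order of the real study.

## Intron retention

Gene-level IR is the coverage-weighted mean of intron ratios with
weights max(SS5, SS3) + D (each intron's own denominator), which
collapses to Σ D / Σ weights; genes whose introns carry no reads are
absent rather than zero. The subgroup test draws each null gene set
without replacement within a draw, independently across draws, from all
genes with defined IR at both stages; the two-sided p uses the add-one
correction and can never be zero. The comparison of |null| against
|observed| uses a 1-part-in-10¹² tolerance so float summation order
cannot break exact ties (the degenerate subgroup-equals-background case
returns p = 1 exactly). The statistic is the subgroup mean by default;
a median option exists. A Welch t test of subgroup post vs pre values
is reported alongside.

## Chromatin

**Cut sites.** Coordinates are 0-based half-open everywhere. A
fragment yields cut sites at start + 5 and end − 4; fragments whose
corrected end does not exceed the corrected start (shorter than 10 bp)
are skipped and counted. Extension windows (2·ext + 1 bp) are clipped
at chromosome ends; the identity "total signal = 2 × retained fragments
× window length" holds exactly away from boundaries. No duplicate
removal is performed, by design.

**Peak scan.** Windows are scored by the number of cut-site *points*
they contain against a single genome-wide Poisson rate
λ = library/genome × window (the no-local-lambda regime). Scoring the
extended *coverage* sum instead would inflate the variance
(2·ext + 1)-fold and destroy the Poisson calibration — the extension
exists for visualization and signal extraction, not for testing.
Qualifying windows that overlap or abut merge into peaks; the peak
score is −log10 p of its best window, fold enrichment is
observed/expected, and the summit is the coverage maximum. The default
effective genome size is the zebrafish mappable genome (1.412 × 10⁹);
synthetic runs pass the actual track size.

**IDR.** Midrank quantiles u = rank/(n+1) are mapped through the
inverse of the model's own marginal mixture CDF; the reproducible
component is bivariate normal (μ, σ, ρ) and the noise component is
standard bivariate normal with ρ = 0. Parameters are estimated by
maximizing the rank-copula likelihood — the joint mixture density
divided by both marginal mixture densities (the Jacobian of the
transform). The Jacobian matters: without it the objective can be
inflated without bound by concentrating the marginal, and a naive
fixed-point EM on the uncorrected pseudo-likelihood empirically
collapses σ and disagrees with any grid search. The corrected
likelihood is maximized by bounded L-BFGS-B from (p, ρ, μ, σ) =
(0.5, 0.8, 1, 1) with a small multi-start (a μ ≈ 0 local optimum that
soaks up overall rank correlation exists), inside bounds p, ρ ∈
[0.05, 0.95], μ ∈ [0, 5], σ ∈ [0.5, 3] that keep the component away
from the degenerate diagonal ridge σ√(1−ρ²) → 0. Local
irreproducibility is the posterior noise probability; global IDR at
rank i is the mean local value of the i best peaks. On data drawn from
the model with p = 0.6, ρ = 0.8 at n = 2000 the fit recovers p within
±0.03; on independent replicates nothing passes at 5%.

**Cascade.** Peak matching across replicates is greedy one-to-one by
descending score with ≥ 1 bp overlap; the element interval is the
union span of the matched pair. The IDR fit receives matched pairs
plus peaks unique to either replicate at a floor pseudo-score in the
other (the usual convention — without an irreproducible component the
mixture is unidentifiable); only matched pairs can pass. With fewer
than 20 matched pairs, or no unmatched peaks at all, every matched pair
is kept. The TSS filter is inclusive and edge-to-point: an element is
dropped when the distance from its closest covered base to any TSS is
≤ 500 bp. Width filters (≤ 1 kb) apply per condition and again after
the union merge; touching (bookended) intervals merge. Every step logs
its survivor count per condition.

**Signal, PCA, SOM.** Element signal is the extended cut-site coverage
summed over a 601-bp window on the element midpoint, divided by library
size (invariant to uniform duplication of a sample's fragments). The
log transform is log(signal × 10⁶ + 1) so the pseudocount has a stable
per-million meaning. PCA is an SVD of the column-centered matrix
embedding the samples; SOM requires the additionally row-centered
matrix (log-fold-change profiles) and runs as a batch map on a 3×3 grid
(nine clusters): codebook initialized from random data rows, Gaussian
neighborhood decaying geometrically from half the grid dimension to
0.25 over 50–100 epochs. The quantization error is recorded per epoch;
it rises once at the first epoch (the wide neighborhood pulls the
random-row codebook toward the data mean) and is non-increasing
afterwards, which is what the trace tests assert. Because nine units
refine three planted patterns, pattern-recovery tests read the map out
two-level: units are agglomerated into three groups by their codebook
vectors before computing the adjusted Rand index.

**Annotation.** Element midpoints are labelled with precedence
promoter (within 1 kb of a TSS, either side) > exon > intron >
intergenic; the signed TSS distance is oriented by the TSS strand.
Strand is otherwise ignored.

## Methylation

The coverage filter (≥ 6 reads) runs at load time; the percent column
is recomputed from counts and discrepancies beyond 0.5 points warn
(counts win). Region methylation is the coverage-weighted mean over
contained CpGs, which makes it exactly recombinable across region
splits. Differential testing pools replicates within group by
position, then applies a two-sided Fisher exact test per CpG with BH
correction; a CpG is differential at q < 0.01 and ≥ 25 percentage
points difference (common per-CpG exact-testing conventions; both
exposed in config). The headline statistic is differential CpGs over
matched CpGs.

## Granules

Areas are pixel counts × spacing²; perimeters count exposed pixel edges
(4-neighborhood; the image border is exposed) × spacing. A granule
boundary edge is contact when the pixel across it lies within the
adjacency distance (default 1 px, i.e. the neighbor is nucleus). Each
granule's ratio divides its contact length by the *total* granule area
of its cell — granules in a cell share a denominator — and a per-cell
Σcontact/Σarea summary is also reported. Ratios scale as 1/spacing
(length over area); masks are unitless unless a spacing is given.
Condition comparisons use the two-sample Wilcoxon rank-sum test at
α = 0.05; conditions with fewer than 3 observations are flagged
untestable rather than tested.

## Pipeline and reproducibility

`run_end_to_end` executes simulate → expression → intron retention →
chromatin → methylation → granules, writes intermediates in plain-text
standard formats (counts TSV, intron TSV, BED6 fragments with MAPQ in
the score column, narrowPeak, GTF, bismark coverage, text mask grids),
and emits a JSON report echoing the seed, the design, every analysis
constant and per-stage truth-recovery metrics. A failed stage marks
itself failed and skips its dependents. Identical config and seed
reproduce the report bit for bit. Default problem sizes (2,000 genes,
240 elements, 25 × 1 Mb genome, 200,000 background fragments per ATAC
sample, 2,000 CpGs, 30 cells per condition) keep a full run under a
minute on one CPU while leaving every statistical stage well powered;
the chromatin stage processes one sample's track at a time to keep
memory flat.
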