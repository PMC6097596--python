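# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `methylomap`, in the order data flows through the
pipeline.

## Coordinates, destranding and input dialects

All internal coordinates are 0-based half-open; GFF3/GTF (1-based closed)
and Bismark-style CpG reports (1-based positions) are converted at the I/O
boundary, so an interval `[a, b]` in GFF becomes `[a−1, b)` with its length
preserved.  A CpG dyad is keyed by the position of its plus-strand C;
destranding merges a plus-strand call at `p` with a minus-strand call at
`p+1` by summing counts, conserving genome-wide totals exactly.  Destranding
is keyed purely on that positional adjacency so call tables suffice; a
genome sequence, when supplied, is used only to warn about non-CG context.
Exons are numbered in transcription order (exon 1 is 5′-most on either
strand), which is the frame in which "exon 1" versus "exons 2–4" semantics
are defined throughout.  1 kb flanks are clipped at contig edges rather
than discarded.

## QC filter chain

The multi-sample site filters run in a fixed order — SNP masking, coverage
outliers, low coverage, uninformative sites — and each stage reports
per-rule removal counts that reconcile exactly (`input = removed + output`).
SNP masking removes a dyad when a variant with quality strictly above 50
falls on either of its two bases; masking precedes everything else so that
a variant on either strand removes the merged site.  SNP call filtering
keeps variants with depth ≥ 8 in every sample and Phred-scaled
homozygous-reference confidence ≥ 900, and discards indel or non-ACGT
alleles.

The coverage-outlier rule reads "coverage greater than 2-fold the standard
deviation" as *coverage > mean + 2·SD per sample* (a literal 2·SD cutoff at
an 11× mean would remove most of the genome); a site is dropped when it
exceeds the threshold in at least `ceil(n_samples / 2)` samples.  Because
removing the tail lowers the threshold, a single pass is not a projection;
the filter iterates the trim to a fixed point so that filtering is
idempotent.  On realistic coverage distributions the first pass removes
almost everything and the iteration converges in one or two extra passes.

Low-coverage filtering requires ≥ 3 reads in *every* sample, which also
removes sites missing from any sample; consequently the uninformative-site
rule for incomplete coverage can only fire when that filter is used
standalone.  The uninformative filter further removes saturated sites
(every sample at 100%) and sites where strictly more than half of the
samples have < 2 methylated reads.

Bisulfite conversion efficiency is computed on CHH-context cytosines not
overlapping known variants, as converted reads / total reads × 100.

## Landscape statistics

Methylation level is `m/(m+u)`; the HM class is strictly above 50% (a tie
at exactly 50% is LM).  Global methylation is the unweighted mean of
per-site levels in percent — site-weighted rather than read-weighted, a
choice exposed as a parameter since read-weighting is equally defensible.
Landscape profiles use pooled levels (counts summed over replicates);
per-sample levels feed the inferential statistics.

The metagene profile maps each CpG to
`bin = floor(101 · offset / feature_length)` clamped to 100, with the
offset measured in transcription orientation, and averages levels per bin
over all genes; zero-level CpGs are excluded by default because they
dominate sparsely methylated genomes.  Smoothing uses lowess with span 0.3
(locally linear with tricube weights, the statsmodels implementation; a
locally quadratic fit would differ negligibly at 101 bins).

The dip statistic is computed exactly by the modal-interval algorithm:
iterate greatest-convex-minorant / least-concave-majorant fits of the ECDF
(the GCM touches the lower step corners, the LCM the upper ones),
accumulate the ECDF deviations outside the candidate modal interval —
without charging the jump at the modal endpoints, since a unimodal CDF may
carry an atom at its mode — and recurse until the GCM/LCM gap stops
exceeding the accumulated deviation; the dip is half that deviation.  Two
numerical points matter: the GCM/LCM gap is maximised over hull contact
points only (it is piecewise linear with breakpoints there; evaluating
interpolated interior points invites round-off artifacts), and ties are
handled by collapsing duplicates into multi-unit ECDF jumps.  The
implementation is verified against an independent linear-programming oracle
(grid over mode locations, convex/concave fits on either side, atom at the
mode) to 1e−10.  The p-value is the seeded Monte-Carlo exceedance fraction
over uniform(0,1) samples of the same size — the least favourable unimodal
null — with an add-one correction, so with `n_boot = 200` the smallest
attainable p is 1/201 ≈ 0.005.  The dip is invariant under affine maps of
the data but *not* under general monotone transforms, which change the
spacings the hull fits depend on.

HM feature enrichment is a chi-squared goodness-of-fit of HM counts across
feature classes against expectations proportional to all-CpG counts
(df = k−1), with a warning when an expected count drops below 5.

## CpG clusters

Inter-CpG distances are differences of successive dyad start positions;
the run threshold is the genome-wide median distance (per-chromosome
optionally), ties inclusive.  Maximal runs of below-threshold gaps with
≥ 2 CpGs are proto-clusters; each is scored by the exact negative-binomial
tail `P(span ≤ L | N−1 geometric gaps at density ρ)` with
`ρ = total CpGs / covered length`, and clusters with `p < 1e−5` are kept.

A caveat documented deliberately: the p-value treats the observed run as if
its membership were fixed in advance, but proto-clusters are *selected*
maximal tight runs, so under uniform random placement the realised
`p < 1e−5` rate is about 1.5e−4 per proto-cluster rather than the nominal
1e−5 — a ~15-fold selection inflation.  This matches the published
construction of the method; treat cluster p-values as a ranking device
with an empirical, not nominal, false-positive rate.

## Differential methylation

The per-CpG test is a binomial logistic regression of methylated proportion
on the group indicator with per-sample totals as weights.  With one binary
covariate the MLE sits at the pooled per-group proportions, so the
likelihood-ratio chi-squared (1 df) is computed in closed form as a G-test
on the pooled 2×2 read-count table — vectorised over sites, and verified in
the tests against an explicit statsmodels binomial GLM.  The LR form stays
finite under complete separation.  No overdispersion correction is applied
(an extension point; between-replicate variance beyond binomial would make
the test anticonservative on real data).

q-values default to `π₀ · BH`: `π₀` is estimated by least-squares linear
fits to the p-value ECDF on `[λ, 1]` over the window grid
`λ ∈ {0.10, 0.15, …, 0.90}`, taking the median slope, clamped to (0, 1] —
under uniform null p-values the tail slope estimates the null proportion.
Plain Benjamini–Hochberg is available.  DMCs are `q < 0.05` (strict), with
direction (hyper/hypo), |difference| magnitude flags at 25/50/90 points,
and the HM/LM class of the pooled control level.

## Methylation–expression coupling

FPKM is `count · 10⁹ / (exonic length · total counts)`, invariant to global
count rescaling.  Genes with exon-overlapping neighbours are removed before
expression comparisons (both members of a pair); homolog-level analyses use
the stricter span-plus-1 kb-flank overlap rule.  Per-gene feature means
(exon 1, exons 2–4, 1 kb upstream) exclude zero-level CpGs; genes with
fewer than four exons use the exons available from exon 2 on, and
single-exon genes are missing for exons 2–4 — this maximises usable genes
without extrapolating.  The quantile regression ranks genes by feature
methylation (stable gene-id tie-break), cuts them into near-equal quantiles
(default 100, configurable; the analyses here use 25 so each quantile holds
a meaningful number of genes at simulation scale), and regresses the
quantile's mean raw FPKM on its mean methylation by OLS.  Expression is
averaged across replicates before regression; log-scaled expression is for
density plots only.  Direction concordance between DMCs (|Δ| > 50 points,
exons 2–4) and differential expression uses the 2×2 chi-squared without
continuity correction, counted at DMC level, optionally restricted to
significant large expression changes.

## Conservation

Orthogroup categories partition on the clades spanned: one species →
species-specific; within one arthropod clade → daphnia-/hymenoptera-
specific; both arthropod clades, no mammal → arthropod-specific; mammals
only → mammal-specific; both sides → common.  Six labels are kept (the
coarser four-way scheme collapses clade pairs; a collapse option exists for
figure parity).  Orthogroup profiles average per-gene feature methylation
(exons 2–4 for arthropods, exon 1 for mammals) within orthogroup and
species, min–max scale per species, and reverse the methylation scale for
mammals (`1 − scaled`, an involution) so that "high" means
expression-associated methylation in every species.  Joint clustering and
ranked-methylation homolog clustering both use Euclidean distance with
average linkage (the choice is configurable; the original heatmap linkage
is unstated, and figure parity cannot be checked without the original
data), cut into k groups; ranks are competition ranks with mean ties, making
all ranked analyses invariant to monotone transforms of the inputs.  The
rank-sum conservation analysis adds methylation and expression ranks per
gene and compares categories by Kruskal–Wallis, optionally with a label
permutation p-value.  Over-representation is the exact hypergeometric upper
tail with BH adjustment across gene sets.

## Synthetic data

The generator is the package's test bed and defines the simulated study
conditions; its defaults are fixed, not tuning knobs.

*Annotation*: non-overlapping genes (2–7 exons of 120–400 bp, introns
80–400 bp) on 4 contigs with intergenic gaps of 3–8 kb, large enough that
1 kb flanks never touch a neighbouring gene; 200 genes by default.  CpG
dyads are placed by a Bernoulli process at 0.045/bp in exons and 0.012/bp
elsewhere for the invertebrate mode (exonic CpG enrichment) and uniformly
at 0.02/bp for the vertebrate mode, with the 2 bp dyad footprint enforced.

*Methylome*: each CpG draws a latent level from a two-mode beta mixture —
Beta(8, 1.3) for the high mode, Beta(0.2, 60) for the low — with the
high-mode probability set by gene methylation status and feature class.
The mosaic architecture methylates a fixed 4.5% of genes (a stratified
draw, so the achieved global level is stable across seeds) with high-mode
probabilities peaking at exons 2–4 (0.60) and low elsewhere; it targets
0.4–1.5% global methylation and lands near 1.1%.  The vertebrate
architecture methylates everything heavily (high-mode probability
0.85–0.93) except promoters: each gene draws a promoter (upstream + exon 1)
high-mode probability from Beta(0.9, 1.2), emulating the island/non-island
promoter dichotomy; it targets 72–76% and lands near 74.5%.  Coverage is
Poisson(11) per strand per sample; destranded records sum both strands
(truncated at 1 read).  A warning fires if the latent global level leaves
the architecture's target range.

*Expression*: log-normal gene baselines (σ = 1) shifted by
`coupling × (feature methylation − mean)` with coupling +3 on exons 2–4
(mosaic) or −3 on exon 1 (vertebrate) in log units — strong enough for the
planted sign to be recoverable at 200-gene scale — then negative-binomial
counts (dispersion 0.2) scaled by exonic length, FPKM-ready.

*Two-group experiment*: base levels uniform(0.1, 0.9); a chosen subset is
shifted ±40 points in the treatment group (direction keeps levels in
range); 4 treatment vs 3 control replicates at per-strand coverage 11.
The calibration checks use single-strand Poisson(11) coverage at level
0.3, matching the null study conditions stated for them.

*SNPs*: placed with a configurable fraction (default 10%) on CpG dyad
bases; qualities, confidences and depths straddle the respective filter
thresholds so every SNP rule is exercised.

*Orthogroups*: categories drawn from a fixed mix over six species in three
clades; a positive conservation–methylation link gives more conserved
categories higher latent methylation and expression.

What the generator does *not* emulate: sequence composition (no real
CpG-island structure or GC skew), mapping artefacts beyond the coverage
outliers, overdispersed biological replicate variance in methylation
(replicates share the latent level), isoform structure, and
chromosome-scale covariates.  Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative
assumptions, not robustness to every artefact of real libraries.

## Problem sizes and determinism

Default analysis scale — 200 genes, ~25–30k CpGs, 3 replicates, 2,000 sites
in the two-group experiment, 200 Monte-Carlo draws for dip p-values, 25
methylation quantiles — keeps any single analysis under a minute on one
CPU while leaving all effects detectable at their design strength.  Every
generator and every stochastic procedure takes an explicit seed, and the
pipeline manifest records config hash and seeds so reruns are bit-identical.
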