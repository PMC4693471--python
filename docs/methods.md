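# Methods

## Count model and inference

Feature counts are modelled per feature as negative binomial with a log
link and offsets `log(lib_size × TMM factor)`. The NB parameterization
is `Var = μ + φ μ²`; `φ = 0` recovers Poisson and `BCV = √φ`.
Coefficients are fitted by IRLS (Fisher scoring with weights
`μ/(1+φμ)`), batched across features since the design matrix is shared;
convergence is declared when the relative deviance change drops below
1e-8 (50 iterations maximum, non-converged features flagged and kept at
their last iterate, with step halving whenever a full step would
increase the deviance). Fitted means are clamped to [1e-10, 1e12] so
all-zero features stay finite.

The study design `~Genotype + Genotype:Age` (Young, Normal as
references) has columns `[Intercept, GenotypeDwarf, Normal:AgeOld,
Dwarf:AgeOld]`. Likelihood-ratio tests hold the dispersion fixed and
compare the full fit against the fit with the tested direction removed;
a contrast vector is handled by an orthogonal change of basis that
makes the contrast the last coefficient of an equivalent design, which
is then dropped. Statistics refer to χ²(1). Both the coefficients and
the LRT statistics agree with edgeR's `glmFit`/`glmLRT` to ~1e-6 at a
fixed common dispersion (cross-checked in the test suite on a small
simulated matrix; edgeR is never used in the computation itself).

## Normalization

TMM with the published constants: reference sample = the one whose
upper-quartile CPM is closest to the mean upper-quartile; M and A
values over features positive in both samples; 30% trimmed from each
tail of M and 5% from each tail of A; inverse asymptotic-variance
(delta-method binomial) weights; factors rescaled to geometric mean 1.
A sample sharing no positive features with the reference gets factor 1
with a warning. CPM is `count / (lib_size × factor) × 1e6`, plain
library-size/TMM scaling — reported average CPM does not depend on the
estimated dispersions.

Limitation (deliberately documented rather than patched): when a large
fraction of features is differentially abundant in one direction *and*
biological noise is at serum scale (BCV ≈ 0.4), the DE and null M-value
distributions overlap, the double trim no longer isolates the null
majority, and TMM under-corrects composition. At the planted fractions
used here (~11% DE) the residual bias is negligible; a stress test at
50% one-directional DE shows log2FC attenuation of ≈ 0.35 — identical
to edgeR's behaviour on the same matrix.

## Dispersion estimation

Cox–Reid adjusted profile likelihood (APL): for each candidate
dispersion on a 26-point log-spaced grid (1e-4 to 10), every feature is
refitted and the profile log-likelihood is penalized by half the
log-determinant of the Fisher information. From the feature × grid APL
matrix:

* **common** — maximizer of the column sums;
* **trended** — per-feature maximizer of the APL after a moving-average
  smooth across features ordered by mean log CPM (window ≈ G/20, i.e.
  20 abundance bins);
* **tagwise** — maximizer of `APL_g + prior_n × APL_trend` with
  `prior_n = prior_df / residual_df` and `prior_df = 10` by default, an
  empirical-Bayes shrinkage of each feature toward its abundance
  neighbourhood.

Maximizers are refined off-grid by parabolic interpolation in log φ.
All-zero features are excluded from estimation and assigned the
low-abundance end of the trend. The default `fit()` uses the tagwise
estimates; calibration on 2000 simulated null features at the study's
size (n = 5/cell, BCV 0.4) gives an interaction-test type-I error of
≈ 0.05 (0.05–0.066 across seeds for tagwise, 0.045–0.052 for
common/trended) and common-dispersion recovery φ̂ ≈ 0.16 for truth
0.16.

## Pattern classification

Inclusion requires interaction |FC| > 1.5 (strict) and FDR < 0.10
(strict); per-genotype direction requires |FC| ≥ 1.5 (inclusive) and
raw P < 0.05 (strict) — boundary semantics exactly as the reporting
convention prints them. The full 3×3 direction grid is labelled; only
the four serum-observed cells get letters (A–D), the rest get
`other(dir_N,dir_D)` since synthetic data can populate them. When a
table carries previously reported labels, strict-rule disagreements are
flagged in a `conflict` column, never silently overridden: the bundled
21-row serum catalogue contains exactly one such row (mmu-miR-344d-2-5p,
printed as pattern C although its dwarf age effect fails the
significance footnote; the strict rule yields B).

## Overtargeting

Interactions are collapsed to binary miRNA–gene pairs before testing —
multiple predicted sites per pair would violate the
without-replacement sampling model (site-level counting is therefore
not offered). For a gene targeted by `n` of the universe's `M` miRNAs,
`k` of them among the `K` focal (GbA) miRNAs, the upper-tail
hypergeometric probability is computed per gene and BH-adjusted across
genes; the significant set is `P < 0.05 and FDR < 0.10`. Focal miRNAs
absent from the universe vocabulary are reported, and an optional
family map normalizes mature-miRNA tokens to family tokens so queries
match family-keyed universes. The functional-annotation second filter
is an explicit user-supplied gene-set file (no external enrichment
service is called), preserving the double-filter architecture; the
network export restricts universe edges to (focal miRNA, significant
gene) pairs and writes SIF and GraphML.

## Tissue-signature enrichment

The null draws |focal| miRNAs without replacement from a caller-stated
universe (which universe — all detected vs all annotated miRNAs — is an
explicit input, not a default). Default one million permutations,
implemented by random-key partial sorting in chunks; the empirical
p-value uses the +1 pseudocount convention, so P ∈ (0, 1]. Because this
null is exactly hypergeometric, an exact mode is provided as a fast
path and as the convergence oracle in tests.

## Family comparison

Mature miRNAs map to families through a user-supplied two-column map
(unmapped tokens are an error, never dropped). The cross-study decision
table formalizes the comparative narrative: a shared family whose dwarf
age response is absent while calorie restriction abolishes the external
age response is "CR-like"; one whose dwarf response diverges from both
the external age and CR responses is "CR-independent"; shared families
fitting neither are "unclassified", families absent externally
"unshared". This table is an interpretation layer and is documented as
such.

## 5′ tRNA halves

Reads are profiled strand-aware against BED annotations (0-based
half-open); a read takes the class of the maximal-overlap same-strand
annotation, ties broken miRNA > tRNA > other sncRNA. tRNA-overlapping
reads partition into 5′/3′ halves (30–40 nt, terminus within 3 nt of
the corresponding tRNA terminus) and 5′/3′ tRFs (16–25 nt, same anchor
rule), else unanchored fragments; the anchor tolerance and size windows
are configurable, and the positional definition of a "5′ half" is this
package's operationalization of the published size ranges. Genomic
coordinates are used throughout, so the post-transcriptional CCA tail
is ignored (a known limitation). Five-prime-half counts aggregate per
isoacceptor (amino acid + anticodon, both GtRNAdb and UCSC name
dialects parsed; unparseable names are returned as rejects). The
isoacceptor matrix then runs through the identical GLM machinery, with
deliberately relaxed default report thresholds (raw P < 0.05,
FDR < 0.28) reflecting the exploratory nature of small tRNA-half
catalogues — exposed as parameters, not endorsed.

## Synthetic data

The generators define the study conditions: a balanced 2×2 design with
5 female mice per genotype × age cell; NB counts with dispersion 0.16
(BCV 0.4, typical for serum small-RNA libraries); log-uniform library
sizes 1e6–3e6 so the catalogue's ~3-CPM features correspond to
single-digit counts; baseline abundances log-uniform over 2^-18–2^-9
relative frequency (≈ 3–2000 CPM); planted pattern fractions
2%/6%/2%/1% (A–D) at 4-fold effects, magnitudes motivated by the
observed 1.5–63.9 FC range. Pattern effects are deterministic given the
config (pattern C at FC 4 means log2FC −2 in Normal and +2 in dwarf).
Counts are generated directly at the feature level; the read simulator
is a separate path feeding only the annotation profiler (76:24
tRNA:miRNA split, miRNA reads 20–24 nt peaked at 21–22, tRNA reads
30–33 nt anchored at the 5′ terminus of toy loci). The interaction
universe uses a 150-miRNA-family vocabulary with 20–80 targeting
families per gene (TargetScan-conserved-family-like density); planted
genes draw their targeting miRNAs with the focal set upweighted
(default ×5). At that operating point, 20 planted genes in 2000 are
recovered at sensitivity ≈ 0.83 with empirical FDR ≈ 0.04 over 20
replicates.

What the generators do **not** emulate: sequencing error, adapter
contamination, multimapping ambiguity, correlated features,
sample-level covariates, or site-level interaction records. Passing
tests therefore demonstrate correctness of the statistical machinery
under the stated model, not robustness to real-library artifacts.
Sequencing depth per sample is asserted, not derived — no public raw
data exist for this design.

## Problem sizes and numerics

Default test and acceptance runs use 2000-feature calibration matrices,
1000-feature recovery runs at n = 30/cell, 10^5-permutation convergence
checks and 20-replicate universe recovery — sizes chosen so the full
suite runs in well under a minute while leaving Monte-Carlo error small
relative to every asserted tolerance. Ties in annotation overlap are
broken by a fixed class priority for determinism; every stochastic
routine takes an explicit seed and CLI runs log their seed and config
snapshot next to their outputs.
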