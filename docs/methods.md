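# Methods

This note documents the models, estimators and numerical conventions
behind `imglia`, the design choices made where several defensible
options existed, and what the synthetic benchmark does and does not
establish about real data.

## The question and the procedure

The package operationalizes one question: do induced microglia-like
(iMG) cells derived from blood monocytes resemble brain-resident
microglia at the transcriptome level?  The procedure is comparative:
merge the test study's count matrix with a reference study's on shared
gene symbols (case-insensitive, whitespace-trimmed), harmonize scales,
remove the study-level batch effect, and then ask three quantitative
sub-questions — do monocyte→microglia fold changes agree across
studies gene by gene (consistency score), do iMG samples cluster with
reference microglia rather than reference monocytes (MDS +
hierarchical clustering of the cascade-filtered signature genes), and
which genes are switched on or off specifically in iMG cells
(presence Venn, NB differential expression)?

## Normalization chain

**Size factors.** "Library-size" normalization is implemented as the
median-of-ratios estimator: for the genes with strictly positive
counts in every sample, each sample's factor is the median of its
counts divided by the per-gene geometric mean.  This choice, rather
than counts-per-million, keeps the downstream presence cutoff
(normalized count > 10) and DE base means on the scale the thresholds
assume, and is robust to the composition shifts a planted signature
induces.  If no gene is everywhere-positive the estimator refuses and
suggests total-count factors rather than silently degrading.

**FPKM.** `fpkm[g,s] = count · 1e9 / (length_bp[g] · column_total[s])`,
used for cross-dataset comparison where transcript length differs
between profiled gene sets.  The identity Σ_g fpkm·length = 1e9 per
sample is a tested invariant.

**Variance-stabilizing transform.** For NB2 counts (variance
μ + αμ²) the stabilizing integral has the closed form
(2/√α)·asinh(√(αx)).  We use one pooled dispersion α and calibrate
affinely so the transform asymptotes to log2(x) at large counts:
`vst(x) = [2·asinh(√(αx))]/ln 2 − log2(4α)`.  This deliberately omits
the per-gene dispersion-trend machinery of full DESeq2 VST: clustering
needs a monotone, variance-flattening, log2-scaled map, and the pooled
form provides exactly that with one interpretable parameter (default
α = 0.1, a typical bulk RNA-seq dispersion).  Where a plain log is
called for, log2(x + 1) is used and the pseudocount recorded in the
transform log.

**Batch removal.** Per gene, `value ~ identity + batch` is fit by
least squares (one solve for the whole matrix, since the design is
shared) and the fitted batch component is subtracted, re-centred per
gene so every gene's grand mean is preserved exactly — the usual
sum-to-zero contrast convention only guarantees this for balanced
designs.  The protected covariate is cell *identity*
(monocyte / macrophage / microglia), not the study-specific group
label: labels are nested within study (iMG only in the test study,
reference microglia only in the reference study), which would alias
the batch term, while identities span both studies.  Protection can
be disabled (`keep=None`) to regress batch out unprotected; a
confounded design raises an error naming the aliased columns.

**Rescaling.** Per-gene affine min→0, max→1; a constant gene maps to
0 by convention.  Applied last, before distance computation, so every
gene contributes comparably to sample distances.

## Consistency score and cascade

For a gene with monocyte→microglia log2 fold changes x (test study)
and y (reference study), the consistency score is 2xy/√(x² + y²),
zero at the origin.  Fold changes enter on the log2 scale: the score's
sign logic and the 0.50 cutoff require a scale symmetric about zero,
which linear ratios (bounded below by 0, centered at 1) are not; a
`log_scale=False` flag retains the linear variant for sensitivity
analysis and the choice is recorded in the result.  Useful exact facts:
score(x, x) = √2·x, so no gene whose fold changes are both below
√2/4 ≈ 0.354 in magnitude can clear 0.50; the cutoff comparison is
strictly greater-than.  Group fold changes are computed from
size-factor-normalized group means with a pseudocount of 1 to protect
all-zero groups.

The cascade applies, in order: (1) the curated signature union;
(2) intersection with genes present in both datasets; (3) consistency
score > 0.50; (4) intersection with test-side DE results at |FC| ≥ 1.2
(linear scale, i.e. |log2FC| ≥ log2 1.2), p ≤ 0.001 and mean
normalized expression ≥ 5 — stage-4 boundaries inclusive, as the
criteria are phrased, in contrast to the strict presence and volcano
cutoffs.  The p in stage 4 is the raw Wald p by default
(`use_adjusted_p` flips it): the FDR language in the source toolchain
attaches to the volcano threshold, not the cascade filter.  Only the
test-side contrast gates stage 4; the reference dataset enters through
the consistency score alone.

## Differential expression

The model is NB2 with fixed per-gene dispersion, a size-factor offset
per sample, and one free mean per group.  Because the two group means
are variation-independent, the likelihood separates by group, and each
gene reduces to two 1-D Fisher-scoring problems solved vectorized
across all genes (steps clipped to ±5 on the natural-log scale; fitted
group means floored at 1e-3 normalized counts so log2FC stays finite
when a group is all zeros; non-converged genes keep their estimates
but are reported with p = 1 and flagged).  The Wald statistic
log2FC/SE is referred to the normal distribution, two-sided, and BH
adjustment is applied across tested genes.  All-zero genes are dropped
before testing and listed in the result's metadata.  An independent
statsmodels GLM fit of the same model is used as a cross-check in the
test suite.

Dispersion: per-group method-of-moments (s² − m̄)/m̄² on normalized
counts, pooled by degrees of freedom, floored at 1e-8, then blended
50/50 with the mean raw estimate of the gene's expression decile.
This is a deliberately simple stand-in for empirical-Bayes trend
shrinkage: it stabilizes low-information genes enough for calibrated
tests (type-I error ≈ 0.05 at 10 vs 10 samples in the test suite)
without importing the full DESeq2 dispersion machinery, and the
divergence is intentional and documented here.

One caveat for the depth-invariance property: scaling one sample's
counts and its size factor jointly by c changes the sample's Fisher
information, so NB statistics move slightly (≈1e-4 in log2FC at
typical counts).  Exact invariance holds only for statistics computed
from normalized values; the test suite asserts the approximate
version.

## Embedding and clustering

Classical (Torgerson) MDS double-centers −½·J·D²·J, eigendecomposes,
and scales the top-k eigenvectors by √eigenvalue; negative eigenvalues
(non-Euclidean geometry) are reported on the result and never used for
coordinates.  PCA takes the SVD of the gene-centered matrix.  Both fix
eigen-sign by forcing the largest-magnitude loading positive, for
platform-reproducible output; on Euclidean distances the two agree up
to an orthogonal transform, which the tests assert to 1e-8 (with
scikit-bio's PCoA as a second, independent reference).  Sample
distances are Euclidean on the rescaled VST matrix by default
(correlation distance available); clustering is standard agglomerative
linkage (average by default; complete and single available).
Cluster purity cuts the dendrogram into k clusters and sums
majority-class counts.  Purity is evaluated over cell identities with
k = 3: after batch removal, same-identity populations from the two
studies are — by design — draws from the same distribution, and their
co-clustering is the outcome under test, not an error to penalize.

## Presence Venn and qPCR

A gene is expressed in a cell type when its mean size-factor-normalized
count over that type's samples is strictly greater than 10 (the mean is
over samples, not a per-sample requirement).  The three-set partition
is exhaustive and disjoint by construction and property-tested over
random set triples.

qPCR fold changes follow the Livak 2^−ΔΔCT convention: per-replicate
ΔCT = CT_target − CT_housekeeping, ΔΔCT referenced to the *mean*
control ΔCT, per-replicate folds retained so mean ± SD can be
reported.  Group comparison is Student's t-test for two groups and
one-way ANOVA above that; identical degenerate groups return p = 1
rather than NaN.  Amplification-efficiency correction is out of scope.

## Synthetic data: what it emulates and what it does not

The simulator draws NB2 counts (gamma–Poisson, variance μ + αμ²,
default α = 0.1) for five populations — monocytes, induced
macrophages, iMG, reference microglia, reference monocytes — across
two studies.  Per-gene baselines are log-normal around a mean of 50
counts; each (gene, study) pair receives an N(0, 0.25²) log2
multiplicative batch shift; library sizes are drawn uniformly on
(0.8, 1.2)×10⁶, a desk-scale depth that keeps every stage fast while
leaving size-factor estimation non-trivial, and each sample's expected
column sum is scaled to its drawn depth.  Default group sizes mirror a
small bulk design (3 monocytes, 3 iMacs, 4 iMG, plus 4 + 3 reference
samples); calibration studies use 10–20 samples per group.

Cell identity is encoded entirely through the planted signature: a
configurable set of genes (default 150 of 2000) shifted by
`effect_multipliers[cell_type] × signature_log2fc` log2 units relative
to monocytes, with multipliers 0 (monocytes), 0.5 (iMacs — an
intermediate macrophage identity) and 1.0 (iMG and reference
microglia).  This makes induced and reference microglia
distributionally identical after batch removal, which is precisely the
structure the pipeline should detect.  A companion generator builds
paired studies with concordant and discordant signature subsets as
ground truth for consistency-score recovery, and a CT-table generator
feeds the qPCR module.  All draws flow from a single seeded generator;
identical seeds give bit-identical output.

Not emulated: read-level artifacts (the pipeline starts at counts),
gene-length variation coupled to expression, dispersion–mean trends,
single-cell dropout, outlier samples, and correlated gene modules
beyond the signature.  Passing tests therefore establish that the
estimators recover planted truth under a faithful NB model of the
study design — not that any particular real dataset will reproduce the
original analysis's headline gene counts, which depend on the actual
deposited data and external reference datasets.

## Degenerate inputs and tie-breaking

Duplicate gene or sample ids, non-integer counts, samples missing from
metadata, empty gene-symbol intersections, confounded batch designs,
groups with fewer than two samples, missing housekeeping CT rows and
unknown config keys all raise errors naming the offending items before
any computation.  Scipy's deterministic agglomerative ordering handles
linkage ties; fcluster's maxclust criterion may return fewer than k
clusters when heights tie, which purity handles transparently.  The
pipeline summary is serialized with sorted keys and fixed rounding so
reruns are byte-identical.
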