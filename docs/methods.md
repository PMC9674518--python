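# Methods

This note documents the models and procedures implemented in `thyrotype`,
the parameters that matter, what the synthetic cohorts do and do not
emulate, and the numerical choices a maintainer would want to know about.

## Input model

Every stage consumes a dense, non-negative gene-by-sample matrix on the
RPKM scale (reads per kilobase per million mapped reads). Quantification
from reads is upstream of this package. Log transformation is always
`log2(RPKM + 1)`; the pseudocount (default 1.0) is configurable and makes
zeros map to zero.

## Gene filtering

Two rules, applied on the linear scale, in order:

1. remove genes with RPKM < 1.0 in strictly more than half of the samples;
2. remove genes whose coefficient of variation (sample standard deviation
   over mean) is below 0.8. A zero-mean gene has an undefined CV and is
   removed.

The CV uses the n−1 denominator. Counts removed by each rule are recorded
in the `FilteredMatrix` provenance.

## Consensus NMF subtyping

The filtered, log2-transformed matrix V (genes × samples) is factorized as
V ≈ WH with W, H ≥ 0 by Lee–Seung multiplicative updates on the Frobenius
objective ‖V − WH‖_F. Initialization is uniform random scaled so the
initial product matches the matrix mean; convergence when the relative
objective change drops below 1e−6 or after 2000 iterations. The objective
is non-increasing across iterations, which the test suite asserts
iteration by iteration.

Consensus machinery: per restart (default 50; 30 in the planted-recovery
checks), samples are hard-assigned by the argmax of their column of H; the
consensus matrix is the co-assignment frequency across restarts. The
reported W/H come from the restart with the lowest final objective.
Stability is summarized by the cophenetic correlation between the
consensus dissimilarity (1 − consensus) and its average-linkage
dendrogram; cutting that dendrogram at k gives an alternative "consensus
cluster" labelling exported for diagnostics. Rank k is fixed by the caller
(6 for the nodule cohort; re-running on one subtype's samples with k = 3
reproduces a subclassification without new code).

Exemplar genes for factor i are ranked by the loading margin
`W[g,i] − max_{j≠i} W[g,j]`, descending, ties broken by gene symbol. The
top 50 (configurable) form the feature pool for marker selection.

## Marker selection

One-vs-rest bootstrap ensembles of decision trees (default 100 trees,
`sqrt` feature subsampling) are trained per subtype on the exemplar pool.
Importance is the mean decrease in out-of-bag accuracy when a feature's
out-of-bag values are permuted. The per-feature null comes from refitting
the whole ensemble under label permutation; p = (1 + #null ≥ observed) /
(1 + permutations), Benjamini–Hochberg adjusted across features, selection
at adjusted p < 0.05.

Known limitation: with many mutually redundant markers per subtype,
permutation importance is diluted across the redundant group (each feature
can be compensated by the others), and some true markers fail the adjusted
threshold. Recovery is complete in planted cohorts with up to ~10 markers
per subtype; above that, the selected set is a correct but incomplete
subset. The permutation count bounds the smallest attainable p at
1/(permutations + 1); with BH over a pool of m features and t true
markers, the count must satisfy (m/t)/(permutations+1) < 0.05 for full
recovery to be possible at all.

## Nearest Template Prediction

Expression in the target cohort is standardized per gene with the target
cohort's own means and standard deviations (nothing flows from the
training cohort except the marker lists, preserving cross-platform
transfer). The template of subtype s is the unit-normalized indicator of
s's markers on the union of all markers; the distance is 1 − cosine
similarity, and each sample takes the nearest template (ties broken by
subtype name and flagged low-confidence). Significance: every permutation
redraws all marker sets (same sizes) from the measured genes and
recomputes the distance to the predicted subtype's random template;
p = (count + 1)/(permutations + 1), BH-adjusted across samples.

## Scores

**TDS** — for each thyroid-function gene, log2(RPKM+1) is centered by its
median across samples; the per-sample sum of centered values is the score.
Adding a sample-independent constant to any gene leaves TDS unchanged.

**Single-sample enrichment (immune / stromal / GEP)** — within each
sample, genes are ranked by expression; the score is the mean difference
between the rank-weighted empirical CDF of in-set genes (position j from
the top weighted by (N−j+1)^τ) and the uniform CDF of out-set genes. τ
defaults to 0.25; at τ = 0 the score is purely rank-based, exactly
mean-zero under random set placement, and invariant to monotone
transforms of a sample's values. At τ > 0 the weighting adds a small
positive offset under random placement; all downstream use is ordinal
(higher = more enriched), so the offset is immaterial. This replaces
kernel-density GSVA machinery deliberately: the scores are consumed only
ordinally, and the rank statistic is verifiable against closed forms. The
stromal score is set enrichment over a stromal/ECM gene set rather than a
purity decomposition; CNV-based purity estimation is out of scope.

The shipped GMT (`thyrotype/data/default_sets.gmt`) contains the standard
16 thyroid differentiation genes and placeholder immune-66 / stromal /
GEP-18 lists meant to be replaced by the user's curated sets.

**Group statistics** — Wilcoxon rank-sum (exact enumeration when both
groups have ≤10 tie-free values, otherwise the tie-corrected normal
approximation without continuity correction) and Pearson chi-square
without Yates correction. Both two-sided.

## MI network, DPI, hubs, pathways

MI between two expression vectors is the plug-in estimate after
equal-frequency binning (quantile edges; default ⌈√n⌉ bins capped at 10),
computed as H(x) + H(y) − H(x,y) with sorted-count summation so it is
exactly symmetric. Units are nats; only the ordering matters downstream.
The estimator's bias is ≈ (B−1)²/(2n); at n = 2000 and 4 bins the null
mean is ~0.002 nats. At small n the ordering of MI values within strongly
correlated triangles is noisy, so DPI-based pruning needs a few hundred
samples (or explicitly coarser bins) to be reliable.

Edges: hub-vs-all MI, then MI among retained neighbors. The significance
threshold defaults to a pooled permutation null (Bonferroni-corrected
quantile over tested pairs); an explicit threshold can be passed. DPI:
every triangle is visited in sorted order; the weakest edge is marked when
its MI < (1 − tolerance) × the smaller of the other two (tolerance 0 by
default), and marked edges are removed after the full scan.

MCC(v) sums (|C|−1)! over the maximal cliques C containing v, enumerated
exactly with Bron–Kerbosch (pivoting). Isolated nodes score 0; a node
whose only maximal cliques are edges scores its degree.

Pre-ranked GSEA: hit increments |score|^p / Σ|score|^p (p = 1), miss
decrements 1/(N−|S|), ES is the maximum deviation of the running sum; the
null permutes set positions; NES divides ES by the mean |null ES| of
matching sign; p uses the matching-sign tail with add-one; BH per sign
family. The hub–pathway graph ranks each top-MCC hub's first-layer
neighbors by the focal subtype's mean log2 difference and attaches the
resulting NES per pathway as the edge weight (one neighbor ranking per
hub; the pathway node carries the mean NES over hubs).

## Trajectory

Dimensionality reduction is 2-component PCA; ⌈n/10⌉ k-means centroids
(seeded) are joined by a Euclidean minimum spanning tree; each sample
projects to its nearest tree edge; pseudotime is the geodesic distance
from the root node (the centroid nearest the mean of the designated
benign-adjacent root samples). Terminal (leaf) edges are extended beyond
the backbone so samples past the tree ends keep distinct, order-preserving
positions — negative upstream of the root — and all pseudotimes are then
shifted to a zero minimum. The first node of degree ≥3 past the root is
the bifurcation; samples take the fate of the subtree their projected edge
reaches (samples on edges fully inside the root-side component are
"pre"). A ≥3-way branch point logs a warning and keeps the two largest
subtrees as fates.

This backbone intentionally replaces reversed-graph-embedding tree
learning: it preserves the properties exercised downstream (benign-rooted
ordering, one bifurcation, branch-dependent expression) with far fewer
unverifiable internals, and the embedding step is pluggable.

**Branch test (BEAM-style)** — null: expression ~ intercept + natural
cubic spline in pseudotime (df = 3, quantile knots), shared across
branches; alternative: plus branch-specific intercept and spline terms for
post-branch samples. Gaussian likelihood ratio n·log(RSS₀/RSS₁) against
chi-square with df equal to the added design rank; BH over genes.
Expression is Gaussian on the log2 scale because the input is RPKM, not
counts; the chi-square reference is asymptotic and the empirical type-I
rate at p < 0.05 sits near 0.05–0.06 at n = 200. Significant genes are
catalogued by their smoothed per-fate curves: declining on both fates
(cluster I), fate-1 activation (II), fate-2 activation (III); genes
matching no pattern fall back to seeded k-means (k = 3) on z-scored
curves, mapped to the majority pattern of unambiguous members.

## Variant post-filters

Deterministic row rules with literal boundary semantics ("at least" → ≥,
"less than" → strict <), applied in fixed order so the first failed rule
is the rejection reason. Fusions: split reads ≥ 5, spanning pairs ≥ 2,
both partners measured, neither partner's maximum RPKM across samples
below 1, and no same-chromosome pair closer than 10 kb (read-through).
Mutations: tumor and normal depth ≥ 10 (the coverage requirement is read
as applying to both samples), tumor VAF ≥ 0.05, normal VAF < 0.01, tumor
alt reads ≥ 5, and not a dbSNP-135 site (consumed as a boolean column; no
database lookup). Zero depth makes the VAF undefined and rejects for
insufficient coverage.

## Diagnostic signature

Per-gene Wilcoxon rank-sum with log2 fold-change log2((mean₊+1)/(mean₋+1))
on the linear scale; the "changed" flag is the disjunction p < 0.05 or
|log2FC| > 1 (a conjunction mode exists behind a flag). The signature
builder: stratified 80/20 split preserving the class ratio; candidate
features standardized by training statistics only; RFE over L2 logistic
regression dropping the smallest-|coefficient| feature per step (10% at a
time above 100 features); each subset size scored by stratified CV AUC
pooled over the 4/6/8/10-fold configurations; the selected panel is the
smallest size within one standard error of the best mean AUC (a best-mean
mode and a forced `panel_size` exist); the final model refits on the full
training split. Evaluation trains LR, RBF-SVM, Gaussian NB, random forest
and k-NN on the panel and reports pooled CV AUC on the training split and
a trapezoidal ROC/AUC on the untouched test split. Test samples never
influence standardization, elimination or fitting.

## Synthetic cohorts

The generator is a log-normal model: gene baselines ~ Normal(3.0, 1.5) in
log2 units (clipped at 0), additive log2 effects, Normal noise (sd 0.5 for
the subtype cohort, 0.3 for the trajectory cohort), exported to the linear
scale by 2^x − 1 clipped at 0.

*Subtype cohort* — six subtypes (four malignant, two benign) × 20 nodules,
1000 genes, disjoint 30-gene marker blocks shifted +2.0 log2 in their own
subtype, a 50-gene immune program scaled by a per-sample immune level
(uniform on [0,1]; shifted toward 1 in the immune-enriched subtype), a
BRAF label enriched (75% vs 5%) in one malignant subtype, and a paired
baseline-only adjacent sample per nodule. Benign subtypes carry marker
blocks of the same effect size as malignant ones — without their own
programs the two benign subtypes would be unidentifiable to any
expression-based clustering — and are distinguished from malignant
subtypes by histology and the absent immune gradient.

*Trajectory cohort* — 200 samples with latent time t ~ U(0,1), branch
"pre" before t = 0.5 and two equiprobable fates after; cluster-I genes
decline with t on both fates, cluster-II/III genes rise linearly after the
branch on one fate only (60 genes each, amplitude 5.0 log2 — the
silenced-to-high dynamic range needed for these programs to pass the
CV ≥ 0.8 variability filter the trajectory stage reuses). The 10% earliest
samples are flagged as adjacent tissue for rooting.

*Diagnosis cohort* — 100 genes, 120 + 120 samples; each malignant sample
spreads a fixed total marker budget (5 × 2.0 log2 units) over the five
informative genes with sparse Dirichlet(0.3) weights, emulating
subtype-specific marker usage: each marker is individually weak but
non-redundant, so a correct panel needs all five.

*Variant fixtures* — candidate rows placed at ±1 (or one VAF step) around
every filter threshold with hand-assigned keep/reject labels derived from
the stated rules at construction time, independent of the filter code.

What the generators do **not** emulate: count noise and library-size
effects, batch effects, correlated gene-gene backgrounds beyond the
planted programs, overlapping marker sets, tumor purity gradients,
sequence-level fusion/mutation artifacts. Passing tests therefore
demonstrate algorithmic correctness and recoverability under the planted
model, not performance on real cohorts.

## Reproducibility

All randomness flows from one integer seed through named child generators
(`rng_for(seed, op_name)`), so stages are independently reproducible and
identical runs are bit-identical; the CLI writes all floats with a fixed
`%.10g` format, making re-runs byte-identical. Problem sizes used by the
test suite and the acceptance script (120-nodule subtyping, 200-sample
trajectories, 500-gene null panels, 200 oracle graphs) were chosen to
exercise each property at the smallest scale where its statistical
assertions are stable.
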