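# Methods

This note records the models, parameter choices and numerical decisions
behind each pipeline stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Single-cell QC and differential expression

QC applies, in order, a gene filter (detected — count > 0 — in fewer
than `min_cells_per_gene = 3` cells) and then cell filters on the
surviving genes: detected-gene count outside
[`min_genes_per_cell = 200`, `max_genes_per_cell = 4500`] or
mitochondrial count fraction above `max_mito_fraction = 0.10`
(mitochondrial genes identified by the `MT-` name prefix). The order
matters — the gene filter can change a cell's detected-gene count — and
is fixed gene-first. All comparisons are strict inequalities, so a cell
at exactly 10% mitochondrial content survives. Filtering is idempotent.

Differential expression between two cell groups is a per-gene two-sided
Wilcoxon rank-sum test on log2(x+1) expression, using the normal
approximation with continuity and tie correction (for our group sizes,
dozens to hundreds of cells, the approximation error is negligible;
genes constant across both groups are reported at p = 1). The effect
size is the difference of group means of log2(x+1). P-values are
adjusted by Benjamini–Hochberg (statsmodels, verified in tests against
a literal step-up implementation). Signature thresholds: log2FC > 1.3
with FDR < 0.05 defines the early set, log2FC < −1.3 the late set —
strict, as are the per-cohort DEG thresholds (|log2FC| > 1 for RNA-seq
cohorts, > 0.2 for arrays). No minimum-detection prefilter is applied
before thresholding.

A pseudocount of 1 is used for every log transform
(log2(x+1)); `normalize_counts` rescales each cell to a common total
(10,000) before distance-based steps.

## Diffusion map and pseudotime

Cells are embedded with a from-scratch diffusion map: Euclidean kNN
graph (`n_neighbors = 15`; neighbor lists are tie-inclusive so
duplicated cells enter symmetrically), Gaussian kernel with locally
adaptive bandwidth (distance to the ⌊k/2⌋-th neighbor, combined across
a pair as the geometric mean), symmetrized by the elementwise maximum,
plus the identity (a lazy walk, which also removes bipartite
oscillation). The row-normalized operator is eigendecomposed through
its symmetric conjugate; the embedding is the leading non-trivial right
eigenvectors scaled by their eigenvalues, components ordered by
decreasing eigenvalue and sign-anchored at the largest-magnitude entry.

Pseudotime is the Euclidean distance from a user-chosen root cell,
min-max rescaled to [0, 1]. The distance is taken in
accumulated-diffusion coordinates — each component rescaled from its
single-step weight λ to λ/(1−λ), the sum over all walk lengths. The
rescaling matters: with single-step weights the second component (a
transient mode, roughly quadratic along a 1-D trajectory) can fold the
root-distance ordering; the accumulated metric suppresses transient
modes by construction and recovered the planted axis at rho ≈ 0.93
where the single-step metric gave 0.65. A disconnected kNN graph is an
error (the message suggests raising `n_neighbors`) rather than a silent
per-component embedding.

Trajectory inference is run on ordering genes — in the analysis
drivers, the union of the derived early/late signatures — because any
strong orthogonal structure (here, the planted copy-number segment)
otherwise competes for the leading component. Branch detection is out
of scope; the model is a single differentiation axis.

## Windowed copy-number estimation

The estimator is the 101-gene moving average CNV_k(i) = Σ_{j=i−50}^{i+50}
E_k(O_j)/101 along the genomic gene order, where E is defined as
log2(x+1) minus the per-gene mean over the reference cells, clipped to
±3 (configurable) for outlier robustness. Centering on a reference is
required for the window mean to be interpretable as a *relative* copy
number; without it the statistic is just smoothed expression. Windows
truncate at chromosome boundaries and divide by the actual member
count, so profiles never smear across chromosomes. Gain/loss calls use
a symmetric threshold: value > +0.2 is a gain, < −0.2 a loss, else
neutral. The estimator is checked in tests against a literal per-gene
window computation and satisfies exact identities (null profile for
reference-identical cells; a unit spike spreads as 1/101 across its
window; translation equivariance per cell).

## Deconvolution

Bulk expression is modelled as y = B·f + ε with B a non-negative
genes × cell-types basis (any LM22-compatible matrix) and f ≥ 0. Per
sample we solve non-negative least squares on the genes shared between
bulk and basis and renormalize f to sum to 1 (relative fractions, the
only mode implemented). Renormalization makes the result invariant to
positive rescaling of a sample. We deliberately fit *unweighted* NNLS:
under additive noise the plain least-squares fit is the best linear
unbiased estimator, and in recovery simulations per-gene SD
standardization measurably hurt (mean per-type r 0.90 → 0.96 when
removed), while per-gene centering makes the weights non-identifiable
(centered profiles sum to zero across types). The support-vector
formulation used by CIBERSORT, and its permutation p-values and
absolute mode, are not reimplemented; the contract — non-negative
weights on a signature basis — is the same. Immune/stromal scores are
ssGSEA of user-supplied gene sets (no proprietary signature lists are
bundled).

## ssGSEA and the hot/cold grade

For each sample, genes are ranked by expression (average ranks on
ties, largest expression = largest rank) and walked in decreasing-rank
order; the score is the sum over positions of the difference between
the cumulative in-set weight fraction (weights rank^α, α = 0.25) and
the cumulative out-of-set count fraction. With `normalize=True`
(default) the score matrix is divided by its global max − min. Only
within-sample ranks matter, so scores are invariant to any monotone
per-sample transform. The four-chemokine grade is the ssGSEA score of
the single set {CXCL9, CXCL10, CXCL11, CCL5}; cohorts are split at the
median grade, ties assigned cold (deterministic and conservative toward
calling a tumor hot; with an even sample count and no ties this puts
exactly half the cohort in each group). The fold-change statistic is
the plain difference of group means, computed per signature column.
Whether to median-split normalized or raw scores is exposed through the
`normalize` flag; the split itself is invariant to any monotone
transform, so the choice only matters if gene sets are compared.

## Consensus clustering and the two-step classifier

Consensus clustering follows the Monti resampling scheme: `reps`
subsamples of 80% of samples drawn without replacement, each
hierarchically clustered into k groups, with consensus[i,j] the
fraction of co-drawn repetitions in which i and j co-clustered. Linkage
is Ward on *unsquared* Euclidean distances (the hclust `ward.D`
convention); scipy's `ward` is the `ward.D2` variant, so we feed it the
square roots of the distances, which reproduces the `ward.D` merge
tree. Final labels come from the same linkage applied to 1 − consensus.
PAC (proportion of ambiguous clustering) is the fraction of
off-diagonal consensus entries strictly inside (0.1, 0.9), exposed as a
diagnostic; k itself is fixed by the design (k=2, then k=3), not
selected by a rule.

The two-step classifier runs step 1 on the immune-cell fraction
columns (k=2); the cluster with the higher mean summed immune fraction
(malignant/non-immune compartments excluded from the sum) is subtype A,
the other B. Step 2 clusters only the A samples on z-scored
early-signature log2 expression (k=3) and orders the clusters A1/A2/A3
by decreasing mean immune fraction, so cluster identities are defined
by infiltration level rather than arbitrary ids. A step-2 cluster with
fewer than two samples triggers a warning and is merged into the
nearest (centroid) surviving cluster. Step 2 depends only on A-side
data, so removing B samples and supplying the A/B split (`ab_labels`)
reproduces the A labels exactly. Default `reps` is 1000 for standalone
consensus runs; the drivers and recovery experiments use 200, which
left label assignments unchanged on cohorts of this size (n ≈ 200).

## Survival

Two-group comparisons use the standard log-rank statistic (lifelines),
validated in tests against a literal risk-table
observed-minus-expected computation and calibrated under the null
(type-I error within [0.03, 0.07] at α = 0.05 over 1000 exponential
simulations). Kaplan–Meier curves are emitted as step-function tables.
Multi-group (>2) comparisons are out of scope.

## Network topology and the hub screen

Degree, shortest-path betweenness, eigenvector centrality and
eccentricity centrality are computed per node. Betweenness is
unnormalized, endpoint-excluding, with each unordered pair counted
once; pairs with no connecting path are skipped. Eigenvector centrality
is the non-negative principal adjacency eigenvector with unit Euclidean
norm, obtained by power iteration (tolerance 1e-10) on A + I — the
shift leaves eigenvectors unchanged but prevents oscillation on
bipartite graphs. Eccentricity centrality is 1/max dist(v, w) over
*reachable* w, and 0 for isolated nodes; on disconnected graphs these
conventions keep every quantity defined. The hub screen takes the first
40 nodes by degree, ranks those 40 by eigenvector centrality and by
betweenness, and intersects the two top-20 lists. Eigenvector is the
default secondary metric (the ranking the screen is reported with);
eccentricity can be substituted via the `secondary` argument. Ties at
any list boundary are broken by (higher metric, then lexicographic node
id) and flagged in the audit trail, since "first n" is otherwise
undefined. `degree_filter` (degree strictly greater than 30) is
provided separately; on arbitrary graphs it need not coincide with the
top-40 list, and composing the two is left to the caller.

## Response network

The predictor is a [7, 20, 5, 1] fully connected network with the
logistic sigmoid at hidden *and* output layers (a single activation
function throughout), inverted dropout (rate 0.2 by default) on both
hidden layers during training only, and mean binary cross-entropy loss,
minimized by full-batch gradient descent. Plain gradient descent was
chosen over adaptive or resilient schemes because it is deterministic
under a seed and directly checkable against finite differences (the
test requires max relative error < 1e-4 with dropout off). Weights and
biases initialize uniform(−0.5, 0.5) under the seed. The default
learning rate is 0.1 for 2000 epochs: at 0.01 the loss stays pinned
near ln 2 through two saturating sigmoid layers within any reasonable
epoch budget, while 0.1 converges across seeds on cohorts of a few
hundred samples with z-scored features. Optional positive-class
weighting in the loss is off by default. Features are z-scored per
column at assembly (constant columns are an error); the 7 features are
the four per-gene chemokine ssGSEA grades and the M1-macrophage, CD8 T
and activated-memory CD4 T fractions. Models serialize to JSON and
reload bit-exactly. Evaluation reports the ROC curve, trapezoidal AUC
(equal to the tie-corrected Mann–Whitney probability, verified by
exhaustive pair counting) and the confusion matrix at threshold 0.5.
The train/test protocol is a generic split: fit on one sample set,
evaluate on a held-out set.

## Synthetic data: what it emulates, and what it does not

`gen_sc_cohort` draws cells with latent time uniform on [0, 1] and
counts from a negative binomial (dispersion 10) around a log2-scale
mean structure: per-gene baselines N(3, 0.8), marker genes at an
elevated baseline N(4.5, 0.4) with a logistic gate of amplitude
`*_effect_log2fc` (default 2) that decays (early) or rises (late)
across the midpoint of latent time; per-cell log2 size factors N(0,
0.3); mitochondrial (`MT-`) genes with a raised baseline. The three
archetypes (C1 early / C2 transitional / C0 mature) are latent-time
thirds. A small fraction of cells is made near-empty (2%) or
mitochondria-dominated (2%) so the QC thresholds have real work.
Copy-number segments multiply the mean of a contiguous gene block in a
configurable fraction of cells; the gene order assigns ~250 genes per
chromosome. Marker baselines are set high enough that the planted
log2 fold change survives the +1 pseudocount compression — at low
expression a planted twofold mean shift measures well below 1 on the
log2(x+1) scale, which would make the stated thresholds unattainable
for reasons unrelated to the statistics.

`gen_bulk_cohort` builds a basis of lognormal profiles with exclusive
marker blocks (16× enrichment — of the order of real signature-matrix
markers) over the 22 LM22 type names plus a malignant compartment,
mixes it with Dirichlet immune fractions scaled by (1 − malignant
fraction), boosts the chemokine genes 2^`hot_effect_log2fc` in hot
samples and the key effector types' Dirichlet weights, adds additive
Gaussian noise clipped at zero, and draws exponential survival (hot
hazard = baseline × hazard ratio, default 0.5, independent exponential
censoring) and Bernoulli response from a logistic model on the 7
z-scored predictor features. With `plant_a_subtypes=3` the hot samples
split into three groups with a malignant-fraction gradient
(means ≈ 0.15/0.30/0.45 vs ≈ 0.70 for cold) and block-structured
early-signature genes, giving the A1/A2/A3/B recovery target.
Deconvolution recovery experiments use immune-only mixtures
(`include_malignant=False`), the setting the basis contract describes.

`gen_ppi` overlays a planted dense module (default: a 12-clique) on a
G(n = 200, p = 0.02) background and wires the module outward at 4× the
background edge probability — hub modules in interaction networks are
highly connected externally as well as internally, and without that
external wiring module members are invisible to betweenness (they
bridge nothing).

All generators are deterministic under their seed and return the
planted truth alongside the data.

What the generators do **not** emulate: batch effects, doublets,
ambient RNA, read-level sampling, gene–gene correlation beyond the
planted structure, platform differences between cohorts, censoring
informative of phenotype, or the noise level of real ICB cohorts.
Passing recovery tests therefore demonstrates correctness of the
estimators under their assumed models, not their field performance; in
particular the response network separates the planted logistic signal
essentially perfectly, which real cohorts (where published test AUCs
sit far below training AUCs) will not reproduce.

## Problem sizes and determinism

The recovery experiments use n = 500 cells / 600 genes (signatures),
n = 300 cells (pseudotime), n = 100–200 bulk samples, 200-node graphs,
consensus `reps` = 200, and 1000 null simulations for log-rank
calibration — sizes at which every planted effect is comfortably
identified and a full run of tests plus the acceptance script takes on
the order of a minute. Every stochastic step takes an explicit seed;
`scripts/acceptance.py` derives all of its seeds from the single
`--seed` argument via `numpy.random.SeedSequence`.

## Known limitations

- One trajectory method (diffusion map); no branch detection or graph
  embedding alternatives.
- Deconvolution has no per-sample significance testing and no absolute
  mode; results are relative fractions.
- ssGSEA is the only enrichment flavor; no permutation-based GSEA.
- The CNV estimator produces smoothed relative profiles, not discrete
  states or significance calls for recurrent regions.
- k for both clustering steps is fixed by design; PAC is reported but
  not used for selection.
- The published signature gene lists (29 immune signatures, ESTIMATE
  sets) are not bundled; callers supply their own GMT files.
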