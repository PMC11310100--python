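# Methods

`rehoscales` implements a multi-scale imaging-transcriptomics analysis for
case-control resting-state fMRI studies, together with a synthetic-data
generator that produces cohorts and expression bundles with known planted
structure. This note documents the models, the tunable parameters, the
numerical choices, what the generator does and does not emulate, and the
known limitations.

## Regional homogeneity

Local synchrony of spontaneous BOLD activity is quantified per voxel by
Kendall's coefficient of concordance (W) over the voxel and its neighbours
(26-connectivity by default; 6 and 18 are supported):

    W = 12 * sum_t (R_t - mean R)^2 / (K^2 (n^3 - n))

with K series, n timepoints, and R_t the sum over series of the within-series
rank at timepoint t. W is 1 when all series share one rank ordering and has
expectation 1/K for independent series. Design choices:

- **No tie correction.** BOLD series are continuous; ties arise only in
  degenerate synthetic inputs and are resolved by average ranks. An
  all-constant neighbourhood returns W = 0 by convention (logged).
- **Edges.** Voxels near the mask boundary use whatever in-mask neighbours
  exist (variable K, recorded per voxel). Voxels with fewer than
  `min_neighbors` (default 7) in-mask neighbours are set to 0 and flagged
  invalid rather than dropped, preserving the grid.
- **Standardisation.** Maps are z-scored over the mask using the population
  SD (divide by N); this convention is frozen so regression tests are exact.
  Standardisation precedes regional averaging.

The map implementation ranks each voxel's series once and accumulates
neighbourhood rank sums by shifting the rank volume, which is bit-identical
to per-voxel evaluation (tested against a brute-force oracle).

## Residual preprocessing

The package assumes spatially preprocessed, grid-aligned data and performs
only the residual temporal steps, in a fixed order: nuisance regression,
then band-pass filtering.

- **Framewise displacement** uses the Power formulation: the sum of absolute
  backward differences of the six realignment parameters, with rotations
  converted to millimetres on a 50 mm sphere; FD of the first volume is 0.
- **Nuisance design**: intercept, linear trend, the Friston-24 motion
  expansion `[p, p^2, p(t-1), p(t-1)^2]`, white-matter and CSF mean signals,
  optionally the global mean (a flag, to support with/without-global
  comparisons), and one indicator ("spike") column per volume with
  FD > 0.5 mm. Scrubbing by spike regression rather than volume deletion
  keeps the regular temporal grid that Kendall's W requires. Rotations in
  motion files are radians.
- **Band-pass** (0.01-0.08 Hz) is an ideal frequency-domain filter: exact
  pass-band preservation and stop-band zeroing, verified against a Parseval
  oracle on white noise.

## Hierarchical parcellation

Label volumes at several scales are linked by fine-to-coarse merge maps;
every coarse region is exactly the union of its fine regions, labels at a
coarse scale equal the merge-map image of the fine labels, and in-mask voxel
counts are conserved. Merges across non-adjacent scales chain the stored
maps. Region metadata records hemisphere and cortical/subcortical
compartment.

## Classification (MVPA)

Per scale, subject-level features (voxel or regional ReHo) enter a
10-fold stratified subject-partitioned cross-validation. Within each
training fold only: two-group ANOVA F-scores rank the features (a feature
with zero within-group variance and a group-mean difference ranks first
with F = +inf); the top `ceil(fraction * n)` features are kept for each
fraction in the configured series (default 10%, 20%, ..., 100%); SVM
hyperparameters are chosen by inner cross-validation (default 5-fold) over
C-SVC with C in 1:5:100 (20 values) and nu-SVC with nu in 0.2:0.1:0.7
(6 values), each with linear, polynomial and RBF kernels — 78 combinations.
Ties take the first combination in the enumeration order linear < poly <
rbf, C-SVC before nu-SVC, smaller penalty first. The fraction with the best
mean held-out accuracy is reported (mean-over-folds is the primary figure;
the pooled-prediction accuracy is also computed).

Significance uses a permutation test: each permutation shuffles the labels
and re-runs the entire pipeline (scoring, selection, grid search, CV);
p = (1 + #{null >= observed}) / (B + 1) (add-one convention, so p is never
below 1/(B+1)). The study-scale default is B = 5000; desk-scale analyses in
the tests and the acceptance script use B = 199 (and B = 49 for the 50-seed
null-calibration check) with a reduced grid (linear kernel, C in {1, 16, 46},
fractions {0.5, 1.0}, 3 inner folds) — these sizes are the package's
desk-scale analysis configuration; the study-scale values remain the
defaults.

Consensus discriminative features are defined only when every fold chose a
linear kernel (weights cannot be read off non-linear machines; the call
refuses explicitly otherwise): features selected in *all* folds are ranked
by mean absolute weight and the top 20% kept. Their values are correlated
with the four symptom scores (Pearson, BH-FDR over all pairs).

The leakage contract (held-out subjects are touched only at prediction) is
enforced structurally — `fit_fold` receives explicit train/test indices —
and tested behaviourally: corrupting held-out labels must leave the
selected features, hyperparameters and weights unchanged.

## Expression processing

The probe pipeline runs in a fixed order: probe-to-gene reassignment
(table-driven; the mapping is an input), background filter (keep probes
detected above background in strictly more than 50% of samples), removal of
genes without RNA-seq coverage, removal of probes with Spearman rho < 0.2
against their gene's RNA-seq profile (refused on fewer than 4 shared
samples; constant probes dropped with a warning), representative-probe
selection (highest rho; ties to the lowest probe id), then differential
stability. Reordering these stages changes results; a test pins the order.

**Differential stability** is, per gene, the mean over donor pairs of the
Pearson correlation between the two donors' regional-mean expression
profiles over common regions (pairs with fewer than 3 common regions are
skipped and logged). The top `ceil(G/2)` genes by DS are retained.

Samples are assigned to the region of the nearest labelled voxel centre in
world millimetres, with a cap of twice the voxel size (a guard against
samples far outside the parcellation); exact ties go to the lowest region
id. Regional expression is the mean over assigned samples. Analyses are
restricted to left-hemisphere samples. Optional per-donor normalisation is
deliberately not applied by default.

## Co-expression modules (WGCNA-lite)

From gene-standardised rows: Pearson correlation, signed adjacency
`A = ((1 + r)/2)^beta`, topological overlap

    TOM_ij = (sum_{u != i,j} A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij),

average-linkage hierarchical clustering of 1 - TOM, and a static cut
(default height 0.99; clusters below `min_module_size` = 30 become the grey
module, labels renumbered by decreasing size). The soft power is the
smallest of 1..20 whose sign-corrected scale-free fit R^2 (log-log
regression of binned degree frequency) reaches 0.8, falling back to
beta = 12 with a warning. Analyses on fewer than 15 units are refused
outright — the same guard that makes very coarse parcellations (e.g. a
9-unit regional matrix) ineligible.

Module eigengenes are first principal components of the standardised module
submatrix, scaled to unit variance, with the sign fixed so the mean
correlation with member genes is non-negative; variance explained is
recorded. The grey module never enters eigengene output unless requested.

Two behaviours of the static 0.99 cut are worth knowing. First, dense
equal-size planted modules are intrinsically non-scale-free, so the fit
fallback (beta = 12) is the expected path on such data. Second, at low
powers the cross-module topological overlap can reach ~0.03, i.e. an
average-linkage merge height of ~0.97, below the 0.99 cut — cleanly
separated blocks then require a lower cut (the block-structure tests cut at
0.95). With the fallback power the default cut separates planted modules
reliably; background noise genes can still chain into modules (full-
partition ARI ~0.85 at defaults), while the planted genes themselves are
recovered essentially perfectly (ARI 1.0 across seeds). Recovery is
therefore scored on the planted genes, which are the ones with a defined
ground-truth module.

## Difference maps and spatial association

Case-control difference statistics are the t of the group term in
`y ~ 1 + group + age + sex` per unit (vectorised across units; collinear
covariates are dropped with a warning; voxel-level maps use the same linear
model). Regional values are screened for normality with a seeded
Monte-Carlo Kolmogorov-Smirnov test: because mean and SD are estimated from
the sample, the standard KS null is invalid, so the null distribution is
simulated (2000 draws, cached per sample size and seed — the p value is
deterministic). Bonferroni thresholds are alpha/m with m the number of units
at the scale.

Eigengene-difference-map association: at the voxel level the t value at
each tissue sample is the mean t over in-mask voxels whose centres lie
within a 6 mm sphere of the sample (no partial-volume weighting; samples
covering no voxel are excluded and logged); at regional levels the regional
t is used directly. Pearson correlations run separately for cortical and
subcortical units (expression profiles differ sharply between compartments);
BH-FDR q values are computed within compartment across modules, with the
raw p reported alongside — the correction is a package addition, flagged
for user awareness. Demographics: pooled two-sample t for age, Pearson
chi-square (df = 1, no continuity correction) for sex.

## Over-representation analysis

A local hypergeometric ORA stands in for web-service GO enrichment: for
each set, p = P(X >= k) with X ~ Hypergeometric(N, K, n), BH-FDR across all
sets tested, any GMT collection accepted. The default universe is the
post-DS retained gene list — the genes actually eligible — rather than the
full genome (selection-consistent background).

## Synthetic-data generator

The generator's defaults are the desk-scale study conditions: a 16x16x16
voxel grid (3 mm voxels, grid centred so hemispheres split at x = 0),
150 volumes at TR = 2 s, 30 patients + 30 controls, hierarchical block
parcellation with 16 -> 4 -> 2 regions, synchrony effect 0.8 in three
planted regions, 300 genes in three 80-gene modules across 200 left-
hemisphere samples from 4 pseudo-donors, 2 probes per gene, and noise SD
0.5. All randomness derives from one seed (outputs are bit-identical across
runs with the same configuration).

- **Synchrony model.** Patient voxels in effect regions are mixed with a
  region-shared latent series, `x <- (1-s) * noise + s * latent`,
  re-standardised — the smallest model that moves Kendall's W, because W
  responds directly to rank concordance of neighbouring series. The
  per-subject strength s varies mildly around the configured weight
  (relative spread 0.15) so that symptom scores have something to track.
- **Symptom scores** are normal with the published cohort means/SDs,
  correlated with the subject's latent effect driver by closed-form
  attenuation (score = rho*z + sqrt(1-rho^2)*noise), rounded to integers
  and clipped at scale minima; controls get no scores. Ages and sexes are
  drawn from the published group distributions.
- **Motion** traces are smooth random walks with 1-3 injected displacement
  spikes exceeding the 0.5 mm scrub threshold.
- **Compartments.** Hemisphere is the sign of the region centre's x world
  coordinate; the subcortical "core" is the innermost fraction of regions
  (default 0.3) by centroid distance from the grid centre — a rank-based
  shell that guarantees both compartments exist at every scale.
- **Expression.** Gene expression is module latent x loading (U(0.6, 1)) +
  noise; the planted module's latent is an affine function of the local
  effect-map value at each sample, hitting the configured eigengene-map
  correlation (default 0.7) in expectation. Probe 0 is the cleanest probe
  per gene; the below-background fraction is drawn from the redundant
  probes so every gene keeps at least one expressed probe (this keeps the
  noiseless round-trip well defined). The RNA-seq twin is a monotone
  transform (exp(x/2)) of the primary probe plus noise.

**What the generator does not emulate:** anatomical geometry, spatial
autocorrelation of BOLD noise, scanner artefacts, haemodynamics, realistic
gene-gene correlation beyond the planted blocks, donor batch effects, or
spatial autocorrelation of expression. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated generative
model, not performance on real data; in particular the near-perfect
classification accuracy at synchrony 0.8 reflects the strength of the
planted effect, not an expected clinical figure.

## Problem sizes used in tests and the acceptance script

Structural tests run on 10-12 voxel grids with 4-8 subjects. Recovery runs
use the generator defaults above; permutation inference uses B = 199
(null-calibration: 50 cohorts of 12+12 subjects on a 10-voxel grid at
B = 49); module recovery averages 10 seeds at 100 units; association
recovery averages 20 seeds at 200 samples. The full suite completes in a
few minutes on one CPU.

## Known limitations

- Static tree cut only; the dynamic hybrid cut used by many co-expression
  analyses is not implemented.
- The pipeline's choice of spike regression (vs volume censoring) and the
  regress-then-filter order are fixed conventions; alternatives change
  results and are not exposed.
- The ORA stand-in shares no database snapshot with any web service, so
  term-level results are not comparable across collections.
- Whether reported accuracy should be mean-over-folds or pooled is
  genuinely ambiguous; both are computed, mean-over-folds is primary.
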