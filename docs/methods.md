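# Methods

`seagea` detects loci putatively under selection along environmental
gradients in marine populations ("seascape genomics") and characterizes the
putatively adaptive population structure they imply.  This note documents
the statistical models, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the package's known
limitations.

## Genotype model and QC

Genotypes are diploid biallelic SNPs stored as minor-allele dosages
g ∈ {0, 1, 2} with NaN for missing calls.  The minor allele is defined
globally over all retained individuals and re-evaluated after individuals
are removed; the minor allele count (MAC) at a locus is
min(Σg, 2·n_obs − Σg), which makes the MAC filter invariant to ref/alt
relabeling.  Default filters: per-locus missingness ≤ 0.2 and MAC ≥ 3.

Duplicate and close-kin screening uses a genomic-relationship moment
estimator over pairwise-complete loci,

    r_xy = Σ_l (x_l − 2p_l)(y_l − 2p_l) / Σ_l 2 p_l (1 − p_l),

clipped to [−1, 1], with p_l the sample allele frequency.  Its expectations
are ≈1 for duplicates, ≈0.5 for parent–offspring and ≈0 for unrelated pairs
(with the usual −1/(n−1) finite-sample offset, which is why the estimator
assumes a panel of tens of individuals or more).  Pairs with fewer than 50
shared genotyped loci are not estimated.  Pruning is greedy at |R| ≥ 0.5:
repeatedly remove the individual in the most flagged pairs, breaking ties
by more missing data and then by lexicographically last sample id, so the
output never retains a pair at or above the threshold and is deterministic.
The estimator is pluggable; likelihood estimators (e.g. triadic ML) trade
implementation complexity for efficiency the thresholded screen does not
need.

## Spatial covariates

Oceanic distances are shortest over-water paths on the 8-connected graph of
water cells of an ESRI ASCII raster, with great-circle (haversine,
R = 6371 km) edge weights; points snap to the nearest water cell within a
50 km radius (configurable).  On an open-water grid the octile metric
overestimates the great-circle distance by at most ~8%, shrinking with cell
size.  Distances are computed between site centroids by default and
broadcast to individuals (individuals at one site share coordinates at
raster resolution); per-point mode is available.

Distance-based Moran's eigenvector maps (dbMEM) follow the classical
construction: truncate the distance matrix at t (default: the longest
minimum-spanning-tree edge), replace longer distances by 4t, double-center
−½d², and eigendecompose.  Positive-eigenvalue eigenvectors (positive
spatial autocorrelation) are the candidate spatial covariates, ordered from
broad- to fine-scale; eigenvalue order is monotone in Moran's I under the
truncated similarity weighting 1 − (d/4t)².

## Forward selection (spatial and environmental)

MEMs and environmental variables are selected against the multivariate
genotype response with one engine.  At each step the candidate adding the
most explained variance is tested with a **max-statistic permutation test**:
the observed best gain is compared with the best gain over *all* remaining
candidates recomputed under each permutation of the current model's
residuals.  Because the maximum is recomputed under the null, selecting the
best candidate does not inflate the test, and the probability of a first
false selection equals alpha by permutation symmetry (verified by Monte
Carlo: rejection ≈ 0.048–0.049 at alpha 0.05 over 1000 nulls).  A candidate
enters at p ≤ alpha; from the second step onward selection also stops when
the cumulative adjusted R² would exceed the global model's adjusted R²
(scope rule).  The first step is exempt from the scope rule: with
uninformative candidates in the set, a single strong predictor legitimately
exceeds the global adjusted R², and the first selection is already exactly
controlled by the max-statistic test.  alpha ≥ 1 disables both stopping
rules and returns a pure gain ranking (diagnostic mode).  Permutation
p-values are always (exceedances + 1)/(n_perm + 1).

Environmental variables are z-scored (sample SD), then pruned before
selection: stage 1 removes one member of each pair with |r| > 0.7 (the
member with the larger mean |r| to the remaining variables; later column on
ties), stage 2 removes the largest-VIF variable while any VIF ≥ 3, with
VIF_j = 1/(1 − R²_j) from the regression of column j on the others.

## Partial redundancy analysis

With Y the mean-imputed, column-centered dosage matrix, X the retained
environmental predictors and Z the selected MEMs: Y and X are residualized
on [1, Z] by least squares; Y's residual is regressed on X's residual; the
constrained axes are the SVD of the fitted values, with eigenvalues
s²/(n−1).  The variance partition reports conditioned (spatial),
constrained (environmental) and residual fractions of the total variance of
Y; they sum to 1 by construction.  Predictor columns made exactly collinear
by the conditioners are aliased (dropped with a warning), mirroring
constrained-ordination software, so conditioning on X itself yields a null
fit; collinearity within X itself is an error naming the offending columns.

Pseudo-F = (constrained/q)/(residual/(n − q − r − 1)); significance is by
permutation of the residuals of the reduced (conditioning-only) model, with
1000 permutations by default.  Marginal per-term tests move the other
predictors into the conditioning set; sequential axis tests condition on
the fitted scores of earlier axes and use the leading eigenvalue of the
remaining fit as the statistic.

Locus loadings are "species scores" (eigenvector × √eigenvalue); candidate
detection z-scores each significant axis's loadings and flags |z| ≥ 3 (the
threshold is configurable), resolving loci flagged on several axes to the
axis of largest |z|.  Under Gaussian loadings the flagged fraction is
2Φ(−3) ≈ 0.27%.  Each candidate is assigned the retained variable with the
largest |Spearman ρ| computed on the **raw observed** dosages over
pairwise-complete individuals — mean-imputed values would bias rank
correlations toward the site mean.

## Population structure of candidate loci

Per-site diversity: Ho is the heterozygote fraction; He is Nei's unbiased
2p(1−p)·2n/(2n−1), averaged over loci with ≥ 2 genotyped individuals at the
site.  Differentiation is Weir & Cockerham's (1984) θ with multilocus
values as ratio-of-sums of the a, b, c variance components; pairwise tests
permute individuals between the two sites (10,000 permutations by default)
and the resulting p-value matrix is controlled by Benjamini–Yekutieli
step-up at FDR 10% (BH is available; BY discoveries are always a subset of
BH discoveries at equal q).

Ancestry clustering is a maximum-likelihood binomial mixture (Hardy–
Weinberg within cluster) fitted by EM — best of 10 seeded random restarts,
relative log-likelihood tolerance 1e−6, 500 iterations cap — returning soft
memberships.  AIC = −2 logL + 2·K·L counts only the K·L cluster allele
frequencies (snapclust convention).  K is chosen by minimum AIC over K =
1…9 and, alternatively, by masked-entry cross-validation: 10% of observed
genotype entries are masked per replicate (10 replicates), the model is
refitted, and the mean squared error of predicting masked dosages from
membership-weighted expected dosages is minimized.  This reproduces the
K-selection surface of ADMIXTURE-style analyses without per-allele ancestry
block relaxation; individual admixture proportions here are posterior
membership probabilities, a documented behavioral difference.

## Genomic context and enrichment

SNP context classes from GFF3 gene/exon features with precedence exonic >
intronic > promoter > intergenic; the promoter is a strand-aware 2000 bp
window (configurable) upstream of the gene start.  GFF3 coordinates are
1-based inclusive; internal arithmetic is half-open 0-based.  GO enrichment
compares candidate loci against the full filtered locus background with
two-sided Fisher's exact tests per term and BH control at q = 0.05;
locus-level (not gene-level) counting is used throughout.

## Synthetic seascape generator

The generator emulates the sampling design the pipeline targets: 9 sites on
a 1-D coastline raster, 200 individuals (22–23 per site), 2000 neutral +
50 adaptive SNPs, ~1% missing data, and 3 planted duplicate individuals.
Environmental variables (5 by default, named after typical marine drivers)
are exact-correlation mixtures of smooth along-coast gradient shapes plus
site-level Gaussian noise (SD 0.1 on the standardized scale) with a default
target correlation of 0.4 (0.8 within the current-velocity pair).

Neutral site frequencies follow a 1-D stepping-stone chain: each site's
frequency is a Beta perturbation of a migration-weighted mix (m = 0.5) of
the previous site's frequency and the ancestral frequency; the Beta
concentration is calibrated by bisection against the package's own
Weir–Cockerham estimator on a 300-locus pilot so realized multilocus F_ST
matches the target (0.02 by default, matching weak marine differentiation).
Adaptive loci keep their stepping-stone frequencies and add a logit-scale
environmental term, p_s = logistic(logit(q_s) + b·z_s) with b = 2 per SD of
the driving variable (round-robin assignment, one variable per locus), so
b = 0 reduces exactly to the neutral model.  Genotypes are Binomial(2, p_s);
missingness is uniform at random.

What the generator does *not* emulate: linkage disequilibrium between loci
(all loci independent), haplotype structure, genotyping-depth-dependent
missingness or error, temporal sampling, and 2-D seascapes.  Passing tests
therefore demonstrate the statistical machinery under the stated
frequency-level model, not robustness to LD or genotyping artifacts.

## Confounding of space and environment

On a 1-D coast with site-level predictors, smooth environmental gradients
lie almost entirely inside the span of the broad-scale MEMs: with 9 sites
the between-site space has 8 dimensions, and conditioning on several
selected MEMs can absorb most true adaptive signal (measured on the default
fixture: mean recovery of planted loci drops from ~1.0 unconditioned to
~0.2 under full MEM conditioning).  The pipeline keeps the conditioned
partial RDA as its default — spatial conditioning is the appropriate guard
against neutral isolation-by-distance in real, 2-D, individual-level data —
but the candidate-recovery evaluation of the ±3SD detector uses the
unconditioned model, and users of strongly collinear designs should inspect
the aliasing report and the conditioned fraction before interpreting
candidate counts.

## Problem sizes and reproducibility

Default analysis sizes (the generator's study conditions) run the full
pipeline in well under a minute on one CPU; Monte-Carlo calibration checks
use 200 null datasets of 60 individuals × 200 loci, and clustering recovery
uses 90 individuals × 150 loci across 10 seeds.  A single global seed is
expanded per stage by a fixed derivation (stage-name CRC32, kept below
2³¹), so identical configuration and inputs give byte-identical reports and
any stage can be reproduced in isolation.
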