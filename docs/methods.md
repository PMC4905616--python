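# Methods

This note documents the statistical procedures implemented in `mmdpath`, the
parameter choices that matter, what the synthetic generators do and do not
emulate, and the numerical conventions that make results reproducible across
platforms.

## Kernel MMD test

Given two samples X (m observations) and Y (n observations) of pathway
feature vectors and a positive-definite kernel k, the test statistic is the
unbiased U-statistic estimator of the squared maximum mean discrepancy,

MMD² = (m(m−1))⁻¹ Σ_{i≠j} k(x_i,x_j) + (n(n−1))⁻¹ Σ_{i≠j} k(y_i,y_j)
     − 2(mn)⁻¹ Σ_{i,j} k(x_i,y_j).

Being unbiased, it can be negative on finite samples.  Two conventions for
the cross term circulate: the full double sum over all (i, j) pairs (the
standard U-statistic, used here by default) and a variant that skips the
"paired" i = j terms, which is only defined for m = n.  The variant is
available through `cross="exclude-paired"` for sensitivity checks; on the
bundled study data the two conventions lead to the same conclusions.

**Permutation null.**  Group labels are reassigned uniformly at random among
the pooled indices, preserving (m, n); the pooled kernel matrix is computed
once and never touched again.  With t permutations (default t = 2499),

p = (1 + #{b : MMD²_b ≥ MMD²_obs}) / (t + 1).

This estimator is never zero, is valid for any t, attains its floor
1/(t+1) = 4·10⁻⁴ at the default, and counts ties conservatively toward the
null.  (A formula of the form (t+1−r)/(t+1), with r the ascending rank of
the observed value, returns 0 when the observed statistic is the largest and
is therefore not used.)  The permutation loop is evaluated as batched
quadratic forms z′Kz over 0/1 membership vectors; a literal triple-loop
implementation is kept in the test suite as the independent oracle.

**Bandwidth.**  The Gaussian kernel is parameterized as
k(x,x′) = exp(−γ‖x−x′‖²).  The rate γ is estimated once, on the pooled
two-condition data, from the empirical distribution of nonzero pairwise
squared distances: the admissible interval is (1/q₀.₉, 1/q₀.₁) and the
default rate is 1/median (linear-interpolation quantiles).  Rationale for
each piece:

- *Pooled, once*: the permutation null must hold the kernel fixed; re-estimating
  per permutation would invalidate exchangeability.
- *Median*: any rate inside the quantile interval is considered acceptable;
  a deterministic midpoint rule is needed for reproducibility, and the median
  is the natural robust choice.  The bounds are always reported so
  sensitivity can be probed.
- *All pairs, no subsampling*: sample sizes in pathway testing are tens, not
  thousands, so the O(n²) distance set is cheap and removes a randomness
  source present in subsampling implementations of this heuristic.

Constant data (no positive pairwise distance) has no scale and is rejected.

**Multi-omics integration.**  Each block (genes, fatty acids, …) receives its
own Gaussian kernel with its own γ; integration is the unweighted sum of the
kernel matrices (weights are configurable but default to 1, and no kernel
normalization is applied by default).  A nonnegative combination of positive
semi-definite matrices is again a valid kernel, now over the concatenated
feature space.  Blocks must first be aligned to one sample order;
`align_samples` intersects and reorders explicitly — silent reindexing is
deliberately impossible, and file orientation must be declared rather than
guessed.

## Baseline tests

**Hotelling T².**  T² = (mn/(m+n)) (x̄−ȳ)′ S⁻¹ (x̄−ȳ) with pooled covariance
S; under normality (m+n−p−1)/((m+n−2)p) · T² ~ F(p, m+n−p−1).  When
p > m + n − 2 the pooled covariance is singular by construction and the test
raises `NotApplicableError` — reported as an outcome (a dash in result
tables), not a crash, because this structural failure is precisely the
regime the kernel test is designed to survive.  A conditioning threshold
(condition number > 10¹²) catches numerically singular cases.

**MST runs test (multivariate Wald-Wolfowitz, mWW).**  Build the Euclidean
minimum spanning tree of the pooled samples, delete every edge joining
samples from different groups, and count the remaining subtrees R (on a tree
R = between-group edges + 1).  Small R indicates separation, so the test is
lower-tailed.  Default inference is by label permutation on the fixed tree,
p = (1 + #{R* ≤ R_obs})/(t+1), valid at the tiny group sizes (4–8 per arm)
this problem class produces.  The classical standardized statistic
W = (R − E[R])/√Var[R] is reported alongside, with

E[R] = 2mn/N + 1,
Var[R] = (2mn/(N(N−1))) [(2mn−N)/N + ((C−N+2)/((N−2)(N−3)))(N(N−1)−4mn+2)],

where N = m + n and C = Σ_v deg(v)(deg(v)−1)/2 counts edge pairs sharing a
node.  Both formulas are verified in the test suite by exhaustive enumeration
of all labelings on trees with N ≤ 8.  An asymptotic lower-tail normal
p-value is available for large N.  Because R is integer-valued and heavily
tied, the permutation p-value is slightly conservative (null rejection rate
≈ 0.035 at α = 0.05 in the calibration study below) — expected for a
discrete statistic, and preferable to anti-conservatism.

**MST-rank Kolmogorov-Smirnov test (mKS).**  The pooled points are ranked by
a height-directed preorder (HDP) traversal of the MST: the root is a node of
maximal eccentricity, and each node's children are visited in order of
increasing subtree height.  The statistic is the classical two-sample KS gap
D = max_i |F̂₁(i) − F̂₂(i)| over prefixes of that ranking, left unscaled in
[0, 1]; inference is by label permutation on the fixed ranking (so no
asymptotic KS distribution is needed and scaling is irrelevant).

Numerical conventions shared by the MST machinery, chosen so independent
reimplementations can agree edge-for-edge: candidate edges enter Kruskal's
algorithm in lexicographic (i, j) order, making equal-weight ties
deterministic (tie-broken trees can otherwise differ in R by ±1);
eccentricity uses unweighted hop distance (scale-free, matching the ranking
intent); all remaining ties (root choice, child order) break by smallest
node index.  The permutation p-value is invariant to any fixed traversal
convention, so these choices affect only the reported ranking, not validity.

**Integrated runs for baselines.**  The baselines operate in the raw
Euclidean feature space, not the kernel embedding; for multi-block analyses
their input is the column-concatenation of the aligned blocks.

## Kernel PCA and arrow fields

The double-centered kernel K̃ = HKH (H = I − 11′/n) is eigendecomposed;
sample coordinates on component k are √λ_k · v_k, and dual coefficients
v_k/√λ_k normalize each feature-space axis to unit norm.  On a linear kernel
over column-centered data this reproduces classical PCA scores, which is the
oracle test.  Component signs are fixed by making the largest-magnitude
coordinate positive, so output is identical across eigensolvers.  Requesting
more components than positive eigenvalues is an error.

To show how a single gene (or fatty acid) varies across the sample map, the
feature is smoothed over the 2-D embedding with a Nadaraya-Watson estimator
(Gaussian weights, per-axis Silverman bandwidth
h_j = (4/(d+2))^{1/(d+4)} n^{−1/(d+4)} σ_j with d = 2), and the arrow at each
sample is the analytic gradient of that smooth surface — the local direction
of maximum growth of the feature.  This smoother-gradient construction is
this package's own surrogate for published arrow displays whose exact
algorithm is not specified; it is fully documented, testable in closed form
(constant features give exactly zero arrows; a feature equal to an embedding
coordinate gives arrows along that axis; the field is rotation-equivariant
for isotropic bandwidths), and deliberately isolated behind
`variable_arrows`.  Both the per-sample field and its mean vector per feature
are exported, since either may be the display of interest.

## Synthetic data and calibration

The generators implement the weakest model consistent with the assumptions
of the tests under study: per block, samples are multivariate Gaussian with
unit variances and exchangeable correlation ρ; the alternative adds a mean
shift δ to a designated feature subset of one block.  Hotelling assumes
exactly this world; MMD/mWW/mKS are model-free, so the Gaussian null is the
natural shared calibration target.

`generate_nutrimouse_like` emulates the bundled study's design — 40 samples
in a balanced genotype (20/20) × diet (5 × 8) layout, blocks of 120 genes and
21 lipids — with the 17 catabolism-pathway genes (real dataset names, so the
bundled GMT applies to synthetic data too) shifted by δ_genotype = 1 between
genotypes, and the three ω3 fatty acids raised by δ_diet = 2 under the fish
diet and δ_diet/2 under linseed, over a baseline with ρ = 0.2.  These
defaults give the same qualitative structure as the real data (strong
genotype signal in the pathway genes; a diet contrast carried by lipids, not
genes) at ordinary effect sizes for this assay class.  Not emulated:
macroarray noise (non-Gaussian, heteroscedastic), the compositional
sum constraint on fatty-acid percentages, and realistic gene-gene
correlation structure.  Passing calibration here therefore demonstrates
validity under the tests' nominal assumptions, not robustness to every
real-data pathology — though the permutation tests are exactly valid under
exchangeability regardless of the data distribution.

The calibration study (`rejection_rate`) draws 500 independent datasets at
m = n = 20, p = 16, δ = 0, runs each test at α = 0.05 with t = 99
permutations, and checks the rejection count against the central 95% region
of Binomial(500, 0.05).  Replicate seeds are spawned from one master seed;
every result object records its seed.  t = 99 suffices because only the
event p ≤ 0.05 matters for calibration; the analysis default stays t = 2499.

## Bundled data

`mmdpath.data` ships the public nutrimouse nutrigenomic dataset (as
distributed with the mixOmics R package) as plain TSV: 40 × 120 gene
expressions, 40 × 21 fatty-acid concentrations, genotype/diet metadata, and
a GMT file with the 17-gene catabolism pathway (the dataset spells one
member `PMDCI`) and the three ω3 fatty acids.  Published sources describe
the pathway as "16 genes" while listing 17 names; the package treats the
gene set as caller-supplied data and bundles the full 17-name list.

## Known limitations

- The MMD test uses only the permutation route; the spectral asymptotic null
  of the U-statistic is not implemented.
- Bandwidth selection is a heuristic; results at the permutation floor are
  insensitive to it, but borderline p-values can move within the reported
  γ bounds (the sun-vs-fish genes-only contrast, for example, is
  non-significant across the admissible range but its exact p varies).
- No missing-data handling, normalization or batch correction: inputs are
  taken as analysis-ready, and missing values are a hard error.
- mWW's permutation p-value is mildly conservative due to discreteness of R
  (see above); mKS is less affected.
- Kernel weights are fixed by the user (default: plain addition); no
  multiple-kernel-learning weight optimization is attempted.
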