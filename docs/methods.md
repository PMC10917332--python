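# Methods

This note records the models implemented in `pfda_audit`, the defaults and
why they were chosen, the numerical decisions that affect reproducibility,
and what the synthetic generators do and do not emulate.

## The discriminant model

Each specimen is a point **x** = (log₁₀ *MD*, *Cg*). Two-class LDA assumes
class *k* is bivariate normal with centroid μ_k and a single shared
covariance Σ; a point is assigned to the class whose centroid is nearest in
the Mahalanobis metric of the pooled within-class covariance (unbiased
estimator, divisor *n* − 2), and with equal priors the class-2 posterior is
a logistic function of the signed distance along the one discriminant axis.
Discriminant scores are standardized to unit within-class variance with
zero at the midpoint between centroids, so they are comparable across fits.

For the symmetric benchmark used throughout — centroids (1.2, −1.2) and
(−1.2, 1.2), Σ = σ²·I, so each centroid sits d = 2.4/√2 ≈ 1.7 from the
ideal boundary y = x — the exact misclassification probability is

    P_wrong = ½ · erfc( d / (σ·√2) ),

the quantity every empirical error converges to as *n* grows. (One source
text describes Σ as σ²/2 times the identity while all of its worked numbers
require Σ = σ²·I; the latter is implemented. A related prose claim that
d = σ misclassifies 68.27% of points contradicts the formula, which gives
15.87%, and is not reproduced.)

## The phylogenetic variant

pFDA with a linear boundary is phylogenetic LDA: under Brownian trait
evolution the tip covariance is C[i,j] = depth of MRCA(i,j), Pagel's λ
scales its off-diagonals (λ = 0: independent tips; λ = 1: full Brownian
structure), and the data are whitened by the inverse lower Cholesky factor
of C(λ) before fitting. Two formulation details matter:

- **The intercept must be whitened too.** Whitening only the trait columns
  injects the grand mean into every transformed row (row sums of the
  whitening factor differ across taxa) and destroys class structure; the
  implementation whitens the design [1 | X] and the class indicator with
  the same factor and fits the discriminant by optimal scoring (a GLS
  regression of the indicator on the design), then applies 1-D LDA to the
  resulting discriminant variate. On ultrametric trees this reduces exactly
  to ordinary LDA as λ → 0 (verified to 1e-12).
- **Test taxa are whitened jointly** with the training taxa, using their
  positions in the same tree; the whitening factor is lower triangular with
  training rows first, so the training block is self-contained.

λ is estimated, unless fixed by the caller, by profile maximum likelihood
of the predictor matrix under Brownian motion (per-column profiled mean and
rate, columns summed), with a 0.01-step grid scan refined by bounded scalar
optimization. Parameter recovery on simulated data at 200 tips is within
±0.1 (median) for λ ∈ {0, 0.5, 1}. Branch-length uncertainty is emulated by
multiplying every branch by an independent Uniform(0.5, 1.5) factor per
ensemble tree (topology preserved, seed-reproducible); the scheme and λ
re-optimization per tree are both configurable.

## Performance metrics and the randomness heuristic

Confusion matrices are fixed to rows = true class, columns = predicted;
a `transposed_legacy()` view reproduces the orientation printed by some
discriminant codebases. Reported together, always: accuracy *A*, balanced
accuracy *B*, Matthews correlation *MCC*, and P_rand = 2(1 − A), the
fraction of purely random classifications that yields the same accuracy
(clipped to [0, 1]; below-chance classifiers are outside the heuristic's
domain). The conventional 5% randomness threshold corresponds to
A ≥ 0.975.

## Bootstrap and BCa intervals

The taxon bootstrap resamples taxa with replacement to the original size
and reruns the discriminant over a fresh tree ensemble per trial
(n_trials × trees_per_trial samples; defaults 2000 × 100, scaled down in
tests). Resamples that collapse a class below 3 records are redrawn, so the
sample count is exact. Duplicated taxa cannot be placed on a fixed
published tree, so bootstrap runs on synthetic topologies use a
`tree_builder` hook that generates a pure-birth topology over exactly the
resampled taxa.

BCa intervals follow the standard construction: bias correction
z₀ = Φ⁻¹(fraction of bootstrap samples below the original-sample
statistic), acceleration from the jackknife skewness, endpoints as order
statistics at the adjusted quantiles. With zero bias and acceleration the
interval reduces to the percentile method; coverage on a known-mean normal
resampling experiment (n = 100, B = 999) is 94.5% over 1000 replicates.
Note a known failure mode retained deliberately: when the bootstrap
distribution is strongly biased relative to the original-sample statistic
(as happens for training accuracy, which duplicated resample points
inflate), |z₀| becomes large and the BCa interval can shift below the
bootstrap median — the bias correction working at the edge of its validity.

## Composition tests

Two probes of whether a class is a representative extinct/extant sample:

- **Permutation rank test** — two-sided rank-sum (Mann–Whitney-type)
  statistic under label permutation, p = (b + 1)/(N + 1); rank-based and
  hence invariant under monotone transforms. The source study reported a
  far smaller p on the printed diver subset (0.0011 where the rank-sum
  statistic gives ≈0.073) without stating its statistic; the documented
  statistic is implemented and the discrepancy is surfaced by the
  acceptance suite rather than hidden.
- **Coin-flip point probability** — C(n, k)/2ⁿ computed in log space;
  this point-probability form (not a tail) reproduces every verifiable
  published value (0.112, 2.1×10⁻¹⁶, 0.00019, 0.00142, 8.7×10⁻¹²) and is
  validated against an exact integer-arithmetic oracle. One published row
  (a 35/15 split listed with 1.7×10⁻¹¹, which is the value for 3-of-50) is
  internally inconsistent and is not built upon.

## Power analysis

Training accuracy — deliberately the optimistic in-sample quantity — is
simulated by a vectorized LDA (closed-form 2×2 pooled-covariance inverse),
pinned against the reference per-fit implementation on identical draws.
Percentile (not BCa) bands are used here, matching the histogram-quantile
presentation of the sample-size analysis. Defaults reproduce the published
anchors: at n = 59, σ = 1.414 the 95% band is (0.831, 0.941) around a
theoretical 0.885; A_LB ≈ 0.973 at d/σ = 2.0, n = 2560; A_LB ≥ 0.975 at
d/σ = 2.5 with only 20 points per group. CI width is fitted as a/√n by
least squares per σ.

## Distribution and clustering diagnostics

Candidate families for discriminant scores: normal; "pooled normal"
(class mean free, sd pooled across both classes — the discriminant's own
assumption, with the pooled sd charged as a parameter, k = 2); uniform
(MLE = data range); logistic; 3-parameter (location-shifted) Weibull;
2- and 3-component normal mixtures (k = 3c − 1, seeded scikit-learn EM);
and a uniform+normal mixture (custom EM, support fixed at the data range,
k = 5). AICc uses n = number of scores. Akaike weights are normalized to
P_dist; the joint normality probability of a dataset is the product of the
two classes' pooled-normal P_dist values. A caution from simulation: at
n ≈ 59 the logistic family (same k) frequently edges out the normal on
genuinely normal data, so "the normal has strong support (ΔAICc < 2)" is
the reliable statement, not "the normal ranks first".

Variance equivalence is tested three ways, all robust to non-normality:
Brown–Forsythe (Levene on medians) and Levene via scipy, and Conover's
squared-ranks test (normal approximation) implemented here and validated
against a permutation oracle.

The Hopkins statistic compares nearest-neighbour distances of m uniform
probe points (u) and m marked data points (w): H = Σuᵉ/(Σuᵉ + Σwᵉ), ≈ 0.5
for spatial uniformity, → 1 for clustered data. Variants: original
(exponent = dimension, bounding-box window), Lawson–Jurs (exponent 1),
Fernández Pierna–Massart (dimension exponent, probes confined to the
data's convex hull). The marked points are removed from the reference set
so both distance sets face the same intensity — with that, in an edge-free
window (known bounds, toroidal distances) the single-trial null is exactly
Beta(m, m) (KS distance 0.009 over 10,000 uniform sets at n = 200). H is
reported as the mean of 100 random 20% subsamples, with p-values from the
Beta law and from a Monte Carlo null matched in size, window and subsample
averaging. For real data the window defaults to the data's bounding box;
boundary effects then make the Beta p approximate, which is why the Monte
Carlo null is the default decision tool.

## Variation statistics and the sensitivity grid

The relative range (max − min)/mean × 100 summarizes repeat *Cg*
measurements; the embedded 19-entry compilation has median 18.6%. Entries
are recomputed from raw measurement values as printed, including one
anomalous third measurement row in the Scutellosaurus entry that the
printed 18.6% median requires. Between-class contrast applies the same
formula to the two class means (denominator: their mean), reproducing the
published 31.8% femoral figure. The within-genus allometry check is OLS of
*Cg* on linear *MD* (linear, not log, axes — the published x-intercept of
103 mm only arises on linear axes); for the six Nothosaurus femora it
gives R² = 0.955 and x-intercept 102.6 mm.

The sensitivity grid reconstructs all 24 published alternative spinosaurid
test points from their rules (diameter upscaling by (1/0.72)^1.5 = 1.6368
for a specimen at 72% of adult linear size; remeasured or 0.9-scaled
compactness values). One published inconsistency is preserved as printed:
the reduced-*Cg* Suchomimus rows are labelled "scaled by 0.9" but print
0.628 rather than 0.682 × 0.9 = 0.6138; the printed value is encoded.
Variant evaluation reports the bootstrap median P₂ with its BCa interval
and flags "strong support" only when the interval's lower bound reaches
0.95 (being 95% confident of at most 5% classification error).

## Synthetic data: what it does and does not show

All generators are bit-reproducible from their seed. The two-class
Gaussian generator *is* the power-analysis model, so those experiments are
exact by construction. The pure-birth/Brownian generator produces data
that genuinely satisfy the phylogenetic model, which is what makes λ
recovery and whitening checks meaningful. The status-shift generator draws
*Cg* from a Beta(6, 2) base (support respected, right-skewed toward high
compactness like real diver data) with an additive shift for the extinct
group, clipped into (0, 1].

The femoral stand-in deserves emphasis: its diver class is the real
published 59-specimen subset, but its terrestrial class is **synthetic**,
generated from published summary facts only — 59 specimens, mean *Cg*
0.610, a uniform law (the class's discriminant scores were reported
statistically indistinguishable from uniform) whose width is set by the
published scale ratio between the classes (uniform span 3.206 vs diver sd
1.338 in discriminant units, mapped through the diver subset's *Cg* sd),
and log-diameters centred on the published class median of 11.5 mm with
the diver subset's spread. Scaled-down bootstrap runs on this stand-in
(200 trials × 10 synthetic trees at λ = 0.05) give median training
accuracy 0.84, qualitatively matching the published full-scale 0.795 —
but the stand-in cannot reproduce the real class's fine structure,
phylogenetic signal or measurement error, so agreement at that level is a
pipeline check, not a replication. Full replication would require the
study's raw training files and supertree, which are external supplementary
material, plus ~200,000 pFDA runs.

## Numerical choices and degenerate inputs

- Whitening uses the inverse lower Cholesky factor; any square root gives
  an equivalent GLS fit. Singular tree covariances (duplicate tips at zero
  distance) raise a tree-diagnostic error.
- Pooled covariance divisor n − 2; fits reject classes with < 3 points,
  coincident centroids, or collinear points.
- Equal class priors by default (configurable); classification threshold
  0.5 on the posterior by default, with threshold sweeps exposed because
  raising the threshold misclassifies more of the training set.
- Degenerate bootstrap resamples are redrawn, not dropped; all-equal
  bootstrap samples yield a flagged degenerate (c, c) interval.
- Coin-flip probabilities are computed via log-gamma in log2 space, exact
  to 1e-12 against integer arithmetic for n ≤ 64.
- Duplicate points in Hopkins inputs are jittered by 1e-9 of the data
  scale (flagged in the docstring) to avoid zero nearest-neighbour
  distances.
- Monte Carlo problem sizes in the test suite (e.g. 200 bootstrap trials ×
  10 trees, 3–5 simulations per λ value, 10,000 Hopkins null sets) are the
  package's chosen desk-scale defaults; the full-scale published settings
  (2000 × 100 bootstrap, 16 × 10⁶ permutations) remain available through
  the same interfaces.

## Known limitations

- The permutation "rank distribution" statistic of the source study could
  not be identified; the rank-sum choice is documented and the numerical
  discrepancy (0.073 vs 0.0011) is left visible.
- λ estimation uses the predictor matrix without class structure; on
  strongly non-Brownian data the ML λ can be large even when classes carry
  no phylogenetic signal, which is why analyses here fix λ ≈ 0.05 (the
  published order of magnitude) unless estimation is requested.
- Tree topology is taken as given (randomized branch lengths only); no
  topology uncertainty is modelled.
- Only two predictors and two classes are supported — one discriminant
  axis; no quadratic boundaries.
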