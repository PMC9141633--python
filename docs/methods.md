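# Methods

## The estimation problem

Functional connectivity (FC) is the statistical dependence between the
temporal activity of two brain regions. In voxel-resolved data each region
is a voxels × timepoints matrix, and the standard estimator — the absolute
Pearson correlation between the two regions' voxel-average series — has two
structural blind spots: it only sees *linear* dependence, and averaging
collapses the multivoxel pattern to one series, discarding the spatial
information the pattern carries. `copulafc` implements a multivariate,
rank-based alternative and the benchmarking machinery to compare the two
families.

## Gaussian-copula mutual information

Mutual information between continuous variables equals the negative
differential entropy of their copula, so MI can be estimated without
modelling the marginals: each dimension is mapped through its empirical CDF
and the standard-normal quantile function,

    z_i = Φ⁻¹( rank(x_i) / (n+1) ),

after which every marginal is standard normal by construction and all
dependence lives in the joint distribution of the z's. Fitting a Gaussian
to that copula gives the closed form (in bits)

    H(X)  = ½ log₂( (2πe)^k |Σ_X| )
    MI(X,Y) = ½ log₂( |Σ_X| |Σ_Y| / |Σ_XY| ),

with Σ estimated as the sample covariance (1/(n−1)) of the transformed
data. Because a Gaussian has maximum entropy for a given covariance, the
Gaussian-copula value is a *lower bound* on the true MI. Because the
transform uses only ranks, the estimate is exactly (bit-identically)
invariant under strictly increasing transformations applied per dimension.

Two consequences worth stating plainly:

- **Blindness to even dependence.** The estimator depends on the data only
  through covariances of rank-transformed variables. If Y is an *even*
  function of a sign-symmetric X (e.g. Y = X² with X zero-mean Gaussian),
  every such covariance is exactly zero in population, so the estimate is
  zero even though the true MI is large. Any correlation-of-monotone-
  transforms statistic shares this blind spot; histogram or
  nearest-neighbour MI estimators do not. This is why the squared-mapping
  benchmark scenario below defeats *all four* measures here, including the
  copula-based ones — see "Known limitations".
- **Negative estimates.** Sampling noise in the determinants can push the
  raw value slightly below zero; values are clipped to 0 (with a warning
  beyond 1e-6 bits).

An optional digamma-style finite-sample bias correction (from the Wishart
expectation of log-determinants) is implemented but off by default, so the
default estimate matches the closed form literally.

### Rescaling to a correlation-like magnitude

For univariate Gaussians MI = −½ log₂(1 − r²). `rescale_mi` inverts this,
mapping an MI of m bits to √(1 − 2^(−2m)) ∈ [0, 1): strictly increasing,
0 ↦ 0, and equal to |r| for Gaussian data. This puts the MI measures on the
same scale as |Pearson r| for fair comparison. (The rescaling is a smooth
power-type transformation of 2^(−2m); among the candidate maps to [0,1] it
is the unique one that recovers |r| exactly in the Gaussian case, which is
why it was chosen.)

## The four connectivity measures

| measure | region summary | dependence statistic |
|---------|----------------|----------------------|
| `pcor`  | voxel average | abs Pearson r |
| `svd_fc`| first temporal singular vector of the voxel-centered matrix | abs Pearson r |
| `uv_mi` | voxel average | rescaled Gaussian-copula MI |
| `mv_mi` | top-5 PCA score series | rescaled Gaussian-copula MI (10-dim joint) |

PCA conventions: per-voxel mean removal over time, no variance scaling
(amplitude information retained); components ordered by decreasing
explained variance; each component's sign fixed so its largest-magnitude
voxel loading is positive (irrelevant to the rank-based MI, but makes
intermediate outputs reproducible). When a region cannot support the
requested component count (fewer voxels, fewer than k+1 timepoints, or rank
deficiency) the count shrinks with a warning rather than failing. With
1-voxel regions `svd_fc` equals `pcor` and `mv_mi` equals `uv_mi` exactly.
`mv_mi` requires n_timepoints > 2·n_components + 1 so the 10-dimensional
copula covariance is full rank.

Exact rank invariance holds per input dimension for `gcmi`/`uv_mi`. For
`mv_mi` the invariance is inherited at the PCA-score stage, so the maps
under which the value is bit-identical are those commuting with PCA:
common positive-affine rescalings of a region and voxel reorderings —
not arbitrary per-voxel monotone maps, which change the PCA basis.

## Two-region simulation benchmark

Region X (default 100 voxels × 500 timepoints) is drawn i.i.d. over time
from N(0, Σ). Three homogeneity regimes for Σ (strength c = 0.9 by
default):

- homogeneous: (1−c)·I + c·𝟙𝟙ᵀ — all voxels strongly positively correlated;
- independent: I;
- mixed: (1−c)·I + c·vvᵀ, v = +1 on the first half and −1 on the second —
  two anticorrelated blocks.

Region Y (default 150 voxels) is Y_t = f(X_t T) + w_t:

- **linear**: T's first 100×100 block is the identity (one-to-one voxel
  mapping); the remaining 100×50 entries are N(0, 0.1²) noise weights;
  f = identity.
- **nonlinear_square**: same T; f squares elementwise.
- **multivariate**: T dense with entries N(0, 1/√N_x) and the empirical
  grand mean of T subtracted. The centering matters: the grand mean of a
  raw i.i.d. draw couples the two regions' voxel-average series (the
  covariance of the averages is proportional to the grand sum of T), which
  would give the scenario a univariate average-to-average component on top
  of the multivariate one it is meant to isolate. Removing it zeroes both
  average-channel terms exactly while leaving the per-voxel amplitudes
  O(1), so only genuinely multivariate estimators (and the SVD summary,
  when a dominant within-region direction exists) can see the interaction.
- **structural_noise**: the linear scenario plus one shared noise series
  added to every voxel of Y (global artifact, e.g. motion), sd 12 by
  default. The magnitude is chosen so the shared noise actually defeats
  the average-based measures at n = 500: the permutation-null 95th
  percentile of |r| is ≈ 1.96/√n ≈ 0.088, and the average-series
  correlation under shared noise of sd s is ≈ σ_signal/s, so s must exceed
  σ_signal/0.088 ≈ 11. The multivariate measure is unaffected because the
  shared series occupies a single PCA direction of Y, leaving the other
  components carrying the interaction.

Measurement noise w_t (sd 0.5) is added to both regions by default (a flag
restricts it to Y). X is temporally white: no haemodynamics and no
autocorrelation are modelled, so permutation nulls are exact by exchange-
ability — with autocorrelated real data the same shuffle would be
anticonservative.

### Performance metric and permutation null

For one simulated pair, the null distribution of a measure is obtained by
independently permuting every voxel's time series in both regions
(destroying cross-region *and* cross-voxel alignment while preserving each
voxel's marginal) and recomputing the measure, 100 times by default. The
95th percentile uses linear interpolation between order statistics (the
convention is visible at n_perm = 100, so it is fixed and documented). A
connection is significant when its observed value strictly exceeds the
threshold — ties count as non-significant — and

    performance = observed FC − 95th-percentile(null),

positive when the measure detects the interaction. Scenario results are the
mean ± sd of performance over independent repetitions (20 in the test
suite, 10 in the acceptance script; the qualitative pattern is stable from
about 10 repetitions on). No multiple-testing correction is applied across
edges anywhere — verdicts are raw per-edge 95th-percentile calls, a known
limitation.

## Graph-level analyses

`assemble_fc` evaluates a measure on all region pairs of a subject.
Given a region→network assignment (seven networks by default), edges split
into within-network (endpoints share a label) and between-network classes.

- **Measure similarity**: Spearman rank correlation between two matrices'
  upper triangles, optionally restricted to one network-pair block.
  Rank-based, so common monotone rescalings are irrelevant.
- **Thresholding**: entries below a fraction of the matrix maximum set to
  zero (fractions 0.1/0.2/0.3 in the pipeline defaults).
- **Nonrandomness**: the weighted matrix is binarized by keeping the top
  `density` fraction of edges (default 0.10; the construction of the graph
  from a weighted FC matrix is a package choice, always logged). On the
  largest connected component, nodes are embedded with the k leading
  adjacency eigenvectors (k = 7 by default, matching the seven-network
  grouping) scaled by √2; each edge's nonrandomness is the inner product of
  its endpoints' embeddings, and the per-edge values over present edges sum
  exactly to the sum of the k leading eigenvalues — the graph-level
  statistic. Community-structured graphs score high, density-matched
  Erdős–Rényi graphs low, and edges bridging two communities get small
  per-edge values. (The √2 scaling is what makes the per-edge
  decomposition tile the eigenvalue sum over unordered edges:
  Σ_edges 2·v_j(u)v_j(v) = v_jᵀAv_j = λ_j.)
- **Subject similarity**: Pearson correlation between each subject's
  (scoped) upper triangle and the element-wise mean matrix over all
  subjects — plain average including the subject itself, with a
  leave-one-out option. Pearson rather than rank correlation here,
  reserving rank correlation for between-measure comparison.

## Synthetic cohort

`generate_cohort` emulates the structure those analyses need without any
real data: seven networks × 4 regions, 8–12 voxels per region, 150
timepoints, 8 subjects by default. Latent network signals and a weaker
global signal are shared across subjects (within_strength 1.0 >
between_strength 0.3), each subject adds region-level noise (sd 0.6) and
voxel-level noise (sd 0.6), and — crucially — each subject draws its own
per-voxel signal weights ~ N(0.5, 1.0). The mixed-sign weights make
regional homogeneity differ across subjects: a region whose weights
partially cancel has a nearly signal-free voxel average for that subject,
degrading the average-based measures' consistency across subjects, while
the multivariate route recovers the latent direction from the voxel
pattern regardless of the weights' signs. An optional strictly monotone
per-region distortion (x + a·x³ or a signed power, drawn once per region
and shared across subjects, as a region's response profile is a property
of the region) makes amplitudes non-Gaussian in a region-specific way —
invisible to rank-based measures, harmful to Pearson-based ones.

What the generator does *not* emulate: haemodynamic response, temporal
autocorrelation, spatial voxel geometry, scanner drift, or subject motion.
Tests passing on this cohort show the estimators respond to network
structure, shared backbones and inhomogeneity as intended; they do not
certify behaviour under real BOLD noise.

## Numerical choices

- Log base 2 throughout; all entropies and MI in bits.
- Empirical CDF as rank/(n+1), avoiding ±∞ quantiles; ties averaged by
  default ("ordinal" available).
- Covariances: sample covariance, 1/(n−1). If the smallest eigenvalue is
  below 1e-10 × trace, one shot of 1e-10 × trace jitter is added; if still
  not positive definite, the operation fails reporting the smallest
  eigenvalue.
- Percentiles: linear interpolation, fixed.
- Significance: strict inequality at the threshold; ties non-significant
  (conservative).
- Every random operation takes an explicit seed; pipeline stages derive all
  seeds from one run seed, and outputs carry the hash of the producing
  configuration, so reruns are byte-identical.

## Problem sizes used in the automated checks

Estimator consistency uses n = 10,000 samples over 20 seeds; type-I
calibration uses 12/15-voxel regions at n = 500 (the calibration concerns
the permutation machinery, not region size) over 200 runs; scenario
reproduction uses the full 100/150-voxel, 500-timepoint design at 20
repetitions × 100 permutations; the SVD/PCor comparison uses 100
homogeneous pairs whose measurement-noise sd spans 0.2–8 geometrically so
pair strengths cover the weak-to-strong range (with one fixed noise level
all pairs share one FC value and a rank correlation across pairs would be
meaningless); the cohort checks use the default 8-subject cohort.

## Known limitations

- The Gaussian-copula MI is blind to purely even dependence (see above).
  In the squared-mapping scenario with zero-mean X this is not a
  finite-sample effect: the population value is exactly zero for *all*
  summaries (averages, SVD vectors, PCA scores), so no measure in this
  package detects that scenario, and benchmark conclusions about
  "nonlinear sensitivity" of the MI measures only apply to nonlinearities
  with an odd/monotone component.
- Permutation nulls assume temporal exchangeability; real BOLD series are
  autocorrelated.
- The estimator is a lower bound on MI; heavy-tailed or tail-dependent
  copulas (checked against a KNN estimator on t-copula data in the tests)
  lose dependence mass.
- Per-edge significance is uncorrected for multiple comparisons.
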