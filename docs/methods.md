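# Methods

## Model and estimator

`sidcor` estimates dependence between features of a samples × features
numeric matrix with the plain V-statistic form of distance correlation.
For feature vectors X, Y observed in n samples:

1. pairwise Euclidean distances a_jk = |x_j − x_k| (for the one-to-all
   mode, b_jk is the Euclidean norm of the (m−1)-dimensional difference
   between sample rows of all remaining features);
2. double centering A_jk = a_jk − ā_j· − ā_·k + ā_·· (every row and column
   of A sums to zero);
3. dCov²(X,Y) = (1/n²) Σ_jk A_jk B_jk, dVar(X) = dCov²(X,X),
   dCor = dCov/√(dVar_X·dVar_Y) ∈ [0,1].

dCor is zero only under full independence and is invariant to affine maps
of either variable, which the property tests assert directly. The
bias-corrected estimator and the O(n log n) univariate algorithm are
deliberately not implemented: target data are tens of samples, where the
V-statistic is the form the downstream significance formulas assume and
runtime is negligible.

**One-to-all square root.** The joint distance uses the true Euclidean
norm (with square root) in (m−1)-space. The no-root variant would silently
replace the metric with squared Euclidean distance and change the
statistic; with the root, a single-column "block" reduces exactly to the
univariate distance, which is the consistency the tests pin.

**Sign.** dCor carries no direction, so the sign of the pairwise Pearson
correlation is attached (signed dCor = sign(r)·dCor). Tie-break: |r| <
1e-15 resolves to +1, so a numerically-zero Pearson (e.g. y = x² on a
symmetric grid) gives a deterministic positive sign. In one-to-all mode
the pair has no single Pearson partner; the sign convention is the Pearson
correlation between the feature and the per-sample mean of the other
features, and the unsigned dCor column is always present so no information
rests on the convention.

**Significance.** p = 2·(1 − F_t(t; n−2)) with t = dCor·√(n−2)/√(1−dCor²).
This borrows the Pearson-test transform and is a *screening* p-value:
monotone in dCor and in n (asserted by tests), but not calibrated under
independence — the permutation energy test would be the rigorous
alternative and is out of scope. dCor = 1 maps to p = 0, dCor = 0 to
p = 1. Benjamini–Hochberg adjustment is available (`--adjust bh`) and off
by default; filtering defaults to raw p-values.

## Partial correlations (GGM route)

Σ_ij = dCov(X_i, X_j) (square-root scale; the diagonal is dVar = dCov(X,X)
on the same scale) is inverted with the Moore–Penrose pseudo-inverse
(relative singular-value cutoff 1e-12·σ_max, configurable; equal to the
ordinary inverse for non-singular Σ — the Penrose identities are tested on
rank-deficient input). Partial correlations follow the precision-matrix
identity ρ_ij·rest = −ω_ij/√(ω_ii·ω_jj); they carry their own sign, so no
Pearson signing is applied in partial mode.

Fisher significance: z = arctanh(ρ), p = 2·(1 − Φ(|z|·√(N−M−1))). Two
genuinely open readings are fixed here and switchable in
`fisher_pvalue`/`fit_partial`:

* the degrees-of-freedom scale is √(N−M−1), not the un-rooted product
  (dimensionally the only plausible Fisher form); `sqrt_df=False` gives the
  literal product for sensitivity analysis;
* M counts **all** usable features, not only the M−2 controlled covariates
  (`count_all_features=False` switches).

Using |z| inside Φ makes strongly negative partials significant too.

Σ built from pairwise distance covariances is not guaranteed positive
semi-definite, and with M ≥ N it is rank-deficient; the pseudo-inverse then
projects away directions and the ρ formula can misbehave. Partial mode
therefore refuses M ≥ N unless `--override-feature-guard` is given (a loud
warning is emitted either way), and any feature whose precision diagonal is
non-positive is excluded by name rather than silently clipped. A
`use_dcor_matrix=True` variant inverts the dCor matrix instead of Σ, for
sensitivity analysis only.

## Preprocessing

* Orientation: rows = samples, columns = features; `--transpose` flips a
  features-as-rows table on load.
* Z-scoring is per feature, (x − mean)/sd with the sample sd (n−1
  denominator), matching common omics practice; it is idempotent and
  applied automatically before every analysis. dCor itself is affine
  invariant, so z-scoring matters only for the joint (one-to-all) distance
  and the Σ matrix, where it puts features on a common scale.
* Missing values: hard error listing every (sample, feature) coordinate.
  No imputation is built in — imputation choices belong upstream.
* Constant features: flagged (pre-normalization variance exactly zero) and
  excluded from all computations with a warning; dVar = 0 would make dCor a
  0/0.
* Minimum sizes: n ≥ 3 samples (so n−2 ≥ 1 df), m ≥ 2 features (m ≥ 3 for
  partial mode).

## Numerical choices

* dCov² is mathematically non-negative; roundoff negatives within
  1e-12 × max(1, dVar scale) are clamped to 0, anything larger raises an
  internal-consistency error instead of being hidden.
* dCor is clamped into [0, 1]; clamping beyond 1e-10 is likewise an error.
* Per-feature centered distance matrices are cached within a run
  (O(m·n²) memory); results are bit-identical to uncached computation, and
  each unordered pair is computed once so the dCor grid is exactly
  symmetric. The diagonal is reported as 1 by convention and never appears
  in edge output.
* Edge tables are ordered by descending |correlation| with lexicographic
  (feature_a, feature_b) tie-break, so identical input and configuration
  produce byte-identical CSV files.
* CSV round-trips are exact at double precision; XLSX numbers are stored at
  16 significant digits (the spreadsheet format's precision), i.e.
  round-trip to ~1e-15 relative.

## Synthetic data

The generator (`sidcor.synthetic_data`, also `sidcor simulate`) produces
the study conditions for every test: pair scenarios (independent; linear
y = x + ε; quadratic y = x² + ε on a grid symmetric about 0, so Pearson
vanishes exactly in the noiseless case; sinusoidal; circular) with default
noise_sd = 0.1, and multivariate-normal graph scenarios — a first-order
Markov chain with adjacent correlation 0.7 (cov r^|i−j|) and a hub in
which one node drives all leaves at correlation 0.7 (leaves correlate at
0.49 through the hub only). Defects (missing cells, constant columns) are
injected last at seeded positions for the error paths. All randomness is
`numpy.random.default_rng` (PCG64), so a seed fully determines a fixture
across platforms.

These fixtures are clean mathematical structures: they do not mimic
log-normal abundance distributions, batch effects, heteroscedastic noise
or censored zeros of real metabolomics data. Passing tests demonstrate the
estimators and pipeline are computed correctly and recover planted
structure under Gaussian/noiseless conditions — not that any biological
network will be recovered at these rates.

## Problem sizes

Tests and the reproduction script run small problems by design: oracle
comparisons on 100 random matrices with n ≤ 20 samples and m ≤ 6 features
(brute-force double-loop references are O(n²) per pair in pure Python);
structure recovery on 3-node graphs with N = 200 samples × 50 replicates;
the end-to-end pipeline on a 60 × 8 chain. These sizes already exercise
every code path and give stable recovery rates; the implementation itself
comfortably handles the hundreds-of-features matrices of real studies.

## Known limitations

* The t-based dCor p-value is heuristic (see above); treat it as a ranking
  device, not a calibrated test.
* Unequal-length vectors are not supported: the estimator is defined on a
  common sample index.
* No regularized precision estimation (graphical lasso, shrinkage); with
  M approaching N the partial estimates degrade and the feature guard is
  the only protection.
* No plotting or graph-file export beyond the CSV/XLSX edge table.
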