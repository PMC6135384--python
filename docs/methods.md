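# Methods

This note documents the statistical procedures implemented in `foramstats`,
their assumptions, the defaults and why, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Data model

The central object is the **assemblage matrix**: samples × taxa nonnegative
abundances, either raw specimen counts or per-sample percent abundances.
The mode is always explicit — percent tables carry no specimen totals, so
quantities that need true counts (Fisher α) take richness `S` and count `N`
separately. Taxon annotations assign each taxon a functional group
(symbiont-bearing / opportunistic / heterotrophic / unknown) and a test
wall type (hyaline perforate / imperforate porcellaneous / agglutinated /
unknown). The packaged Galápagos survey stores the 28 dominant taxa (~75%
of all specimens) from 19 samples across 7 islands; its annotation table
records, per taxon, whether the functional-group assignment is stated in
the source survey or inferred from taxonomy (`assignment_basis` column),
because no complete assignment table was published.

## FORAM-Index

`FI = 10·Ps + Po + 2·Ph` over the proportions of the three functional
groups among **classified** material. Design choices:

* Unknown-group taxa are excluded from the denominator rather than lumped
  into the heterotrophs; lumping would silently pull FI toward 2.
* Category boundaries are the closed interval: `FI > 4` reef development,
  `FI ∈ [2, 4]` marginal, `FI < 2` stressed, so the boundary values 2 and 4
  classify as marginal.
* FI is invariant to uniform row rescaling, so counts and percent input
  give identical results.
* Site aggregation defaults to the arithmetic mean of per-sample FI values
  (`mean_of_sample_fi`); a `pooled_counts` alternative pools the classified
  group masses across a site's samples before recomputing proportions. The
  two differ when specimen totals vary strongly between samples; the mean
  form is the default because site values are conventionally reported as
  averages of per-sample indices.

Site-level FI for the packaged survey spans ~1.65 (San Cristóbal) to ~7.14
(Darwin) when computed from the 28-taxon subset. These are *not* the
published per-sample FI values: the subset covers only ~75% of specimens
and the functional groups of the unprinted taxa are unknown, so per-sample
FI is not reproducible from the packaged matrix and only ordering
properties (Darwin maximal, a southern site minimal) are asserted.

## Fisher α

`f(α) = α·ln(1 + N/α) − S` is strictly increasing in α with a unique root
for `1 ≤ S < N`; the root is found with Brent's method on `[1e-8, 1e8]` at
machine tolerance. Outputs destined for tables are rounded to two decimals;
full precision is kept internally. Of the nineteen published per-sample α
values in the packaged reference table, eleven reproduce exactly (±0.01)
from their printed (S, N) pairs and eight disagree by amounts equivalent to
one or two species (e.g. DAR-B-43: S=57, N=318 gives α=20.24, printed
19.19). The printed pairs cannot adjudicate the source of the discrepancy
(plausibly the published α used a different effective S or N, such as
excluding unidentifiable specimens); the package recomputes from the
printed values and treats the eight rows as documented mismatches.

## Transforms and distances

The Hellinger transformation divides each row by its sum and takes square
roots, so each transformed row has unit sum of squares. A displayed version
of this formula sometimes omits the radical typographically; the square-root
form is used because without it the transform is a plain profile and the
comparability argument with chord/χ² distances fails. Chord distance
unit-norm-scales rows and takes Euclidean distances (range [0, √2] for
nonnegative data); on Hellinger-transformed data the rows are already
unit-norm, so chord distance on transformed data equals Hellinger distance
— the composition prescribed for the clustering stage is therefore
well-defined even though it reads as a double standardization. Chi-square
distance uses the correspondence-analysis row metric; all-zero taxon
columns have no defined column weight and are dropped with a warning
(Hellinger retains them as zeros).

## Ward clustering

Agglomeration uses the Lance–Williams recurrence. The default `D2` variant
runs the recurrence on squared distances and reports heights square-rooted
back to original units — appropriate because chord distances are
Euclidean-embeddable; the `D` variant (recurrence on raw distances) is
available behind the `ward_variant` config flag since linkage software
varies and published dendrograms rarely state the convention. Ties between
equal-cost merges are broken by the smallest leaf indices contained in the
candidate pair, making the dendrogram deterministic bit-for-bit. Cutting at
`k` removes the `k−1` highest merges (heights are monotone under Ward);
labels run 1..k in left-to-right leaf order. `k` is always configured,
never inferred: the survey analysis reports `k = 5` alongside the `k = 2`
major-group cut. Exact merge heights of any particular published dendrogram
are not reproducible without knowing its software's variant and tie-breaks,
so cluster recovery is validated at the level of island composition.

## Canonical correspondence analysis

Ter Braak's weighted eigenanalysis, as described in the README: scale to
unit grand total, form the standardized residual matrix
`Q = (P − r cᵀ)/sqrt(r cᵀ)`, standardize the environment columns to zero
mean and unit variance in the row-mass metric, project `Q` onto the
row-mass-weighted environment space, and SVD the projection. Numerical
choices:

* **Axis signs** are unidentifiable; each axis is flipped so the LC site
  score of largest magnitude is positive, for cross-platform determinism.
* **Scores.** LC site scores are standard coordinates of the fitted space;
  WA site scores are weighted averages of species scores divided by the
  eigenvalue; species scores are scaling-2 principal coordinates. The exact
  transition identity is: species scores equal abundance-weighted averages
  of **LC** site scores (this is the identity asserted in tests; it does
  not hold for WA scores in general).
* **Collinear constraints.** With covariates constant within islands there
  are fewer distinct environment rows than variables, so the centered
  environment matrix is rank-deficient by construction. The default is a
  hard error naming the collinear columns; `drop_collinear=True` (used by
  the pipeline) aliases dependent columns out of the constraint space with
  a warning, uses the effective rank `q` in the pseudo-F, and still reports
  biplot scores (row-mass-weighted correlations with the LC axes) for every
  supplied variable. Biplot geometry is invariant to affine rescaling of
  any environment column.
* **Percent input** is accepted as-is: rows are treated as compositional
  with masses proportional to row sums (near-equal for percent data). A
  pseudo-count conversion via per-sample specimen totals is possible
  upstream with `AssemblageMatrix` arithmetic if exact count weighting is
  wanted.
* **Permutation test.** pseudo-F = (constrained/q)/(residual/(n−q−1));
  whole sample rows of the environment table are permuted, and
  `p = (1 + #{F* ≥ F}) / (1 + n_permutations)`. Under the null, p is
  uniform on the achievable grid, so the type-I error at any nominal level
  is exact; the test suite verifies the 5% level within binomial error over
  200 null replicates. Residual/reduced-model permutation schemes are out
  of scope.

## Partition tree

Greedy binary recursive partitioning of cluster membership on environmental
predictors. The default cost is the multinomial deviance
`D = −2 Σ n_k ln(n_k/n)`; candidate thresholds are midpoints between
consecutive distinct predictor values; `value ≤ threshold` routes left.
Stopping: pure node, node smaller than `min_node` (default 2, sized for
n ≈ 19), or best reduction below `min_deviance_fraction` (default 0.01) of
the root cost. Ties are broken toward the earlier predictor column and the
smaller threshold — with island-constant predictors several variables can
induce identical partitions, so the winning *label* on a split can be a
tie-break artifact even when the partition is stable. Gini and RSS costs
are available as options; the RSS cost treats a numeric response (e.g.
dendrogram-ordered cluster bin numbers) as a regression target, which is
how classic regression-tree software behaves when handed numeric bins. On
the packaged survey, the regression reading makes the long-term SST anomaly
the strict root winner, while under multinomial deviance the SSS anomaly
edges it out — a concrete example of criterion choice changing the headline
variable. No pruning or cross-validation is attempted at n = 19.

## Environmental series

The mean is the arithmetic mean of monthly values. The mean anomaly
compares each month against its own year's annual mean and averages the
**absolute** deviations over all months: the signed per-year deviations
average to zero by construction, which cannot produce the large positive
anomaly statistics observed in survey tables (SST mean anomalies of
2–3 °C against ~23 °C means), so the absolute form is the default with the
signed variant behind `absolute=False`. Whether the annual reference is
per-year (default) or a single climatological mean is toggled by
`climatological=True`; the published statistics cannot adjudicate between
the readings without the raw series, so both are implemented and the
default follows the literal per-year wording. Partial years are included
with a warning (satellite series typically start mid-year). Logger
summaries are plain mean/min/max plus the fraction of readings below a
configurable threshold; reproducing any particular published logger
statistics requires the raw instrument file, which is not packaged.

## Synthetic data

The generator emulates what the analyses assume: unimodal (Gaussian) niche
responses `λ_ij = h_j·exp(−(x_i − u_j)²/(2 t_j²))` along latent gradients,
with per-site assemblages drawn multinomially at specimen totals uniform on
290–480 (the range observed in well-picked survey samples, 292–475).
Default design: 30 sites, 28 taxa, one gradient, optima spread evenly on
[0, 1], tolerances uniform on [0.12, 0.3], peaks uniform on [0.5, 1.5].
The environment table carries covariates linearly correlated with the
gradient plus Gaussian noise on realistic scales. The FI-gradient variant
assigns functional groups by niche-optimum rank (low optima
symbiont-bearing, high heterotrophic) so the expected FI declines
monotonically along the gradient. The monthly-series simulator adds a
sinusoidal seasonal cycle, white noise, and injected event offsets
(ENSO-like anomaly trains).

What the generator does **not** emulate: spatial autocorrelation among
sites, taphonomic loss (differential test destruction by wall type),
time-averaging of assemblages across decades, overdispersion beyond
multinomial sampling, and island-structured (rather than continuous)
environments. Passing recovery tests therefore show that the estimators
recover structure under their own model assumptions — not that real
assemblages satisfy those assumptions.

All randomness flows through one `numpy` `default_rng` seeded generator per
simulation; seeds are recorded in every truth record and output manifest.

## Problem sizes and determinism

The test suite and the acceptance script run on the packaged 19 × 28 survey,
on toy matrices up to 5 × 5 against dense-eigendecomposition oracles, on
100-case random suites for the tree-split oracle, on 200 null replicates ×
99 permutations for permutation-test calibration, and on 20 seeds of the
default 30 × 28 design for gradient recovery — sizes chosen to exercise the
estimators' operating range on this kind of survey data. Identical inputs,
configuration and seeds reproduce identical outputs byte-for-byte; the
pipeline manifest records SHA-256 digests to make that checkable.

## Known limitations

* Per-sample FI and eight of nineteen published Fisher α values are not
  reproducible from the packaged subset (see above); only ordering and the
  consistent rows are asserted.
* The CCA permutation test permutes environment rows only; no partial CCA,
  detrending, or forward selection.
* The tree has no pruning, surrogate splits, or honest inference; with
  island-constant predictors its split labels are tie-break-sensitive.
* Chi-square distance and CCA drop all-zero taxon columns; analyses of
  presence-structured rare taxa should pre-filter deliberately.
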