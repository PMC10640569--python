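# Methods

This note records the modeling choices behind `netpercolate`: what each
stage computes, the assumptions it rests on, the parameters that matter,
and what the synthetic benchmarks do and do not establish.

## Spectral connectivity

Node-level trials (default 2 s epochs) are demeaned and tapered with
discrete prolate spheroidal (Slepian) sequences.  The time–half-bandwidth
product is `NW = duration × half_bandwidth`; with the defaults (2 s,
±2 Hz) `NW = 4` and the standard concentration rule keeps `2NW − 1 = 7`
tapers.  Bin centres (0.5–100 Hz in 0.5 Hz steps) are aligned to exact
DFT bins by zero-padding when `duration × fstep` is not an integer; the
implementation requires the sampling rate to be an integer multiple of
the bin step.

The weighted phase lag index is computed per bin by pooling trials and
tapers as i.i.d. observations of the cross-spectrum:

    wPLI_ij(f) = |E[Im S_ij(f)]| / E[|Im S_ij(f)|],  S_ij = X_i conj(X_j).

Pooling (rather than trial-averaging before the expectation) is a
deliberate choice; the plain estimator is used, not the debiased squared
variant.  When `E[|Im S|]` is zero the index is defined as 0 — zero-lag
coupling is exactly what the phase-lag index is designed to discount.  In
floating point, identically zero imaginary parts can surface as values at
rounding-noise level (fused multiply-add in the complex product), so the
0/0 convention triggers whenever the denominator falls below 1e-10 of the
mean cross-spectral amplitude for that pair.  Note one consequence of
multitaper pooling: antisymmetric (odd-order) tapers nearly annihilate an
on-bin sinusoid, and those near-zero observations carry leakage-level
imaginary parts of arbitrary sign.  wPLI's magnitude weighting makes this
immaterial (a noiseless quarter-cycle pair scores 0.9999… rather than
exactly 1), which is why tests assert the unit value at 1e-3.

Per-bin matrices are aggregated as `W_ij = sqrt(Σ_f wPLI_ij(f)²)`,
bounding each weight by `sqrt(n_bins)`.  The mean Euclidean distance over
all node pairs is carried along as a nuisance covariate for the
regression stage (a proxy for field-spread differences between small and
large heads).

## Attacks and percolation

Weighted connectomes are proportionally thresholded: at density `d` the
top `round(d·N(N−1)/2)` edges by weight are kept (round half away from
zero, ties broken by lexicographic node-pair order) and the graph is
binarized.  Centralities and components are computed on the unweighted
graph — the convention of the attack literature; weighted centralities
after a rank-based threshold would re-import the weight scale the
threshold was meant to remove.

Removal orders: uniformly random, or descending betweenness /
eigenvector centrality computed **once** on the intact thresholded graph
(static ranking; re-ranking after each removal is available behind
`recompute_centrality` but off by default, matching the sequential-order
reading of targeted attacks).  Centrality ties are permuted uniformly at
random, and attacks are iterated (production default 100×) so that tie
handling and random orders average out.  Eigenvector centrality is the
leading eigenvector of the adjacency by power iteration (tolerance
1e-10, ≤10 000 iterations, absolute values); iterating on `A + I` keeps
the same eigenvectors while making the dominant eigenvalue unique on
bipartite graphs, where plain power iteration oscillates between the
±λ_max pair.  Nodes outside the dominant component receive ≈0 and fall
to the end of the ranking.

After each removal the two largest component sizes are recorded (S2 = 0
with fewer than two components).  The percolation point is `k*/N` where
`k*` is the first step at which S2 attains its maximum; an all-zero S2
trace (e.g. a complete graph) degenerates to `1/N`.  Traces are computed
by reverse union-find (re-inserting nodes from the empty graph), with a
numba kernel batching the iterations; the pure-Python implementation of
the same algorithm is the tested reference, and both are checked against
exhaustive component enumeration on small graphs.

The *pre-failure set* of one iteration contains the nodes removed
strictly before step `k*`.  A subject's per-density pre-failure mask is
the majority vote across iterations, and the removal-frequency map is
the fraction of subjects (optionally restricted to an age quartile)
whose mask contains each node.

Densities too sparse to retain a single edge are recorded as missing and
dropped before functional gridding.

## Functional preprocessing

Per-subject percolation-point-by-density functions live on an ascending
density grid.  Because the attack sweep runs from 100 % down to the
sparsest graphs, the sweep's terminal value — where the percolation
estimate is unstable on a handful of edges — is the *lowest*-density
point; subjects whose value there has z > 2 across the cohort are
dropped (computed once, not iterated; zero-variance cohorts drop
nobody).

The grid is then trimmed to the informative range.  The mean function
rises steeply at low densities and flattens once the graph is dense
enough to be uniformly robust; `d*` is the first grid point (beyond the
first) where the mean finite-difference derivative falls to the
tolerance (default 1e-6), and `[d_1, d*]` is retained.  A function that
never flattens keeps the whole domain with a warning; a flat function
trims to two points with a warning.  The across-subject SD of the
derivative is exposed separately (`derivative_dispersion`) for
transparency.  Trimming is idempotent.

Each trimmed function is represented in an order-4 B-spline basis with
knots at the grid points — `M + order − 2` basis functions for an
M-point grid, hence 402 on the production 400-density grid — fitted by
penalized least squares with a second-derivative roughness penalty.  The
weight λ is selected from `e^k, k = −5…12` by GCV
(`M·SSR/(M − tr H)²`).  The roughness Gram matrix is evaluated with
density expressed in *percent*: B-spline bases are affine-invariant in
the domain, but `∫B″²` scales as the inverse cube of the knot spacing,
and on the fractional scale even `e^−5` would oversmooth every function;
on the percent scale the grid spans near-interpolation to heavy
smoothing.  Subjects whose smoothed fit has SSR z > 2 are dropped (the
threshold mirrors the terminal-spike rule and is configurable).
Smoothing serves outlier detection only: the regression consumes the
raw trimmed functions, since pre-smoothing removes variability the model
should see, and the pipeline wiring enforces this.

## Function-on-scalar regression

Model: `y_i(d) = Σ_j x_ij β_j(d) + ε_i(d)` with covariates intercept,
age (centered at the cohort mean, which affects only the intercept
function), sex (female = 1), handedness (left and no-preference
indicators, right-handed reference), and mean node distance.  Each
β_j(d) is expanded in 5 cubic B-splines with equally spaced knots on the
trimmed domain and a first-order difference penalty on the basis weights
(P-splines), whose null space is the constant functions — so smoothing
shrinks each coefficient toward constancy, never toward zero.  A single
smoothing weight shared by all terms (the response's smoothing applies
to every coefficient) is selected on the stacked Kronecker system from
`e^−5…e^12`.

Selection uses restricted maximum likelihood by default.  GCV is
available (`selection="gcv"`) but empirically undersmooths pure noise in
a nontrivial fraction of replicates, which inflates the constancy test
below; REML keeps it at its nominal size.

Point estimation treats grid points as working-independent.  Two
effective dimensions are tracked: `edf = tr(H)` (model complexity) and
the residual effective dimension `2 tr(H) − tr(H²)`, for which
`E[RSS] = σ²(n_obs − edf_res)` holds exactly — a penalized hat matrix is
not idempotent, and using `tr(H)` in the variance estimate makes every F
test anti-conservative (~9 % size at nominal 5 % in our null
simulations; the residual form restores ~5 %).

* **Overall constancy test** — F ratio of the full fit against plain
  least squares with every coefficient constant over density, with
  `df1 = edf_res − p`, `df2 = n·M − edf_res`.  Degenerate collapse
  (`edf_res ≤ p`) raises rather than reporting a vacuous test.
* **Per-covariate tests** — drop-one refits at the selected λ, same F
  construction.
* **R² family** — adjusted R² from residual edf; functional R² compares
  the full (or intercept-plus-one-covariate) model against the
  intercept-only *functional* fit, each with its own selected λ;
  semi-partial correlations are `sqrt(max(0, R²_full − R²_−j))`, clamped
  because edf differences can make the difference marginally negative.
* **Bootstrap bands** — subjects are resampled with replacement (case
  bootstrap; resampling grid points would break within-function
  dependence, which is precisely what the bootstrap is meant to absorb),
  the model is refit with λ re-selected, and pointwise 2.5/97.5
  percentiles form the 95 % bands.  Rank-deficient resamples are redrawn
  and counted.  Deterministic given the seed.
* **Three-condition rule** — a covariate is reported as significant over
  the contiguous density ranges where the overall test, its own test
  (both at α, default 0.001; 0.01 is a common reporting alternative and
  is just a parameter), and CI-excludes-zero all hold.

## Synthetic data

`generate_cohort` draws modular weighted graphs whose vulnerability
increases with a continuous age covariate.  Architecture per subject:
a strong ring backbone inside each module (weights 0.92–1.0) keeps
modules internally connected at sparse thresholds; each module has a
designated channel-0 *hub* with strong spokes into its own module (its
internal centre, giving it clearly-top betweenness at every age) and
inter-module channels connect the ch-th bridge node of every module pair
(weights 0.8–0.9).  The number of parallel channels falls from 3 to 1 as
the concentration `c(age) = clip(slope·(age − age_min), 0, 1)` rises
(default slope 1/15 per year reaches full concentration at the top of
the default 4–19 y range), and the surviving channel's weight grows with
`c`.  Mid-tier intra-module chords (0.3–0.6) and weak background
coupling (0–0.3) fill the remaining pairs — a wPLI connectome has no
true zeros — and Gaussian edge noise (SD 0.02) perturbs everything.
Young networks therefore tolerate losing their top hubs (secondary
channels reroute traffic; the consistently removed hubs become the young
quartile's shared group-level hubs in removal-frequency maps), while old
networks disconnect a module at the first hub removal.  With slope 0 the
topology is age-independent by construction.  Node coordinates are drawn
once per cohort on a sphere (radius 70 mm), scaled ~10 % over the age
range with per-subject jitter so mean node distance correlates with age
without being collinear.  Sex and handedness frequencies follow the
reference cohort table (54.9 % female, 87.8 % right-handed,
`datasets.reference_cohort_demographics`), with every factor level
forced to appear at least once so small cohorts cannot produce
rank-deficient designs by sampling accident.  Per-subject seeds are
spawned from the master seed and never reused.

`simulate_coupled_oscillators` builds recordings where designated pairs
share a per-trial-random-phase sinusoid at a set frequency and phase
lag, plus independent Gaussian noise at a set SNR (signal SD / noise
SD); uncoupled nodes get unit-variance noise.  It exists to give the
connectivity stage analytically known targets.

`simulate_functional_cohort` draws percolation-point-like functions
directly — `y_i(d) = μ(d) + β_age·(age_i − mean) + ε`, ε i.i.d.
N(0, 0.05²) across the grid — and is the engine for the regression
calibration studies: running the full graph→attack pipeline hundreds of
times per calibration point is far beyond a desk budget, and the
regression's statistical properties depend on the functional data, not
on how the graphs produced them.  Its null uses a *constant* mean
function, because a density-varying intercept is itself a departure the
overall constancy test is designed to detect.  The i.i.d. noise matches
the working-independence assumption; calibration results therefore
certify the test machinery, not robustness to strong within-function
residual dependence (which the bootstrap, not the F reference, is
responsible for in real data).

## What the benchmarks show — and what they don't

The synthetic cohort encodes the hypothesized development contrast by
construction; pipeline results on it (negative age effects at low
densities under random and betweenness attacks, no effect structure
under the null, more shared pre-failure hubs in the young quartile)
demonstrate that the pipeline *detects what is there* and stays quiet
when nothing is, not that any particular real cohort behaves this way.
The generator does not emulate sensor physics, source leakage,
inter-regional distance structure in connectivity weights, or realistic
spectral content; wPLI validation uses idealized oscillators.

## Problem sizes and defaults

Production defaults follow the analysis the package implements: 400
densities (0.25 %–100 %), 100 attack iterations, 1000 bootstrap
resamples, α = 0.001.  The bundled tests and the acceptance script use
desk-scale sizes chosen to exercise every code path with stable
statistics: 60-subject cohorts on 64-node graphs, a 30-density grid
(1 %–30 %, the informative low-density range), 25 attack iterations,
100–200 bootstrap resamples, 200 calibration replicates at n = 80.

## Known limitations

* Per-covariate F tests use drop-one refits at the full model's λ; the
  paper-level construction of per-term tests in penalized functional
  models is not unique, and alternatives (constant-vs-varying per term)
  would give different numbers.
* The functional R² adjustment is the residual-edf form; other
  adjustments exist.
* No subject-level functional random effects: between-subject
  correlation beyond the covariates is absorbed into ε and handled only
  by the case bootstrap.
* The trimming rule keys on the group-mean derivative; cohorts whose
  mean function dips non-monotonically before its plateau will trim at
  the first dip.
* Eigenvector-centrality rankings on graphs with several similar-sized
  components depend on which component dominates numerically; such
  graphs sit outside the regime the measure is meant for.
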