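# Methods

## The accuracy scaling law

The package's central object is the expected prediction accuracy of a
linear(izable) FC-phenotype model as a function of training sample size *N*
and scan time per participant *T*:

    rho(N, T) = K0 * sqrt(1 / (1 + K1/N + K2/(N*T))),    K0 in (0,1], K1, K2 >= 0.

The form follows from decomposing prediction error into a coefficient-
estimation part (variance ~ 1/N) and an FC-measurement part (edge variance
~ 1/T, entering through the fitted coefficients, hence ~ 1/(N·T)). Its key
assumptions are (i) stationarity — FC computed from any portion of the scan
estimates the same subject-level quantity — and (ii) independence of
phenotype-model errors and FC measurement errors. Both assumptions are
explicitly probed by the simulation machinery (below).

Limits and consequences used throughout:

- `rho -> K0` as both N and T grow; `rho -> K0/sqrt(1+K1/N)` as T grows
  alone (scan time cannot substitute for participants indefinitely);
- when `K1/N << K2/(N*T)` accuracy depends on N and T only through the
  total scan duration N·T — the interchangeability regime, equivalently the
  logarithmic model `y = z*log2(N*T) + k` that holds empirically for scans
  up to ~20 min (the default `t_cap_min = 20`);
- at fixed N·T accuracy is strictly decreasing in T whenever K1 > 0:
  sample size is ultimately more important than scan time.

## Fitting

`fit_theoretical` minimizes the mean squared error between the law and the
rep-averaged accuracy cells. The problem is smooth but can be multi-modal
for noisy grids, so the optimizer is bounded L-BFGS with analytic gradients
from 20 seeded Latin-hypercube launch points (k0 uniform; k1, k2
log-uniform) plus a linearized launch point obtained by regressing 1/y² on
[1, 1/N, 1/(N·T)]. Bounds: k0 ∈ (0, 1] (it is an asymptotic correlation),
k1 ∈ [0, 1e8], k2 ∈ [0, 1e10]. A flat grid short-circuits to
(k0 = the common value, k1 = k2 = 0, R² := 1). Convergence is judged by the
projected gradient at the best solution rather than the line-search status
flag. Fits require ≥ 4 cells; the logarithmic OLS requires ≥ 2 cells at or
below the scan-time cap. Goodness of fit is the coefficient of
determination about the observed mean; it is undefined (raises) for
zero-variance observations.

Model comparison across phenotypes uses the two-sided Wilcoxon signed-rank
test on paired R² lists (all-zero differences return p = 1). The
fit-vs-predictability association uses Spearman's rho with a
label-permutation p-value (1,000 shuffles by default).

## Design surfaces and optimization

A fitted phenotype is normalized by its own K0, giving the fraction of
maximum achievable accuracy — independent of K0, hence comparable across
phenotypes — evaluated at the *training* sample size `f·N` with
`f = train_fraction = 0.9` by default (a tenfold cross-validation design;
costs are charged on recruited N). Surfaces average this fraction,
unweighted, across phenotypes; datasets therefore contribute in proportion
to their phenotype counts. Surfaces are analytic objects; grids (default
N ∈ {25, ..., 10000} by 25, T ∈ {1, ..., 200} min) are only materialized for
export.

Iso-accuracy contours solve for the smallest N reaching the target at each
T: closed form `N = (K1 + K2/T) / (f·(1/target² − 1))` for a single fit,
vectorized bisection (tolerance 0.01 participant) for averaged surfaces.
N is kept real along the contour and rounded up only when costed.

Study cost is `(T/60 · S + O) · N` with scan cost S per hour and overhead O
per participant. The budget optimizer enumerates T on a 1-min grid
(default 1–200), buys `N = floor(B / (T/60·S + O))` and maximizes the
surface fraction; the target optimizer costs the contour and minimizes.
Both break ties toward shorter scans. Cost inefficiency of a *fixed* T is
`cost(T)/cost(T_opt) − 1` per scenario, averaged over scenarios (default
grid 5–100 min in 5-min steps; default conditions: targets {0.80, 0.90,
0.95} × O {500, 1000} × S {500, 1000} per dataset); the curve is also
reported normalized by subtracting its minimum. Savings relative to a
reference scan time are `100·(1 − mean[cost(T)/cost(T_ref)])`. The two
curves weight scenarios by different denominators, so their optima agree
exactly per scenario and up to the flat region of the optimum for
heterogeneous scenario sets. The bootstrap for the most cost-effective
fixed time resamples phenotypes with replacement within each dataset
(1,000 replicates, percentile 95% CI by default); the resampling unit is a
documented assumption.

## Synthetic cohorts

The generator produces cohorts with exactly the structure the law assumes,
so that the prediction and reliability engines can validate it end-to-end:

- true edge values i.i.d. N(0, `edge_signal_sd`²) per subject
  (`edge_signal_sd = 0.1`, a realistic between-subject spread for Pearson
  FC edges);
- a sparse weight vector (density 0.2) rescaled so the noise-free linear
  predictor has unit variance; phenotype = linear part +
  N(0, `phenotype_noise_sd`²) with default 1.0, putting the accuracy
  ceiling at 1/√2 ≈ 0.71 — a well-predicted phenotype;
- observed FC after T minutes = true + noise with variance
  `obs_noise_sd²/T` (`obs_noise_sd = 0.2` per √minute, matching the order
  of magnitude of FC sampling noise at TR 0.8 s). In `direct_noise` mode
  (default) runs are materialized as run-level estimates keyed by the
  original run index, so per-subject run-order permutation moves noise and
  drift with the run, and partial runs receive exactly the extra variance
  that keeps the overall 1/T law. In `time_series` mode stationary
  multivariate Gaussian parcel series encode the true edges as population
  correlations around a shared 3-factor base matrix; this mode validates
  the 1/T assumption itself (edge variance ≈ (1−ρ²)²/frames) and the
  time-course-noise → edge-noise mapping, at higher cost;
- contiguous sibling blocks (`family_block_size`), round-robin site labels,
  and a deterministic seed: identical configs give bit-identical cohorts.

Default desk-scale dimensions are 50 parcels (1,225 edges), cohorts of
~1,200–2,000 subjects, runs of 5 min, TR 0.8 s. These are deliberately far
smaller than a real 419-parcel consortium dataset; the law's regime does
not require more, and simulations complete in minutes.

**Non-stationarity.** `inject_nonstationarity` adds a run-indexed shared
offset vector o_r ~ N(0, drift_sd²) to each run's generative edge values,
scaled per subject by the standardized phenotype. This makes the
FC-phenotype relationship itself run-dependent — under the natural run
order, short scans see a different (partly phenotype-aligned) FC signal
than long scans, violating stationarity in a way the 1/(N·T) term cannot
absorb. Phenotype-independent offset scalings turn out *not* to violate
the law: in a high-dimensional edge space the cumulative offset norm
self-averages into a smooth 1/T profile that the K2 term fits. Per-subject
run-order randomization (fresh per CV repetition) restores exchangeability
and the fit recovers; a drift of 0.03 (30% of the edge signal s.d.) yields
a reliably directional effect. What passing this probe shows is that the
*pipeline* detects relationship non-stationarity, not that real fMRI drift
has this exact structure.

## Prediction engine

Kernel ridge regression on FC feature vectors with a correlation kernel
(Pearson correlation between subjects' edge vectors) by default; the ridge
parameter is selected on a 16-point log grid spanning [1e-4, 1e4] by inner
k-fold cross-validation minimizing validation SSE, using one
eigendecomposition per inner training set to sweep the whole grid. Linear
ridge regression is available as the primal counterpart (and the
linear-kernel duality is asserted in tests against scikit-learn's Ridge).

The cross-validation design mirrors the workflow the law is fitted to:
folds never split families (greedy largest-first assignment of family
blocks); within a repetition the test fold is fixed while the training pool
is subsampled to each requested size, so cells differ only in training
data; per-cell RNG streams make each cell's result independent of which
other sizes were requested. A leave-p-site-clusters-out scheme (clusters
from greedy size-balanced bin-packing of sites) and training-estimated site
regression of the phenotype are provided for multi-site designs. Metrics:
Pearson's r and COD `1 − Σ(y_te − ŷ)²/Σ(y_te − mean(y_train))²` — the
training-mean null keeps COD comparable across training sizes.

Statistical companions: the corrected resampled t-test
`t = mean(d)/sqrt((1/J + n_test/n_train)·var(d))` with J−1 degrees of
freedom, for comparing accuracies across overlapping CV training sets;
Benjamini-Yekutieli step-up FDR (valid under arbitrary dependence; always
at most as many rejections as Benjamini-Hochberg); and the Haufe transform
(per-feature covariance with the predicted phenotype), the interpretable
encoding-direction counterpart of multivariate weights.

## Reliability

Split-half reliability draws two disjoint random halves, computes a
per-edge association statistic in each — univariate correlation
t statistics, or Haufe activations of a predictor trained on the half —
and measures agreement with a one-way random single-measurement ICC over
edges, `(MS_between − MS_within)/(MS_between + MS_within)`, which penalizes
mean offsets between halves; a consistency-type ICC (Pearson over edges) is
available via `icc_kind`. Zero-variance edges are dropped pairwise with a
count. On synthetic cohorts the ICC grid is nondecreasing in half size and
scan time. The often-reported reliability advantage of Haufe activations
over univariate statistics does **not** emerge under this generator's
independent-edge signal — there is no cross-edge structure for the
multivariate model to denoise — so it is not asserted; with latent-factor
(correlated) edge signal both statistics are highly reliable and the Haufe
ICC grows with half size, which is what the tests check.

## Numerical conventions and edge cases

- Ties in both optimizers break toward shorter scans; budget infeasibility
  (not even one trainable participant) raises.
- Fractional participants exist only on contours; costing rounds up.
- Pearson grid cells are clipped to [−1, 1] after rep-averaging; constant
  test predictions score r = 0.
- Accuracy-table ingestion rejects duplicate (N, T) cells, lists missing
  columns, and reports the file line of non-numeric values; the adapter
  matches common column aliases case-insensitively.
- All stochastic components draw from `numpy` Generators keyed by
  (seed, stream-tag) so independent noise sources never alias.

## Known limitations

- The generator emulates the law's own generative assumptions plus a
  specific relationship-type non-stationarity; it does not emulate
  haemodynamics, motion, censoring, autocorrelated noise, site batch
  effects on FC, or heavy-tailed phenotypes. Passing tests validate the
  machinery and the law's self-consistency, not the law's truth on any
  particular real dataset.
- Reproducing published per-dataset numbers requires the corresponding
  released accuracy tables as input; the package ships none.
- Cost modelling ignores currency, inflation and multi-site heterogeneity;
  participant attrition is a simple recruited-N inflation factor in the
  CLI.
- The logarithmic model is a short-scan approximation only; it exceeds
  r = 1 for large enough N·T by construction.
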