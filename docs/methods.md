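# Methods

This note documents the statistical models implemented in `survsel`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Data model

All routines consume right-censored triplets `(Y_i, δ_i, X_i)`: observed
time `Y_i = min(T_i, C_i)`, event indicator `δ_i = I(T_i ≤ C_i)`, and a
numeric covariate row. Tied observed times are allowed — registry-style data
has them — and every downstream component handles ties via the Breslow
convention (tied events share one risk-set denominator). Left truncation,
interval censoring, competing risks and time-varying covariates are out of
scope.

## Cox machinery

The negative log partial likelihood is normalized by n and uses the Breslow
tie approximation. Newton–Raphson with step halving fits the unpenalized
model; convergence is declared at relative objective change < 1e-9 or
gradient max-norm < 1e-6, capped at 100 iterations, with a ridge
stabilizer (default 1e-9) on the Hessian. A coefficient norm above 50
triggers a monotone-likelihood (separation) warning rather than an error.
Linear predictors are shifted by their maximum before exponentiation to
avoid overflow. The baseline cumulative hazard is the Breslow
step-function estimator, right-continuous, with no interpolation; survival
curves are `S(t|x) = exp(−H0(t) e^{x'β})`, clipped to [0, 1].

## Penalized selection (lasso and SCAD)

Covariates are standardized (mean 0, variance 1) inside the fitter — the
penalties are scale-sensitive — and selection is decided on the
standardized scale at `zero_tol = 1e-8`; reported coefficients are on the
original scale. The λ grid holds 50 log-spaced values from
`λ_max = max_j |X_j'u(0)|/n` (the smallest λ with an all-zero solution)
down to 0.01·λ_max.

The solver is IRLS + coordinate descent: each outer pass builds the local
quadratic of the partial likelihood from the per-subject gradient
(martingale residuals) and diagonal curvature, then solves the penalized
weighted least-squares subproblem by cyclic soft-thresholding with an
active-set/KKT-screening strategy and warm starts along the grid. The
curvature is floored at 1e-7 to keep working responses finite. A fit that
exhausts its 200-sweep budget returns its best iterate with a warning.

SCAD uses a = 3.7 (the conventional value) and is solved by local linear
approximation: up to 5 reweighted-L1 problems with per-coordinate penalties
`p'_λ(|β_j|)`, initialized at the lasso solution at the same λ. LLA
reweighting stops early once coefficients move < 1e-5.

λ is tuned by 10-fold cross-validated partial-likelihood deviance in the
Verweij–van Houwelingen form (full-sample log partial likelihood at the
fold-complement estimate minus the complement's own); the partial
likelihood does not decompose over subjects, which rules out a naive
per-fold test likelihood. Folds are stratified on δ and reseeded (up to 10
times) if any fold lacks events. Cross-validation fits the per-fold paths
with a reduced iteration budget (3 outer IRLS passes, coordinate tolerance
1e-5): only the deviance *ordering* of the λ grid matters there, and the
final model is refit at full accuracy.

## Component-wise Cox boosting

From β = 0, each step computes the negative gradient of the log partial
likelihood with respect to the linear predictor — exactly the martingale
residuals `u_i = δ_i − H0(Y_i) e^{x_i'β}` with the Breslow baseline at the
current β — fits the univariate least-squares learner
`b_j = (X_j'X_j)^{-1} X_j'u` to every standardized column, picks the column
minimizing the residual sum of squares (ties to the lowest index; constant
columns are skipped), and updates that coordinate by ν·b_j. ν defaults to
0.1, the conventional weak-learner step. m_stop, which directly bounds the
number of selected features, is tuned on a default grid 0..200 by 10-fold
cross-validated deviance evaluated incrementally along each fold's path.
The path is fully deterministic given the data and fold seed.

## Random survival forest

Trees are grown on bootstrap resamples (drawn with replacement, size n).
At each node, `mtry = ⌈√p⌉` randomly chosen features are scanned; candidate
cut points are midpoints of in-node values, capped at 32 quantile-spaced
midpoints per feature (the nsplit device of standard RSF software — for the
node sizes this package targets the cap changes essentially nothing while
bounding the split search). Splits are scored by the squared standardized
two-sample log-rank statistic; a split is admissible only if both daughters
keep at least one event, and exact score ties are broken randomly from the
forest's seed stream. A node is split only if it has ≥ `nodesize` (default
15) rows and ≥ 3 distinct event times. Leaves store the Nelson–Aalen
cumulative hazard of their in-node rows; ensemble predictions average leaf
hazards over trees, and `S = exp(−CHF)`. Out-of-bag error is 1 − C-index of
OOB ensemble mortality (CHF summed over the event-time grid).

Selection has two modes, dispatched on p/n as is customary for
minimal-depth methodology:

- **p/n < 10 — minimal depth.** A feature's per-tree minimal depth is the
  depth of the shallowest node split on it; features unused in a tree are
  penalized at that tree's maximal depth + 1 (a finite, rank-preserving
  simplification of the maximal-subtree depth distribution, which is not
  implemented). Features whose mean minimal depth falls below the
  forest-wide mean are selected.
- **p/n ≥ 10 — variable hunting.** Repeated (default 50×) subsampling of
  80 % of rows and min(p, max(10, n)) features; each repetition grows a
  forest, ranks by minimal depth, and extends a nested model in
  minimal-depth order until its out-of-bag importance (1 − OOB error)
  changes < 1e-3 over three consecutive additions, capped at n/2 features.
  Features appearing in ≥ 50 % of repetitions are kept. The literature
  leaves the stabilization rule and the final frequency rule open; these
  operationalizations are this package's documented choices.

## The majority vote

The four selectors run independently on identical data; votes are counted
over the union of their feature sets and the final panel keeps features
with at least 3 of 4 votes (the threshold is exposed). Counting over the
union — rather than filtering the four-way intersection, which would make
the ≥3 rule vacuous — is the only reading under which the rule does any
work, and is what the selection algorithm's step-by-step description
prescribes. If any base selector fails the hybrid aborts naming it: a
majority over three surviving sets would silently change the rule's
semantics. An empty final panel is returned as such with a warning; the
benchmark layer (not the voting rule) falls back to the selector's
top-ranked single feature so that predictors always have a covariate, and
flags the cell.

## Evaluation metrics

- **Censoring distribution.** `Ĝ` is the reverse Kaplan–Meier estimate
  (1 − δ as the event), computed on the evaluation set itself so the
  evaluation is self-contained.
- **IPCW Brier score.** At horizon t: events before t contribute
  `(0 − Ŝ(t|z))² / Ĝ(t_i)`, subjects still at risk contribute
  `(1 − Ŝ(t|z))² / Ĝ(t)`, and subjects censored before t contribute
  nothing. Subjects whose required `Ĝ` value is 0 are dropped with a
  warning and the denominator reduced. The IBS integrates BS(t) over the
  distinct test event times by the trapezoidal rule, extends the step curve
  constantly to the ends of `(0, max Y_i]`, and normalizes by `max Y_i`.
- **C-index.** A pair (i, j) with `t_i < t_j` is comparable iff the earlier
  subject had the event; at tied times the pair is comparable iff exactly
  one is an event (ordered event-first). This is the rule that yields 10
  comparable pairs among 5 ordered uncensored subjects and 6 when the 2nd
  and 4th are censored. Tied predictions count 1/2, which makes constant
  scores sit exactly at 0.5. Hazard mode compares risk scores (Cox linear
  predictor, RSF mortality); survival mode compares predicted curves at the
  median observed event time, a fixed reference that makes the statistic
  well defined.
- **IAE / ISE.** Trapezoidal integrals of |S_KM − S̄| and (S_KM − S̄)² over
  the event-time grid from 0, where S̄ is the cohort-average (marginal)
  predicted curve. KM is a marginal estimator, so comparing it to
  per-subject curves would conflate discrimination with calibration; the
  marginal convention is this package's documented interpretation. The
  difference is taken as 0 at t = 0, where both curves are probability 1.
  IAE/ISE are in the data's time unit and are not normalized.

## Benchmark protocol

Selection happens inside each training split, never on full data —
selecting globally would leak test information into the panel. The default
protocol is a stratified 70/30 split on δ, 10 repeats averaged per cell,
with per-repeat seeds derived from a base seed; dataset tables, grand
averages, and win counts (best selector per dataset × metric, ties split
equally; minimized for IBS/IAE, maximized for CI) are emitted as CSV.

## Synthetic-data generator

The generator emulates the structure of high-dimensional survival cohorts:
equicorrelated standard-normal covariates (default pairwise correlation
0.2, a mild stand-in for co-expression), a sparse linear predictor with
`n_informative` coefficients at ±`beta_magnitude` (alternating sign, first
positions) and the rest exactly 0, Weibull proportional-hazards event times
(shape 1.5, scale 1) drawn by inversion, and independent exponential
censoring whose rate is calibrated by bracketed root-finding so the
expected censored fraction equals `censor_rate` (0 disables censoring).
The standard recovery design used throughout the tests is n = 300, p = 50,
5 informative features at |β| = 1.5, 40 % censoring.

What it does **not** emulate: heavy-tailed or grouped covariates,
block-correlation structure, non-proportional hazards, informative
censoring, measurement batch effects, or tied times (continuous draws are
almost surely tie-free; tie handling is exercised by dedicated fixtures
instead). Passing recovery tests therefore demonstrates correctness of the
algorithms under a proportional-hazards generating model, not robustness
to real-data pathologies.

## Problem sizes in the test suite

Long-running checks are run at documented desk scales chosen by this
package: recovery suites use 25 generator seeds with forests of B = 100
trees and a 25-point λ grid; oracle-equivalence suites use 1000 random
micro-instances (n ≤ 10) per operation; the random-score concordance
anchor uses 200 simulated cohorts of n = 200. Forest defaults outside the
tests remain B = 300 and the full 50-point λ grid.

## Known limitations

- The SCAD objective is nonconvex; LLA from the lasso start finds a good
  local solution but not a certified global one.
- Minimal depth uses the max-depth+1 penalty for unused features rather
  than the exact maximal-subtree depth distribution.
- The Brier-score weighting follows the convention that divides event terms
  by `Ĝ(t_i)` (not `Ĝ(t_i⁻)`); with continuous censoring times the two
  differ on a null set.
- Efron tie handling, stratified Cox models, robust variances, elastic net
  and adaptive lasso are not implemented.
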