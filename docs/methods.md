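# Methods

`stvcpanel` implements a Bayesian spatiotemporally varying coefficient (STVC)
analysis of areal panel data — the motivating application is county-level
healthcare-resource density (hospital beds per 10,000 people) observed over a
decade on a county contiguity map, explained by socioeconomic ("SE") and
environmental ("EX") covariates. This note records the model, the estimation
and evaluation machinery, the synthetic-data design, and the numerical and
design choices that were genuinely open.

## Observation model and preprocessing

The raw response `Y_it > 0` (area `i = 1..I`, year `t = 1..T`) is log
transformed, giving a Gaussian observation model on the log scale:

    log Y_it = eta_it + eps_it,   eps_it ~ N(0, sigma^2).

Every covariate is z-scored with one mean and standard deviation pooled over
the full space–time panel (not per year), so all coefficients live on a
single comparable "per standard deviation" scale; the standardization
metadata is kept so effects can be mapped back to original units. Covariates
that are constant over years within every area are flagged time-invariant
automatically. Missing response cells are allowed (they become prediction
targets); missing covariate cells in present rows are an error, and cells
left undefined by wholly absent rows are filled from the area's own
covariate mean, since they only ever feed the posterior predictive.

## The five nested models

With `x_p,it` the standardized covariates, the structured additive
predictors are

1. `eta = b0 + sum_p b_p x_p`                       (ordinary multivariate)
2. `eta = b0 + sum_p b_p x_p + xi_i + psi_t`        (+ space/time intercepts)
3. `eta = b0 + sum_p gamma_p,t x_p`                 (TVC: temporal coefficients)
4. `eta = b0 + sum_p mu_p,i x_p`                    (SVC: spatial coefficients)
5. `eta = b0 + sum_p (mu_p,i + gamma_p,t) x_p`      (STVC)

Spatial fields (`mu_p`, `xi`) carry an intrinsic CAR (Besag) prior on the
areal adjacency graph: conditionally, each value is Normal around the mean
of its neighbors with variance `sigma_f^2 / m_i`; the joint density is the
improper GMRF `exp(-x'Qx / 2 sigma_f^2)` with `Q = diag(m) - A`. Temporal
paths (`gamma_p`, `psi`) carry a first-order random-walk prior penalizing
squared successive differences (tridiagonal `Q`, rank `T - 1`). `Q` is used
raw — no rescaling by its generalized variance — so each variance component
is interpreted on the structure matrix as written. Each precision
`1/sigma^2` (observation and per field) carries a diffuse Gamma(1, 5e-5)
prior; global terms carry flat priors. Time-invariant covariates never
receive a temporal coefficient path (a covariate with no temporal contrast
cannot support one), so in models 3 and 5 they contribute only through
whatever spatial/global terms the model has — in model 3 they drop out
entirely, which is a documented consequence of that model's structure.

### Identifiability

Adding a constant to a TC path and subtracting the matching amount from its
paired SC field leaves `eta` unchanged, so exactly one member of each pair
is constrained. The scheme: TC, SI and TI fields are re-centered to zero
mean (per graph component for SI) after every update, with the removed mean
absorbed by the paired SC field, the matching global slope, or the
intercept; SC fields are left unconstrained so the spatially varying
coefficient carries its covariate's overall effect level (models 4 and 5
have no global slopes to carry it). A TC field with no paired term at all
(model 3) is left unconstrained for the same reason. This bookkeeping is
exactly `eta`-preserving, which the test suite checks directly.

Disconnected adjacency graphs are handled per component; for a multi-
component graph the SI field's component-level offsets beyond the global
mean are not representable by a single intercept and are discarded — a
known limitation that costs nothing on connected maps. Isolated areas carry
no ICAR information and are pinned to 0 in prior draws.

## Inference: blocked Gibbs sampling

Because the likelihood is Gaussian after the log transform, every latent
block has an exact Gaussian full conditional: precision
`Q / sigma_f^2 + diag(d) / sigma^2` with `d` the per-coordinate sum of
squared covariate values, and matching right-hand side from the partial
residual. The sampler sweeps: (1) all flat-prior global terms jointly, (2)
each field block via dense Cholesky of its conditional precision (I- or
T-dimensional — at the panel sizes this package targets, a few hundred
areas, dense factorization is faster and simpler than sparse machinery),
(3) conjugate Gamma updates of every precision using the prior rank of `Q`
(`n` minus the number of components for ICAR, `T - 1` for RW1), and (4)
data augmentation: missing response cells are re-imputed from the current
posterior predictive, which is what makes estimated response surfaces at
unobserved cells a byproduct of the fit.

Defaults: 2 chains x 5,000 iterations, 2,500 burn-in, no thinning, all
randomness derived from a single seed (runs are bit-reproducible).
Split-Rhat and effective sample size are computed (via ArviZ) for all
scalar quantities and variance components; any Rhat above 1.05 attaches a
warning to the fit rather than failing it. The replicate studies and tests
use shorter chains (stated below); at those lengths the diagnostics are
routinely clean for global terms, with occasional high Rhat on weakly
identified variance components of null fields — expected and harmless for
the quantities being checked.

## Model comparison

All criteria are computed from the draws x observed-cells matrix of
pointwise Gaussian log-likelihoods:

* **DIC** `= Dhat + 2 p_DIC`, `p_DIC = Dbar - Dhat`, with the plug-in at
  the posterior-mean linear predictor and posterior-mean observation
  variance (not all hyperparameters) — standard for hierarchical Gaussian
  models and well defined for every model 1–5.
* **WAIC** `= -2 (lppd - p_WAIC)`; `lppd` via log-sum-exp over draws,
  `p_WAIC` the summed posterior variance of pointwise log-likelihood.
* **LS**: the leave-one-out logarithmic score from conditional predictive
  ordinates, `CPO_c` estimated by the harmonic mean of pointwise
  likelihoods (computed in log space); `LS = -mean_c log CPO_c`, smaller
  better. Harmonic-mean CPO is noisy when importance weights concentrate;
  cells whose weights have effective sample size below 10 are counted and
  reported, never dropped.
* **R^2** `= 1 - SS_res / SS_tot` on the log (model) scale at the
  posterior-mean predictor, clamped to [0, 1]. (Whether to compute it on
  the log or original scale was an open choice; the log scale matches the
  scale the model is fitted on.)

## Covariate screening

Step 1: iterative VIF filtering, within each covariate block separately
(socioeconomic and environmental candidates are screened against their own
block). `VIF_j = 1 / (1 - R_j^2)` from regressing column `j` on the rest
plus an intercept; while the maximum exceeds the threshold (default 5), the
worst column is dropped and VIFs recomputed — greedy elimination rather
than one-shot thresholding, the standard realization of "keep the most
representative" within a collinear group. Every round is logged. Perfect
collinearity yields +inf, not an exception; a block reduced to one column
keeps it unconditionally.

Step 2: a regression random forest (500 trees by default, ~p/3 features per
split) ranks the survivors by MDI — impurity importance, where for a
continuous response the impurity is the split variance — and by MDA,
the mean increase in out-of-bag squared error over 10 permutations of each
feature (each sample predicted only by trees whose bootstrap missed it).
The selected set is the intersection of the two top-k lists (default
`k = ceil(p/2)`), ordered by mean rank. Screening rows are pooled
space–time cells (each area-year is one observation).

## Hot spots and response surfaces

Per-area summaries (e.g. posterior-mean SC fields) are classified with the
local Getis-Ord Gi* statistic under self-inclusive binary contiguity
weights (`w_i = m_i + 1`), with two-sided bands at |z| >= 1.645 / 1.960 /
2.576 (90/95/99%). No multiple-testing correction is applied by default,
mirroring descriptive hot-spot mapping; a Benjamini–Hochberg switch exists.
A constant field is classified all-not-significant with a warning.

Estimated response surfaces return to the original positive scale via the
full log-normal mean, `mean_s exp(eta_s + sigma_s^2 / 2)` — unbiased on the
original scale, unlike `exp` of the posterior-mean predictor — with
equal-tailed bands across draws; missing cells are filled from the same
posterior predictive.

## Synthetic data generator

The generator emits a miniature of the motivating panel with full ground
truth: a rook-contiguity lattice (default 10x10, standing in for a county
contiguity map), T = 10 years, 5 SE + 5 EX covariates with the last 2 EX
time-invariant. Covariates mix a spatial ICAR component, a temporal
random-walk component and white noise, are cross-correlated within the
time-varying and time-invariant groups (exchangeable rho = 0.3 by default;
mixing across the groups would destroy time-invariance), standardized, and
emitted on arbitrary raw units so preprocessing is genuinely exercised.

True SC fields are drawn from the constrained ICAR itself (so recovery
tests are well specified; a `misspecified_sc` switch draws iid Gaussian
fields instead), plus a per-covariate global effect level ~ N(0, 0.15^2).
True TC paths are centered random walks with increment sd 0.08. The ICAR
`scale` parameter is the average marginal standard deviation of the
constrained field (default 0.2); the RW1 `scale` is the increment standard
deviation — the natural parameter of each prior. Observation noise sd is
0.2 on the log scale, and `b0 = log 30` puts the default response mostly in
a realistic 5–100 beds-per-10,000 band. Missingness is completely at
random (default 5%) — the real-world missingness mechanism is unknown, so
nothing fancier is claimed.

The response is assembled through the *same* `linear_predictor` code path
the models use, evaluated at the truth, so there is a single source of the
predictor algebra; the pre-noise predictor is recorded for exact
self-consistency checks. Everything is bit-deterministic under the seed via
named substreams.

What the generator does **not** emulate: the real geography of any region,
real administrative-data marginals, informative missingness, measurement
error in covariates, or space–time interaction in the coefficients.
Passing recovery tests therefore demonstrates correctness of the machinery
under the model's own assumptions, not robustness to real-data violations
of them.

## Replicate studies and problem sizes

The packaged studies (`stvcpanel.experiments`) run seeded replicates at the
10x10 / T=10 / 3-covariate scale with 2 chains x 1,200 iterations (600
burn-in) per fit — long enough for stable posterior means of the fields
and criteria at this problem size. Across such replicates the STVC model
recovers true SC fields at mean Pearson r ~ 0.89 and TC paths at r ~ 0.93,
covers the true intercept at the nominal 95% rate, and wins DIC, WAIC, LS
and R^2 against models 1–4 essentially always, while costing roughly 40x
the effective parameters of the ordinary regression — the qualitative
comparison pattern the method exists to demonstrate.
`scripts/acceptance.py` recomputes all of these from scratch.

## Known limitations

* The harmonic-mean CPO estimator can be unstable for highly influential
  cells; instability is reported, not corrected (no Pareto smoothing).
* Per-component SI levels on disconnected graphs are discarded (above).
* Likelihoods other than log-Gaussian (areal counts), proper/Leroux CAR,
  RW2, and space–time interaction random effects are out of scope.
* Adjacency must be supplied (GAL or edge list); polygon topology is not
  derived from geometries.
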