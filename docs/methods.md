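# Methods

## Scope and conventions

The package analyses a three-variable mediation system — exposure X,
mediator M, outcome Y — from study-level correlation evidence.  The
correlation vector is fixed throughout as (r_XM, r_XY, r_MY) and all
matrices use variable order (X, M, Y); a single canonical vectorization
prevents silent element swaps between stages.

## Effect-size ingestion

Studies report correlations, standardized regression betas, or full path
models; all are converted to correlations before pooling.

* **Beta to r.** The empirical imputation r = 0.98·β + 0.05·λ, λ = 1 for
  β ≥ 0, clamped to (−0.999, 0.999) so that Fisher transforms stay
  finite.  The conversion was calibrated on |β| ≤ 0.5; larger values
  convert but emit a warning.  The function is monotone with a 0.05 jump
  at β = 0 — a property of the imputation itself, not of this
  implementation.
* **Path models.** For a recursive standardized model with coefficient
  matrix B (strictly lower triangular in causal order) the implied
  correlation matrix is Σ = (I−B)⁻¹ Ψ (I−B)⁻ᵀ with diagonal residual
  variances Ψ solved sequentially so every variance is 1.  For the
  mediation model this reduces to (a, c′ + a·b, b + a·c′).  A path-model
  entry informs all three relations.
* **Composites.** Multiple within-study effects for the same relation
  are combined as the back-transformed unweighted mean in Fisher-z
  space.  Weighting by subscale size is deliberately not done: composite
  formation is defined on the z scale without weights, and inputs rarely
  carry the information a weighted version would need.
* **Admissibility.** A complete reported triple that is numerically
  non-positive-definite is projected to the nearest correlation matrix
  (Higham alternating projections, via statsmodels).  The repair is
  logged; if any element must move by more than 0.05 the study is
  dropped (with a warning) rather than rewritten.

Every conversion, composite, repair and drop is appended to a plain-text
provenance log.

## Stage 1: random-effects pooling

Within-study sampling covariances use the normal-theory fourth-moment
(Olkin–Siegel) formulas, Var(r_ij) = (1−ρ_ij²)²/n and the matching
covariance for element pairs.  They are evaluated at a **fixed-effects
reference triple** obtained in two passes: an n-weighted element-wise
mean seeds the formulas, and the resulting GLS fixed-effects pool is the
reference at which the final covariances are computed.  Evaluating at a
pooled reference rather than each study's own noisy estimate stabilizes
small-study covariances.

The random-effects model places independent between-study variances on
the three elements (diagonal tau², no between-element tau covariances —
matching what meta-analyses of correlation matrices typically report).
Estimation is maximum likelihood, not REML: the pooled triple is
parameterized through atanh to stay in (−1, 1) and tau² through a
softplus to stay non-negative; L-BFGS-B with up to five deterministic
jittered restarts, convergence at gradient ∞-norm 1e−6.  Studies are
grouped by observation pattern so the likelihood is evaluated with
batched 3×3 (or smaller) Cholesky factorizations.  The asymptotic
covariance of the pooled triple is the inverse observed information for
the mean parameters, Σᵢ Pᵢ' Σᵢ⁻¹ Pᵢ, with the estimated tau² plugged in.
An element observed in fewer than two studies has its tau² fixed at 0
with a warning.  If the pooled triple is not positive definite (possible
under extreme missingness) it is projected to the nearest correlation
matrix and flagged.

Heterogeneity: Q = Σᵢ (rᵢ − r̂_FE)' Vᵢ⁻¹ (rᵢ − r̂_FE) over observed
elements against χ² with df = (observed elements) − 3; per-element
I² = tau² / (tau² + ṽ) with the Higgins–Thompson typical within-study
variance ṽ = (k−1)Σw / ((Σw)² − Σw²), w = 1/Var(rᵢ); the mean I² across
the three elements is the arithmetic mean.

## Stage 2: WLS mediation fit

F(θ) = (r̂ − ρ(θ))' acov⁻¹ (r̂ − ρ(θ)) is minimized by BFGS with the
analytic Jacobian of ρ(θ), started at the closed-form inversion
(a = r_XM, b = (r_MY − r_XM·r_XY)/(1 − r_XM²), c′ = (r_XY −
r_XM·r_MY)/(1 − r_XM²)), so the saturated case converges immediately
with F ≈ 0 and df = 0.  SEs come from (J'WJ)⁻¹, the inverse Hessian of
F/2 at the optimum.  Named paths can be fixed, each adding one df, and
F_min is then a chi-square statistic.

The indirect effect is a·b.  Its default CI is the delta method,
Var(ab) = b²Var(a) + a²Var(b) + 2ab·Cov(a,b) — deterministic and
auditable; a profile interval (inverting the WLS discrepancy over a·b at
the χ²(1) 95% point, inner minimization by SLSQP) and a parametric
bootstrap (default 2,000 seeded draws of the pooled triple from
N(r̂, acov), inadmissible draws rejected, closed-form refit, percentile
interval) are available as options.  On admissible inputs of the scale
this package targets, the three intervals agree closely; tests check the
delta/bootstrap widths within 10% at large total n.

## Moderation and sensitivity

Stage 1 is pooled **per subgroup** (separate rho, tau², acov), then the
equality of (a, b, c′) across the two groups is tested by minimizing the
joint WLS discrepancy with shared paths.  Each unconstrained group model
is saturated, so the constrained joint minimum is itself the chi-square
difference, with df = 3 for the omnibus test; single-path tests (df = 1)
are reported as secondary, exploratory output — their statistics are not
additive and are not treated as such.

Sensitivity analyses exclude studies by flag — nightmare/PTSD item
overlap, participants under five, or beta-converted effects — and re-run
ingestion, Stage 1 and Stage 2 on the remainder, reporting main and
sensitivity estimates with absolute differences.  An empty flag set
reproduces the main run exactly.

## Synthetic data generator

The generator draws, per study: element-wise true deviations
u ~ N(0, diag(tau²)) added to the population triple implied by the
generative paths (heterogeneity is placed on correlation elements, the
same place the Stage-1 model puts it, so recovery tests are directly
interpretable; a paths-level per-group override exists for moderation
power studies); a log-normal sample size (median 800, σ_log = 1.2,
truncated to [30, 50,000] — a right-skewed evidence base summing to a
few hundred thousand participants at K ≈ 100); sample correlations
either from n simulated multivariate-normal observations (``raw``) or
from the asymptotic normal with normal-theory covariance (``fast``);
a Bernoulli missingness mask with per-element observation probabilities
(0.6, 0.7, 0.6) and at least one element forced present; subgroup labels
(cross-sectional share 74/98, Western share 68/98) and sensitivity flags
(rate 6/98 each).  Inadmissible study-truths are rejection-sampled (≤100
attempts) with nearest-correlation projection as a logged fallback, and
a warning is emitted if more than half the studies needed handling.
Everything is reproducible from a single integer seed.

What the generator does **not** emulate: item-level psychometrics and
measurement error, selective reporting or publication bias, overlapping
cohorts, and non-normal raw data.  Passing recovery tests therefore
show that the estimator inverts its own assumed data-generating process
at realistic scale — not that those real-data complications are handled.

## Problem sizes used in the test suite

Deterministic checks run at full precision (1,000 random triples for the
WLS/closed-form equivalence).  Stochastic checks use sizes chosen to
keep the suite fast while leaving comfortable statistical margins:
pipeline recovery averages 20 raw-mode replicates of K = 98; the Q-test
and equality-test null calibrations use 500 fast-mode replicates each at
K = 50 per arm (both rejection rates land near 0.04–0.07 against the
nominal 0.05); the Monte-Carlo covariance oracle uses 100,000 datasets
of n = 500; CI coverage and subgroup-ordering properties use 40–60
seeded replicates.

## Known limitations

* tau² is diagonal; correlated between-study deviations across elements
  are not modeled (and not identifiable from typical reporting).
* The equality-constraint test plugs in estimated Stage-1 covariances;
  with very few studies per group it can be mildly anticonservative,
  as is usual for Wald-type multi-group tests.
* No publication-bias diagnostics, meta-regression on continuous
  moderators, or more than two groups per moderator.
* Conversions cover betas and recursive path models; odds ratios,
  Cohen's d and 2×2 tables must be converted upstream.
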