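# Methods

## The index and its estimator

Let W₁,…,Wₙ be independent observations and θ̂ the maximizer of the sample
average Ψ(θ) = n⁻¹Σᵢψ(θ; Wᵢ), equivalently the root of the averaged score.
With J = −E ∂²Ψ/∂θ∂θᵀ (bread) and K = E[score scoreᵀ] (meat), √n(θ̂ − θ) is
asymptotically normal with the sandwich covariance J⁻¹KJ⁻¹, a limit that does
not require the second-moment (variance) model to be correct. Partition
θ = (α, β) with m₀ nuisance and m₁ target coordinates (target block last
throughout the package). The robust effect size index is

    S² = (β − β₀)ᵀ Σ_β⁻¹ (β − β₀),

where Σ_β is the target block of the sandwich and β₀ a user-chosen reference
(zero by default). S is reported as the nonnegative root; direction is the
caller's concern. n·S² is the noncentrality of the robust Wald statistic
T² = n(β̂ − β₀)ᵀΣ̂_β⁻¹(β̂ − β₀), which is the bridge to power analysis.

The estimator is the truncated noncentrality root

    Ŝ = √max{0, (T² − m)/(n − m)},

where m = m₀ + m₁ is the *total* parameter count — the subtraction of m (not
m₁) and the (n − m) divisor account for estimating all parameters. Ŝ is
consistent but biased in small samples: truncation forces Ŝ ≥ 0, so the null
case is biased upward, and the finite-sample behaviour of the plug-in
sandwich inflates T² at small n. The simulation module quantifies both
effects. Confidence intervals for Ŝ are out of scope.

Assumptions worth stating: observations are independent (no clustered or
longitudinal sandwich variants), the outcome is scalar for the built-in
families, and the score has a root in the interior of the parameter space.
No small-sample correction (HC1–HC3) is applied to the meat; J and K are
averaged over n, and all small-sample correction lives in the (n − m)
divisor of Ŝ.

## Estimation engine

- **Solver.** Damped Newton on the mean score: analytic Hessian when the
  family provides one, otherwise central finite differences with step
  ε^{1/3}(1 + |θⱼ|); step halving until the score norm decreases; cap 100
  iterations, gradient tolerance 1e-8 (∞-norm). Failures are explicit: a
  `ConvergenceError` naming the final gradient norm, a
  `RankDeficientDesignError` naming the offending design columns (QR with
  column pivoting), a `SingularMatrixError` naming the condition number.
- **Bread/meat.** J is the symmetrized negative Hessian at θ̂ (singular J,
  cond > 1e12, is an error); K is the empirical outer product of
  per-observation scores. For the least-squares family n⁻¹·Σ̂ reproduces the
  textbook HC0 covariance (X'X)⁻¹X'diag(e²)X(X'X)⁻¹ to machine precision;
  this equivalence is a standing test invariant.
- **Two-means family.** The difference-in-means score
  (2xᵢ−1)π_{xᵢ}⁻¹yᵢ − θ defines a single parameter μ₁ − μ₀ without assuming
  identically distributed outcomes. Its K is defined *conditionally on the
  design*; the raw score outer product instead converges to the marginal
  score variance, which differs whenever the scaled group means are not
  centred (the score is not location-invariant). The family therefore
  supplies a specialised meat from group-centred residuals,
  n⁻¹Σ π_{xᵢ}⁻²(yᵢ − μ̂_{xᵢ})², whose limit is π₁⁻¹σ₁² + π₀⁻¹σ₀². Group
  proportions may be declared known or estimated as n₁/n; the mode is
  recorded on the problem. Regression-family scores have conditional mean
  zero given the design, so for them the generic outer product needs no such
  adjustment.
- **Contracts.** A user-supplied objective is validated against the score by
  numerical differentiation at random probe points at construction time.

## Closed forms

- **Two groups.** S = √[(μ₁−μ₀)² / (π₁⁻¹σ₁² + π₀⁻¹σ₀²)]: proportional to
  Cohen's d under equal variances, but it absorbs unequal variances and
  unbalanced sampling — exactly the design features that move the power of
  the test.
- **Simple linear regression.** S = |β|·√(σₓ⁴/σ²ₓᵧ) with
  σ²ₓᵧ = E[(X−μₓ)² e²]; under homoskedasticity this collapses to
  |β|·√(σₓ²/σ²). Moments can be supplied analytically or as divide-by-n
  plug-ins from a sample (consistent with the J/K averaging convention).
- **Logistic regression.** With model weights P = p(1−p) and empirical
  weights Q = (y−p)², the blocks A_kl(W) = n⁻¹X_k'diag(w)X_l yield the
  information of the target after projecting out the nuisance,
  I_β = A₁₁(P) − A₁₀(P)A₀₀(P)⁻¹A₀₁(P), and the robust block Σ_β assembled
  from the mixed P/Q formula. When P = Q (no over/underdispersion)
  Σ_β = I_β⁻¹ and S = √(βᵀI_β β) — a fully standardized coefficient that
  discounts collinearity with the nuisance block. A redundancy test
  recomputes Σ_β through the generic sandwich on the same data and requires
  agreement to ~1e-8, guarding the block algebra against transcription
  error.

## Conversions and bands

All conversions route through S, so every pairwise round trip is an exact
identity (tested to 1e-12): S ↔ d via the design factor (π₁⁻¹+π₀⁻¹)^{±1/2},
f² = S², R²_β = S²/(1+S²) in the no-other-covariate case, and the
two-argument forms R²_β/(1−R²), f²_β/(1+f²) when a full model is present.
d-conversions return magnitudes. Bands on the S scale are [0, 0.1]
none-small, (0.1, 0.25] small-medium, (0.25, 0.4] medium-large (right-closed
endpoints); above 0.4 the classifier reports "large", an open-ended
extrapolation beyond the published thresholds, labelled as such in CLI
output. These thresholds are conventions for the behavioral sciences, not
universal clinical judgments.

## Bias of classical indices

The pooled-SD Cohen's-d estimator converges to a limit standardized by the
pooled variance π₁σ₁² + π₀σ₀²; the robust d standardizes by the sandwich
variance. Their ratio

    d_C/d(S) = (π₁⁻¹+π₀⁻¹)^{−1/2} · √[(π₁⁻¹σ₁² + π₀⁻¹σ₀²)/(π₁σ₁² + π₀σ₀²)]

equals 1 iff π₁ = 1/2 or σ₁² = σ₀², is symmetric about (0, 1/2) in
(log₂ σ₁²/σ₀², π₁) coordinates, and exceeds 1 (classical d overestimates)
when the minority group has the larger variance. For regression,
R²_C/R²(S) = (σₓ⁴β² + σₓ²σᵧ²)/(σₓ⁴β² + σ²ₓᵧ), equal to 1 under
homoskedasticity. A note on the pooled-SD form: the limiting d_C is
implemented with the square root over the pooled variance (the estimator a
practitioner actually computes); the ratio formula above is consistent with
that form, and the empirical concordance test (Monte-Carlo pooled-SD d̂ over
the robust d) pins it down. Percent bias is reported as 100·(ratio − 1).

## Power

Power = 1 − Φ_df(Φ_df⁻¹(1 − t₁; 0); n·S²) with Φ(·; λ) the noncentral
chi-squared CDF. S = 0 returns t₁ exactly (by construction, not by the tail
routine). Inversions for n, S and t₁ use bracketed Brent root searches —
n on [1, 10⁹], S on [0, 100], tolerance ~1e-10 — exploiting monotonicity;
n is treated as continuous with an optional ceiling. The asymptotic power
formula uses population S; no finite-sample (n − m) adjustment is propagated
into the noncentrality, and post-hoc power from a plug-in Ŝ is accepted
as-is without bias adjustment.

## Synthetic-data generator and simulation study

The generator emulates a regression study with correlated covariates and
covariate-driven heteroskedastic, skewed errors:

- Covariates: mean-zero multivariate normal, identity within-block
  covariance, constant cross-block entries ρ²/(m₀m₁), so the total squared
  nuisance–target correlation is ρ². Defaults cover ρ² ∈ {0, 0.6}, m₀ = 2,
  m₁ = 1; m₀ ∈ {2, 5} and m₁ ∈ {1, 3, 5} are available behind the config.
- Outcomes: E[Y|X] = β·Σ_k X_{target,k} (the common coefficient β on every
  target covariate; the nuisance covariates carry no signal), plus a gamma
  error with shape a and rate √(a/x_v²), centred to mean zero, where x_v is
  the first target covariate. This gives Var(Y|X) = x_v² and conditional
  skewness 2/√a (0.63 at the default a = 10; a = 0.5 is available). A floor
  of 1e-8 on x_v² guards the degenerate rate at x_v ≈ 0. Centring is forced
  by the stated mean structure. Note the *marginal* error distribution is a
  scale mixture (skewness ≈ 1.01 for standard-normal x_v); the 0.63 figure
  is conditional, and tests check it with the variance driver pinned at 1.
- Calibration: because the errors are additive and β-free, Σ_β does not
  depend on β, and for this Gaussian design it has the closed form
  Σ = Σ_X⁻¹ + 2e_v e_vᵀ (Isserlis' fourth-moment identity applied to
  K = E[x_v² XXᵀ]). Hence S(β) = |β|·√(𝟙ᵀΣ_β⁻¹𝟙) and
  β = S·(𝟙ᵀΣ_β⁻¹𝟙)^{−1/2} exactly — no Monte-Carlo calibration noise. The
  closed form is itself verified against a brute-force simulated sandwich in
  the test suite.
- Fits include an intercept (the practitioner default); for this mean-zero
  design the intercept's cross moments with the meat vanish, so Σ_β and the
  calibration are unchanged, and m = 1 + m₀ + m₁ enters Ŝ.
- The grid driver replicates each (n, S, ρ²) cell, estimates Ŝ through the
  full least-squares pipeline, and reports bias = mean(Ŝ) − S and the
  across-replicate standard deviation. Seeding uses spawned `SeedSequence`
  streams per cell and replicate, so identical (config, seed) reproduce
  bit-identical summaries; replicate failures are logged and counted, never
  fatal to the grid.

What the generator does *not* emulate: dependent observations, outliers
beyond gamma skewness, non-Gaussian covariates, measurement error, or
model-selection effects. Passing tests therefore speak to estimator
behaviour under covariate-driven variance and skewed errors, not to all
real-data pathologies.

Problem sizes in the default test run are chosen to make Monte-Carlo checks
sharp but cheap: the replication grid uses 200 replicates per cell over
n ∈ {25, 100, 500} and S ∈ {0, 0.25, 0.6} (the qualitative findings —
upward bias at n = 25 shrinking below 0.03 by n = 500, spread increasing in
S, insensitivity to ρ² — are stable across seeds at this size), and
rejection-rate concordance uses 2000 replicates at n = 500. Consistency
checks run at n = 10⁴–10⁵; moment oracles at n up to 10⁶.

## Numerical and statistical choices

- Tolerances: score root 1e-8; HC0 equivalence 1e-8 relative; conversion
  identities 1e-12; power inversions ~1e-10.
- Monte-Carlo assertions use 3 standard errors (block-based where the
  statistic is nonlinear, e.g. skewness); the ρ²-agreement check compares 9
  cell pairs simultaneously and uses 3.5 combined SEs per pair, a
  Šidák-style allowance keeping the family-wise strictness at the usual
  3-SE level; the rejection-rate check uses the Agresti–Coull-adjusted
  binomial SE because the predicted power sits near 1, where the raw
  plug-in SE degenerates.
- Ŝ's truncation flag records T² < m; Ŝ = 0 exactly when T² ≤ m.
- Degenerate inputs fail loudly with domain-specific messages (non-PD
  Σ_β, rank-deficient designs, unreachable power targets, non-PD covariance
  requests with the minimum eigenvalue named).

## Known limitations

- No confidence intervals or standard errors for Ŝ; improved noncentrality
  estimators (the truncated form is inadmissible in the decision-theoretic
  sense) are noted but not implemented.
- Scalar outcomes only; no clustered/longitudinal sandwiches or GEE.
- The index is defined conditionally on the covariates; marginal effect
  summaries require a different estimand and are out of scope.
- Asymptotic power only; at very small n the robust Wald statistic
  over-rejects, which is visible as the upward bias of Ŝ at n = 25 in the
  simulation grid.
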