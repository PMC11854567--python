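# Methods

## Model

Observations `D_i = (X_i, Y_i, δ_i)`, `i = 1..n`, with covariates
`X = (U', Z')'` always observed and the response `Y` observed iff
`δ = 1`.  Missingness is MAR through the direct covariates:
`Pr(δ = 1 | X) = π(U; γ)`, modeled as logistic
`logit π = γ_c + U'γ_u` (q = 1 + dim U parameters).  The substantive
model is a set of unconditional moment restrictions
`E[g(X, Y; β)] = 0` (r of them, p parameters).  The stacked system per
observation is

    G(D_i; θ) = ( (δ_i/π_i) g(X_i, Y_i; β) ,  (δ_i/π_i − 1) d(Z_i) ),

θ = (β', γ')', t = r + m ≥ s = p + q.  The calibration map defaults to
`d(Z) = (1, Z)`: the constant is required for the propensity intercept to
be identified (m = q).  Three moment families ship:

* **linear**: `g = (1, X)'(Y − β_c − X'β_x)` — the premultiplier uses the
  full covariate so that all p + 1 outcome coefficients are identified
  (an instruments-only variant is available but identifies only the
  Z-block);
* **logistic**: `g = (1, Z)'(Y − expit(β_c + Z'β_x))`, binary `Y`;
* **SEM / vech**: `g = vech(Y Y' − B Σ_X B' − α I)` for an e-vector of
  manifest variables loading on f latent variables through `B` (e × f);
  the latent covariance `Σ_X = T Σ_Z T'`, `T = [C_u; I]`, is held fixed
  at its structural value and only `B` is estimated.

## ET likelihood and the saddle point

The ET likelihood minimises `Σ w_i log w_i` under the weighted moment
constraints; its dual profile is `l_n(λ, θ) = log mean_i exp(λ'G_i)`,
convex in λ with `l_n(0, ·) = 0`, and the estimator maximises
`ψ(θ) = inf_λ l_n(λ, θ)`.  The inner problem is solved by damped Newton
on the log-mean-exp form: the Hessian is the softmax-weighted covariance
of the moment rows, every quantity is computed after max-subtraction, and
the moment columns are rescaled to unit RMS (the multiplier absorbs
column scalings exactly).  Exponents `λ'G_i` are restricted to ±500 — a
domain condition, not a value clip; a *tight* cap would stop the infimum
early on wild moment configurations and overstate ψ, which corrupts model
comparison, so the cap is deliberately generous.  The hot kernel is JIT
compiled with numba when available.

The outer maximisation is a damped Gauss–Newton ascent with the envelope
gradient `Σ_i w_i J_i'λ̂` and the curvature model `D'Ω⁻¹D`
(`D = Σ w_i J_i`, `Ω = Σ w_i G_iG_i'`).  Objective evaluations inside
line searches use a looser inner tolerance (1e-6) than gradients and
final values (1e-9); all BIC values are recomputed by a cold, deep inner
solve so that model comparison never inherits warm-start optimism.

## Penalization

SCAD (shape a = 3.7), Lasso and adaptive Lasso on the standardized
coefficient scale (covariate columns divided by their sample standard
deviations, estimates reported raw) — standard penalized-regression
practice, and essential in designs where the raw scales of active and
inactive covariates differ by an order of magnitude.  Intercepts are
never penalized.  The penalized objective is maximised by nested local
quadratic approximation: diagonal weights `ṗ_ν(|θ_j|)/|θ_j|`, a damped
quadratic step (with an equality-constrained KKT variant for contrast
restrictions), exact deletion of coordinates below the floor 1e-4,
no resurrection.  Two auxiliary deletion rules keep the path honest
under collinearity: a *partial-cost* rule (a small coordinate is deleted
when `θ_j²/(2[A⁻¹]_jj)` — its re-optimised fit cost — is below the
penalty it saves, letting collinear partners re-adjust afterwards) and a
*zero-check* at stalls (setting a small coordinate exactly to zero is
accepted when it costs no more than the stopping tolerance).

Tuning: geometric grids for (ν₁, ν₂) spanning `[0.01, 2]·√(log s / n)`,
with the upper end extended to the 90th magnitude percentile of the dense
estimate's penalized coordinates (so the grid reaches the coefficient
scale).  The default search is sequential — a coupled ν₁ = ν₂ path, then
one refinement pass per block — with every fit started from the dense
(unpenalized) ET estimate; a full product grid is available.  BIC is
`−2 n l_n(λ̂, θ̂_ν) + B_n log(n) df_ν`, df = all nonzero coefficients,
`B_n = max(log log s, 1)` for growing dimension.  The per-observation
form of the criterion (without the factor n) degenerates — the fit term
vanishes asymptotically against the complexity term — so the χ²-scaled
form standard in the (generalized) empirical likelihood literature is
used.  A `lasso_stage="shared"` option runs one Lasso-weighted pass at
the middle of the grids and starts every SCAD fit from it; this resolves
directions that the likelihood leaves flat or nearly flat (collinear
covariate pairs, factor rotations).  After selection, a backward polish
revisits each surviving penalized coordinate and keeps any deletion that
lowers the BIC (disabled for the SEM family, where the flat directions
make the polish remove true loadings).

## Locality

All consistency and oracle statements for this estimator are local: they
concern solutions in a root-n neighbourhood of the truth.  Designs that
violate the overlap condition (propensities not bounded away from zero)
or moment boundedness admit spurious distant optima of ψ — extra free
coordinates can "absorb" the tilting cost of an unfittable calibration
block.  Fits are therefore anchored: a box
`|θ_j − θ_init,j| ≤ 2(1 + |θ_init,j|)` around the consistent complete-case
initialiser (complete-case least squares / ridge-logistic; ridge 1e-2 so
separation cannot blow up the start).  The evaluated propensity is
floored at the overlap constant (`π* = max(π, c₀)`); the package default
is c₀ = 0.01, and the replication harness uses c₀ = 0.3 for the two
regression designs, whose generating propensities are essentially 0 or 1
for most units (see Limitations).

## The synthetic-data generators

Three study designs with known sparse truth (defaults are the published
configurations):

1. **Linear**: instruments `Z ~ N(0, Σ)`, `Σ_kl = 0.5^{|k−l|}`; direct
   covariates `u_j ~ N(10 z_j, 1)`; `Y = 1 + 0.6 u₁ + 0.5 u₂ + N(0,1)`;
   missingness `logit π = 1 + 0.8 u₁ + 0.5 u₂` (M1), a two-level step
   mechanism with levels (0.5, 0.9) cut at the predictor median (M2,
   deliberately misspecified; the printed definition assigns one level to
   both branches and is read as a typo), or probit (M3).
2. **Logistic**: `Z ~ N(0, I_p)`, binary `Y` with
   `logit = 1 + 0.6 z₁ + 0.5 z₂`; `u_j ~ N(z_j, 100)` drive missingness
   with the same γ truth.
3. **SEM**: latent `Z = C_z⁻¹ ε_z`, `ε_z ~ N(0, 0.8 I)`, `U = C_u Z`
   (no latent noise on U), manifest `Y = B X + N(0, 0.8 I)`; loadings
   0.6 on the band `|j₁ − j₂| = 1`; `n = round(((p + 80)/18)³)`.  The
   printed coupling matrices (unit diagonal, ±0.5 / ±0.8 off-diagonals)
   are used directly as the reduced-form maps: the alternative reading
   `Z = (I − C_z)⁻¹ ε_z` is exactly singular for odd `f − h`, i.e. for
   two of the three published configurations.

What the generators do **not** emulate: real covariate measurement error,
model misspecification of the outcome moments, non-logistic truth beyond
M2/M3, per-component missingness of a multivariate response (a single
indicator governs the whole vector), or any real-data covariate
distribution.  Passing the Monte-Carlo checks therefore demonstrates
internal consistency of estimator + generator under these specific
designs, not field performance.

The replication harness derives per-replication seeds from the master
seed by a counter scheme (`SeedSequence([seed, rep])`), so results are
independent of the worker count; failed fits are recorded and excluded,
with a flag above 10%.  Metrics: per-coordinate bias / SD / RMSE with
divisor-T conventions (so RMSE² = bias² + SD² exactly); TP (true zeros
estimated zero) and FP (true nonzeros estimated zero) averaged over
replications; per replication UF (some true zero kept — this literature's
naming, the reverse of common usage), CF (exact support recovery), OF
(otherwise); intercepts excluded from the counts.  Coverage (CP) and
average length (AL) are computed for a tracked coordinate from
profile-LR or Wald intervals.

## Inference

For `H₀: Cθ = c` (orthonormal rows), the constrained fit runs the same
LQA machinery with the restriction in each quadratic step (KKT), the
penalties held at the unconstrained tuning.  The statistic
`2n[l_pn(θ̂) − l_pn(θ̃)]` is scaled by
`M = e / tr[(C V_model C')⁻¹ (C V_sand C')]`, where `V_model` is the
inverse Gauss–Newton curvature on the support and `V_sand` the sandwich
covariance of the first-order (λ, θ) system (second-derivative terms of
G dropped — exact at λ = 0); `M → 1` under correct specification, and a
numerically unstable `M` falls back to 1 with a warning.  When the
constrained solve lands above the unconstrained optimum (a stall), the
unconstrained fit is re-polished from the constrained point before the
statistic is formed.  Scalar intervals invert the scaled profile by
noise-tolerant bisection; Wald intervals from the sandwich are the
fallback and are always available.

On benign-overlap linear designs (unit-scale covariates, propensities
bounded away from zero) the scaling stays near one and the profile and
Wald intervals agree in width order, which the test suite checks
directly; see Limitations for the behaviour under the published designs.

## Problem sizes used in the shipped checks

Monte-Carlo checks run at 200 replications (300 for the smallest linear
design and for the coverage study), tuning grids of 8 points, and the
Wilks calibration gate at 500 simulated datasets of the n = 500, p+1 = 9
linear shape.  These are the package's desk-scale choices; all quantities
are recomputed from scratch at run time.

## Known limitations

* **Overlap violation in the regression designs.**  With direct
  covariates of standard deviation ≈ 10 and slopes 0.8 / 0.5, the
  generating propensity is essentially 0 or 1 for most units:
  `E[1/π]` diverges, the sample calibration equations typically have *no
  root* near the truth, and the propensity coefficients escape toward
  the separation limit.  The outcome block remains consistent
  (complete-case regression is valid under covariate-only MAR), and
  propensity *selection* is penalty-driven and reliable, but propensity
  *magnitudes* are weakly identified, inverse weights are heavy-tailed,
  and both the exact-recovery proportions and the Wilks calibration
  degrade relative to a benign-overlap design.  The published per-table
  values that presuppose near-perfect behaviour here (exact-recovery
  ≈ 0.98, intercept RMSE 0.005 — below the full-data information bound)
  could not be reproduced by this implementation and, as far as we can
  determine, are not attainable under the printed designs.
* **SEM rotation flatness.**  With Gaussian latents and second-moment
  constraints only, the loadings are identified exactly up to a factor
  rotation (and globally up to sign), and rotated representations can be
  *sparser* than the generative one.  Support recovery of the generative
  pattern is therefore only meaningful for the local solution near the
  truth; the Monte-Carlo study anchors the dense stage at the generative
  loadings and restricts the fit to a `√(t/n)` box — the neighbourhood
  in which the estimator's oracle statements live (the signal size 0.6
  stays separated from the deletion range inside it, as the theory
  assumes).  Even so, the data at n = 241 barely distinguish merged
  one-coordinate rows from the generative two-coordinate rows (the BIC
  gap is ~1 complexity unit), so exact-recovery proportions stay below
  the published ones.
* The Wald sandwich drops second-derivative-of-G terms (exact for
  just-identified systems, O(‖λ̂‖) otherwise).
* FCP and MCP penalties, nonignorable missingness, per-component
  response missingness and nonparametric propensities are out of scope.
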