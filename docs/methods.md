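# Methods

## Estimand and estimator family

The estimand is the average treatment effect β = E[Y¹ − Y⁰] under the usual
identification assumptions: unconfoundedness (Y⁰,Y¹ ⫫ A | W), positivity
(0 < P(A=1|W) < 1) and consistency (Y = Y^A). Estimation is two-step: first
the outcome surfaces Q(a,W) = E[Y|A=a,W] and the propensity score
g(W) = E[A|W] are estimated, then the predictions are plugged into a
second-step estimator.

All second-step estimators implemented here are specializations of the
general doubly robust (GDR) form

    β̂ = (1/n) Σᵢ [ Aᵢ(yᵢ − Q̂¹ᵢ)/h¹ᵢ − (1−Aᵢ)(yᵢ − Q̂⁰ᵢ)/h⁰ᵢ ] + (1/n) Σᵢ (Q̂¹ᵢ − Q̂⁰ᵢ),

indexed by per-unit denominators (h¹, h⁰):

| scheme  | h¹            | h⁰                    |
|---------|---------------|-----------------------|
| aipw    | ĝ             | 1 − ĝ                 |
| naipw   | ĝ·γ̂           | (1−ĝ)·λ̂               |
| trimmed | ĝ·γ̂ if ĝ<ε else ĝ | (1−ĝ)·λ̂ if ĝ>1−ε else 1−ĝ |

with γ̂ = (1/n)Σ Aᵢ/ĝᵢ and λ̂ = (1/n)Σ(1−Aᵢ)/(1−ĝᵢ). With the nAIPW
denominators the correction terms are exactly the self-normalized (Hájek)
ratio forms: weights within each arm sum to one, so each correction is a
convex combination of residuals and |β̂_nAIPW − β̂_SR| is bounded by the
largest residual magnitudes. AIPW enjoys no such bound: a treated unit with
ĝ = 10⁻ˢ contributes an additive (1/n)·10ˢ·(yₖ − Q̂¹ₖ) that dominates once
10ˢ ≫ n, whereas the nAIPW treated component converges (in s) to
yₖ − Q̂¹ₖ + mean(Q̂¹). Both schemes satisfy the moment conditions
E[A − h¹] = 0, E[(1−A) − h⁰] = 0 when g is correct, are doubly robust
(consistent if either the outcome or the propensity model is consistent),
rate doubly robust (the second-order remainder is bounded by the product of
the two nuisance RMS errors), and Neyman-orthogonal (vanishing Gateaux
derivative of the estimating function in the nuisance directions), so
cross-fitting restores valid asymptotics with slowly converging ML
first steps.

The naive, SR, IPW and nIPW comparators are the corresponding textbook
estimators; the naive contrast deliberately averages the *predictions* per
arm (not raw outcomes), mirroring how the family is usually tabulated.

### Variance estimation

Standard errors come from the influence-function representation:

    σ̂²_AIPW  = (1/n²) Σᵢ [ Aᵢ(yᵢ−Q̂¹ᵢ)/ĝᵢ − (1−Aᵢ)(yᵢ−Q̂⁰ᵢ)/(1−ĝᵢ) + (Q̂¹ᵢ−Q̂⁰ᵢ) − β̂ ]²
    σ̂²_nAIPW = Σᵢ [ Aᵢ(yᵢ−Q̂¹ᵢ)wᵢ(1)/Σⱼ Aⱼwⱼ(1) − (1−Aᵢ)(yᵢ−Q̂⁰ᵢ)wᵢ(0)/Σⱼ(1−Aⱼ)wⱼ(0) + (Q̂¹ᵢ−Q̂⁰ᵢ−β̂)/n ]²

with w(1)=1/ĝ, w(0)=1/(1−ĝ). The per-unit centering term Q̂¹ᵢ−Q̂⁰ᵢ follows
the efficient influence function; an alternative sometimes written with the
scalar average β̂_SR in its place is available via `variance_form="literal"`.
The two coincide whenever Q̂¹−Q̂⁰ is constant across units (e.g. under the
default partially linear outcome network). nAIPW influence contributions
sum to zero by construction, and confidence intervals are β̂ ± 1.96·SE.
With complex, weakly regularized first-step models these asymptotic SEs are
known to understate the Monte Carlo dispersion; the harness reports both so
the gap is visible.

### Numerical choices

- Propensities are floored into [1e-12, 1−1e-12] at container construction,
  purely to avoid division by a rounded 0/1. No statistical trimming is
  applied by default — studying untrimmed behaviour is the point. An exact
  0/1 propensity reaching the IPW estimators raises an error rather than
  being clipped silently.
- The trimmed hybrid scheme defaults to ε = n^{−1/2}; ties at ĝ = ε take
  the untrimmed branch.
- All-treated or all-control inputs raise errors rather than produce NaN.

## First-step networks

Two separate multilayer perceptrons (no parameter sharing):

- outcome: ŷ = β₀ + β·A + Wα + H(W)Γ_Y with squared-error loss. The
  treatment enters the output layer linearly, so Q̂¹−Q̂⁰ is constant
  (partially linear). `a_in_features=True` appends A to the inputs instead,
  permitting heterogeneous surfaces.
- propensity: logit ĝ = β₀′ + Wα′ + H′(W)Γ_A with Bernoulli log-loss.

Both have ReLU hidden layers (default: three layers as wide as the input),
a direct linear skip path Wα from the standardized inputs to the output,
and an L1 penalty C·Σ|ω| over connection weights (biases unpenalized).
Optimization is Adam with β₁ = 0.95 (the "momentum" convention), β₂ = 0.999,
learning rate 0.01, batch size 3p, 200 epochs, fully deterministic given the
seed. The objective is the *mean* data loss plus C·Σ|ω| — the scale at
which the hyperparameter grid of interest {0.01, 0.1} visibly tempers
extreme propensity predictions; weighting the penalty against a summed loss
would make it inert at these C values for n in the thousands. Covariates
are standardized to zero mean/unit variance internally, using training-fold
statistics only under cross-fitting. The networks are implemented directly
on numpy with explicit backpropagation, keeping the dependency surface
small and the arithmetic reproducible.

L2 and dropout are deliberately absent; L1 is the regularizer under study.
There is no early stopping or GPU path.

Cross-fitting (`crossfit_nuisance`) partitions units into K folds (default
K = 5) by a seeded shuffle and predicts each unit from networks trained on
the other K−1 folds; every unit gets exactly one out-of-fold prediction and
`fold_id` records provenance. A training split with an empty treatment arm
raises an error suggesting fewer folds.

## Synthetic design

Four independent covariate blocks — confounders X_c, instruments X_iv,
outcome predictors X_y, noise X_irr — each MVN(0, Σ) with AR(1) correlation
Σ_{kj} = ρ^{|j−k|}, ρ = 0.5. Treatment and outcome:

    A ~ Ber(expit(η)),  η = f_a(X_c)γ_c + g_a(X_iv)γ_iv
    Y = 3 + A + f_y(X_c)γ′_c + g_y(X_y)γ_y + ε,  ε ~ N(0, 1)

so the true ATE is exactly 1. Each structural function selects
⌈0.2·block_size⌉ columns of its designated block by a seeded draw, pairs
them consecutively (an odd leftover pairs with the first selected column),
and applies a transform drawn uniformly from:

    l1 = exp(x1·x2)/2        l2 = x1/(1+exp(x2))     l3 = x1·x2/10 + 2/3
    l4 = (x1+x2+3)/2         l5 = g(x1)·h(x2)

with the step functions g(x) = −2·I(x≤−1) − I(−1<x≤0) + I(0<x<2) + 3·I(x≥2)
and h(x) = −5·I(x≤0) − 2·I(0<x<1) + 3·I(x≥1) (boundary overlaps in common
write-ups of these steps are resolved to half-open intervals, the higher
interval winning; an indicator pair I(x≥0), I(x≥1) is selectable). l1's
exponent is clipped at 10 for overflow safety (<1e-4 of draws at ρ=0.5).
All structural coefficients default to the constant 0.25; genuine uniform
ranges are configurable. Defaults n=750, block_size=8 (p=32) correspond to
the small benchmark scenario; the large one (n=7500, p=300) is reachable by
configuration.

The generator emulates instrument-driven positivity violation (inflating
γ_iv pushes propensities to the tails) and nonlinear confounding. It does
not emulate survey designs, covariate missingness, heteroscedastic or
heavy-tailed outcome noise, or treatment-effect heterogeneity (the effect is
additive and constant by construction) — so passing tests demonstrate
estimator behaviour under the stated structure, not robustness to those
real-data features.

## Monte Carlo harness

`run_mc` freezes one simulated world (structural plans drawn once from the
DGP seed), redraws data per replicate with seed+j, obtains nuisance
estimates (oracle / in-sample networks / cross-fitted networks) and
summarizes each estimator by

    bias δ̂ = β − μ̂,   MCstd σ̂_MC = sqrt((1/m)Σ(β̂ⱼ−μ̂)²),   RMSE = sqrt(σ̂²_MC + δ̂²),

(1/m variance convention, so RMSE² = bias² + MCstd² identically) plus the
mean asymptotic SE. Replicate failures are logged and excluded; >20%
failures aborts. Reported summaries additionally cap estimates at ±10
(`capped_mean`); raw estimates are never capped.

The orthogonality check computes the central-difference Gateaux derivative
of the empirical nAIPW estimating function along a user-supplied nuisance
direction (step h = 1e-3). Perturbation components at propensities pinned
to the numerical floor are dropped, and the direction is rescaled only by
the minimal factor needed to keep g inside (0,1). The remainder probe
evaluates the sample Hölder bound rms(g/ĝ−1)·rms(Q¹−Q̂¹) + (control arm
analogue) across a grid of n.

## Test-scale choices

The statistical test suite runs at desk scale: oracle-nuisance studies use
n=2000 with 200–500 replicates; double-robustness checks use n ∈ {500,
5000}; the network-based dispersion comparison uses 10 batches × 30
replicates at n=750, p=32 with 30-epoch networks and 5-fold cross-fitting.
These sizes give Monte Carlo standard errors small enough for the stated
3-SE and ordering assertions while keeping the full suite in the minutes
range. The large-grid benchmark (p=300, n=7500, 200-epoch networks over a
hyperparameter lattice) is reachable through the same API but is
cluster-scale work, not part of the test suite.

## Known limitations

- The asymptotic variance estimators are consistent only under the rate and
  cross-fitting conditions; with weakly regularized in-sample networks they
  can badly understate the true sampling dispersion (the harness makes this
  measurable rather than hiding it).
- The trimmed hybrid scheme is implemented as specified but its theory is
  conjectural; it is exposed as `gdr_trimmed` for experimentation.
- m-out-of-n subsampling variance estimation and targeted-learning (TMLE)
  variants are out of scope.
- The numpy networks are CPU-only and intended for the moderate n, p of the
  benchmark design, not for large-scale image/text-style workloads.
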