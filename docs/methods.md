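# Methods

## Model

Yearly crop production per municipality is modelled as a Poisson count with
the previous year's observed production as a multiplicative offset, so the
modelled quantity is a rate of change rather than a level:

    y_it ~ Poisson(ρ_it · ε_it),   ε_it = y_{i,t-1}
    log(ρ_it) = α + γ_i + δ_t + β x_it

* `γ_i` — exchangeable municipality effects, iid `N(0, τ_γ⁻¹)`.
* `δ_t` — yearly effects under a first-order random-walk (RW1) prior:
  increments `δ_t − δ_{t-1}` iid `N(0, τ_δ⁻¹)`. The RW1 density is improper
  (invariant to a level shift); identifiability is restored by constraining
  `Σ_t δ_t = 0` while `α` stays free and `γ` is left unconstrained under its
  proper shrinkage prior. Every component (generator, likelihood, both
  inference engines) shares this one convention.
* `β` — the effect of a single environmental covariate in its original
  units, because effects are reported per °C, per kPa, etc. Covariates are
  never standardized.
* One covariate per fit. Climate variables are strongly collinear;
  single-covariate designs trade omitted-variable bias for interpretable,
  stable marginal effects, and the sweep fits every (crop, covariate) pair
  separately.

Priors: `α, β ~ N(0, 1/0.001)` (sd ≈ 31.6 on the log scale — effectively
flat but proper; the model is silent about fixed effects so a weak default
is used). `τ_γ, τ_δ ~ Gamma(shape 1, rate 5·10⁻⁵)`, the standard
weakly-informative default for log-precision hyperpriors. A printed
shape of 0 sometimes quoted for this default describes an improper density;
shape 1 is the proper default actually implemented by mainstream
latent-Gaussian software, and is what `PriorConfig` adopts.

Production in tons is treated as a count. Fractional inputs are rounded
half-to-even on ingestion with a warning. Rows whose offset is zero are
dropped rather than pseudo-counted: a municipality that produced nothing in
year t−1 has no defined rate of change for year t. Consecutive calendar
years only are paired; a gap breaks the chain.

## Synthetic data

The generator draws from exactly the model above, recursively:
`y_{i,1} = round(LogNormal(log 5000, 1))`, then each later year is a Poisson
draw around the previous observation times `exp(η_it)`. Because the offset
is the *observed* previous value, a chain that hits zero stays at zero — the
generator never resurrects it, and the design builder drops those rows just
as it would for real non-producing municipality-years. The baseline level
log 5000 makes extinction negligible at the default effect scales while
keeping counts in a realistic tons-per-municipality range.

The monthly climate process is mean + per-municipality offset + linear
yearly trend + sinusoidal seasonality + Gaussian noise. Its only structural
role is to give the covariate variance both across municipalities and across
years within municipality, so `β` is identified; it does not attempt to
match the marginal distributions, spatial correlation, or extremes of real
gridded climate data. Consequently the recovery studies validate the
*inference machinery*, not robustness to real-data pathologies (measurement
error, spatially correlated shocks, regime changes).

Default study conditions (also used by the recovery studies): 150
municipalities, 14 years, α = 0.05, β = 0.025, sd(γ) = 0.3, RW innovation
sd = 0.1, covariate mean 25 °C with 0.05 °C/yr trend and unit monthly noise.
A side effect of the recursive design worth knowing: multiplicative growth
compounds over 14 years, so municipalities in the upper γ tail can reach
astronomically large counts. This is faithful to the stated generative
process and stresses the inference code's numerics deliberately.

## Climate features

Monthly variables collapse to yearly covariates as: yearly **minimum** of
monthly minimum temperature, yearly **maximum** of monthly maximum
temperature, yearly **mean** of everything else. Average temperature is the
yearly mean of the monthly midpoint (tmin + tmax)/2 — the standard
climatological midpoint, chosen because gridded products typically carry no
separate mean-temperature layer. Aggregation is calendar-year (Jan–Dec)
with no crop-calendar alignment. Partial years are averaged over available
months and flagged (`complete = False`), never imputed; a variable wholly
absent for a municipality-year yields a missing cell, never a silent zero.
NetCDF rasters are sampled at municipality centroids (nearest grid cell);
no areal averaging or reprojection.

The descriptive trend smoother fits OLS polynomials of degree 1–4 and keeps
the AIC minimizer, `AIC = n ln(RSS/n) + 2(d+2)`. Note AIC's known behavior:
with probability ≈ P(χ²₁ > 2) ≈ 0.16 it accepts one superfluous degree, so
"the right degree" is selected in most but not all noisy replicates. Fits
use a centered/scaled abscissa internally for conditioning; coefficients are
returned in original units.

## MCMC engine

Metropolis-within-Gibbs, fully seeded (`SeedSequence([seed, chain])` per
chain). Per stored draw the kernel applies two full sweeps of:

1. adaptive random-walk Metropolis on `α` and on `β` (target acceptance
   0.44);
2. simultaneous single-site Metropolis on all `γ_i` (they are conditionally
   independent, so all sites propose and accept/reject in parallel with
   per-site adapted scales);
3. five block updates of `δ`: Gaussian proposal preconditioned by the
   per-year curvature (Poisson info + RW1 diagonal), projected onto the
   sum-to-zero subspace, target acceptance 0.234;
4. an **exact Gibbs draw of the (α, γ) translation coordinate**
   (`α → α + e`, `γ → γ − e`): the likelihood is invariant along this
   direction and the conditional distribution of `e` is Gaussian in closed
   form. This replaces a deterministic "recentering" of γ — a non-stochastic
   recentering perturbs the joint posterior (it visibly biases the τ_γ
   marginal on small instances), whereas the Gibbs translation is exact and
   mixes the same direction;
5. three Metropolis moves along the **β ridge** — the direction
   `(β, α, γ, δ)` in which the other location parameters follow their
   conditional means as β changes, taken from the inverse Hessian of a
   pre-fit (below). Along this ridge the likelihood resistance equals β's
   marginal precision, so steps of one marginal sd are acceptable; across
   it, β is pinned to ~10⁻⁶ by the huge counts. One additional
   *independence* Metropolis proposal on the same ridge draws β directly
   from the frozen pre-fit Gaussian (Hastings-corrected), which makes the
   β draws nearly independent;
6. exact conjugate Gibbs draws `τ_γ ~ Gamma(a + N/2, b + Σγ²/2)` and
   `τ_δ ~ Gamma(a + (T−1)/2, b + Σ(Δδ)²/2)`.

Proposal scales adapt by Robbins–Monro on the log scale **during warmup
only** and are frozen afterwards, as is the δ preconditioner and the
independence-proposal parameters, so the post-warmup kernel is a fixed,
exactly invariant MCMC kernel.

Initialization: one Newton optimization of the penalized log-posterior at
fixed precisions (τ = 10) provides the mode and curvature; each chain starts
at that mode plus overdispersed Gaussian jitter (`2 · init_jitter_sd`
approximate posterior sds per coordinate) and proposal scales start at 2.4×
the approximate sds. If the pre-fit fails, a crude rate-based init with
fixed jitter is used. Non-finite initial states re-jitter up to 20 times,
then fail loudly.

Summaries pool draws across chains (linear-interpolation quantiles);
split-R̂ and rank-based bulk ESS come from arviz. With a single chain, R̂ is
reported as NaN (unavailable), never 1.0.

## Laplace cross-check

An independent engine in the spirit of deterministic latent-Gaussian
approximations: damped Newton maximization of the penalized log-posterior of
(α, β, γ, δ) at fixed precisions — δ parameterized in an orthonormal
sum-to-zero basis — with the precision pair chosen by Nelder–Mead on the
Laplace approximation to its marginal posterior. Posterior sds are the
square roots of the inverse negative-Hessian diagonal. Agreement between
the two engines (mode vs posterior mean within fractions of an sd) is the
package's correctness argument for the inference, since they share no code
path beyond the model definition.

Numerical details: the Newton gradient-norm tolerance is
`max(1e-8, 1e-14 · Σy)` — on panels whose total count reaches 10¹¹ the score
cannot be driven below the float64 resolution of the objective, and the
line search treats objective differences below `1e-9·|f|` as noise. The
backtracking line search halves up to 60 times; non-convergence raises with
the last gradient norm.

## Problem sizes and runtime choices

The recovery studies use the default study conditions above (150 × 14, four
chains of 1000 warmup + 1000 kept draws), 20 replicates per study; the
engine cross-check uses 20 × 5 with 10 replicates; the precision-update
distributional check uses 10,000 draws; the griddled-posterior oracle for
τ_γ uses a 3-municipality instance where the marginal is computable by
nested 1-d quadrature, with 50,000 draws. These sizes make the whole
validation suite run in minutes on one CPU while keeping every Monte-Carlo
tolerance comfortably resolvable.

## Known limitations

* No overdispersion, zero-inflation, or spatially structured (CAR/BYM)
  municipality effect — γ is iid by design.
* Single-covariate fits cannot separate effects of collinear climate
  variables; the sweep makes no multiple-comparison adjustment across its
  55 fits (noted in the run manifest).
* Zero-offset rows are dropped, which conditions on survival; a municipality
  repeatedly entering and leaving production contributes only its
  within-run transitions.
* The Laplace marginal optimization treats the precisions as a point
  estimate; its sds are conditional on those precisions and mildly
  understate total uncertainty relative to MCMC.
* Synthetic climate is not real climate: passing recovery tests demonstrate
  correct inference under the stated model, not robustness to model
  misspecification.
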