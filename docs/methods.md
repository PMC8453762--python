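# Methods

## Trait-integrated multispecies functional response

The predator population's quantitative trait x is Gaussian with mean x̄
and variance σ² (trait units²). Foraging on prey *i* is governed by two
kernels centred on the prey-specific optimum X_opt,i:

* attack rate α_i(x) = α_max · exp(−(x − X_opt,i)² / (2 τ_α²)) — maximal
  at the optimum;
* handling time η_i(x) = η_min · exp((x − X_opt,i)² / (2 τ_η²)) —
  minimal at the optimum and inflating away from it.

Only the extrema at the optimum are biologically prescribed; the
Gaussian / inverse-Gaussian forms are our choice — smooth, positive,
symmetric, and standard in trait-matching models. They sit behind a
small kernel protocol (`__call__`, optional `log_at`), so alternative
shapes (e.g. quadratic inflation) can be substituted without touching
the integrator.

The mean intake on prey *i* integrates the multispecies type II
response — numerator α_i R_i C, denominator 1 + Σ_j α_j η_j R_j shared
across the diet — against the trait density. All quantities are in
dimensionless simulation units; nothing checks units.

**Quadrature.** The default route is Gauss–Hermite in the standardized
variable (the natural rule under a Gaussian weight), 64 nodes, which is
exact for polynomial integrands of degree ≤ 127. Because the
denominator can vary on a scale much narrower than the trait
distribution (small kernel widths, large σ²), the default `auto` method
self-checks by doubling the node count; if the two estimates disagree
beyond max(10⁻⁹, 10⁻⁶·|f|) it falls back to adaptive quadrature on
[x̄ − 8σ, x̄ + 8σ]. The α·η product in the denominator is formed from
summed log-kernels: far from an optimum α underflows while η overflows,
and the naive product is NaN even though the response there is simply
zero.

**Degenerate limit.** σ² ≤ 10⁻¹² is treated as a point mass: the
bracketed response is evaluated directly at x̄, avoiding a zero-width
Gaussian. The quadrature route converges to this limit as σ² → 0
(relative error ∝ σ²), which the tests verify.

## Rewiring metrics

A link "exists" when its intake exceeds a threshold ε. No absolute
threshold is biologically given, so the default is relative: 10⁻³ × the
maximum intake of the profile at the smallest σ² in a sweep. This makes
the cutoff scale-free in densities and kernel amplitudes, and it is
recorded in every sweep row. Turnover between two scenarios is the
Jaccard complement 1 − |retained|/|union| over link sets (0 for an
empty union).

**Reference fixture.** Ten prey with equal densities, shared kernel
parameters (α_max = η_min = τ_α = τ_η = 1) and mismatch evenly spaced
on [0, 25]. The span is chosen so the most-mismatched prey sit below
the relative threshold when σ² ≈ 0 — the specialist regime — while a
variance of σ² = 7 links the whole diet: the fixture straddles the
fewer-but-stronger / more-but-weaker transition that the variance sweep
quantifies. The monotonicity of link count (nondecreasing in σ²) and
maximum strength (nonincreasing) is asserted on this fixture only;
arbitrary communities need not be monotone.

## Temperature-dependent consumer–resource model

Per-capita dynamics (1/R)dR/dt = r − (r/K)R − aC and
(1/C)dC/dt = eaR − m. The coexistence equilibrium is closed-form,
R\* = m/(ea) and C\* = (r/a)(1 − R\*/K), feasible iff R\* < K. The
Jacobian at the feasible equilibrium is analytic,

    J = [[ −rR*/K,  −aR* ], [ eaC*,  0 ]],

with trace −rR\*/K < 0 and determinant eaR\*·aC\* > 0, so every
feasible coexistence equilibrium of this model is locally stable;
resilience is −Re(λ_max), the asymptotic return rate from small
perturbations. (The reciprocal return time 1/resilience carries the
same ordering near equilibrium; we report −Re(λ_max) as primary.)

**Reaction norms.** Each demographic parameter is a function of
temperature anchored at T_ref = 15 °C. Linear norms encode the
G/E/G×E construction: genotypes sharing the value at 15 °C differ only
in thermal sensitivity, so intercept spread is G, the mean slope is E,
and slope spread is G×E. The resource's growth rate defaults to a
quadratic peak, v(T) = v_ref + c·[(T − T_peak)² − (T_ref − T_peak)²]
with c = −0.0015 and T_peak = 25 °C — rising then falling with
temperature, positive over the declared 0–40 °C range (r(0) ≈ 0.21,
r(25) = 1.15, r(40) ≈ 0.81). K defaults flat: no established thermal
response to encode. Linear norms inevitably cross zero somewhere;
evaluations are floored at 10⁻⁶ (configurable) with a recorded warning
rather than an exception, keeping temperature sweeps total while
flagging biological invalidity.

**Selection.** Evolution is resolved as competition among a discrete
genotype panel under ecological/evolutionary timescale separation: a
rare invader's fitness is its per-capita growth at the resident's
equilibrium, s = e′a′R\*_res − m′, whose sign equals
sign(R\*_res − R\*_inv). The favoured genotype is therefore the argmin
of R\* = m/(ea) — the R\* rule — and the implementation cross-checks
this against the full pairwise invasibility matrix. Ties with
|ΔR\*| < 10⁻⁹ set a neutrality flag and resolve to the
lexicographically smallest id for determinism. No genotype-frequency
dynamics are modelled.

**Crossing temperatures** (where two genotypes' R\* curves intersect,
i.e. the favoured genotype switches) are located by scanning ΔR\*(T) on
a 256-point grid and refining each sign change with Brent's method
(xtol 10⁻¹²). Identical genotypes give ΔR\* ≈ 0 everywhere and are
reported as having no isolated crossing.

**Integration.** Trajectories use an adaptive explicit Runge–Kutta
stepper (RK45, rtol 10⁻⁸, atol 10⁻¹⁰); densities are clipped at zero
inside the vector field so roundoff cannot drive them negative.

**Variance decomposition.** For one parameter on a complete
genotype × temperature grid, cells are the un-floored norm evaluations;
V_G is the population variance of genotype means, V_E of temperature
means, and V_G×E of the interaction residuals
(cell − row mean − column mean + grand mean). On a balanced grid these
are orthogonal and sum exactly to the total population variance.

## Synthetic fixtures

The generators draw from `numpy.random.Generator` (PCG64), so a seed
fully determines every fixture across platforms. Mismatch-graded
communities use deterministic even spacing (not random placement) so
the rewiring monotonicity assertions are stable; optional lognormal
density variation is seeded. Genotype panels draw intercepts
N(intercept, intercept_sd²) and slopes N(mean_slope, slope_sd²) per
parameter, truncate intercepts at the parameter floor (logged) rather
than resampling, and return the planted variance components in closed
form (for linear norms the interaction residual factors as
(s_g − s̄)(d_t − d̄), so V_G×E = Var(s)·Var(d)); recovery tests compare
these against the decomposition of the evaluated grid to 10⁻⁸.

Panel defaults emulate the two-genotype construction used throughout
the consumer model: identical phenotypes at 15 °C (no G), a positive
mean thermal slope for attack and mortality (E), differing slopes
(G×E), and a flat conversion efficiency. Default feasible-parameter
ranges (r ∈ [0.5, 2], K ∈ [5, 20], a ∈ [0.5, 2], e ∈ [0.2, 0.8],
m ∈ [0.1, 1]) describe a well-provisioned consumer–resource pair in
simulation units; rejection sampling enforces m/(ea) < K and aborts if
more than 99 % of draws fail.

## What the synthetic data does and does not show

The fixtures reproduce the *structure* the models assume — Gaussian
traits, smooth trait-matching kernels, linear thermal reaction norms,
balanced genotype × temperature designs. They contain no measurement
error, no unbalanced sampling, no correlations between parameters, and
no multi-trait or multi-resource complexity. Passing tests therefore
demonstrate the internal consistency of the models and their
implementation, not the empirical adequacy of either model for any real
food web.

## Problem sizes

The verification suite uses 100 seeded communities for the
degenerate-limit and Monte-Carlo checks (10⁶ draws each), 1,000
parameter draws for the equilibrium/stability properties, 1,000
5-genotype panels for the R\* rule, and a 31-point temperature grid for
sweep/crossing consistency — sizes at which each check's sampling error
is far below its assertion tolerance.

## Known limitations

* One consumer, one resource (or one predator, many independent prey
  densities); no dynamic prey depletion during intake evaluation, no
  multi-trophic assembly.
* No mechanistic (Boltzmann–Arrhenius) temperature dependence; reaction
  norms are phenomenological.
* Selection is among fixed genotypes; no mutation, no standing-variance
  dynamics, no genotype-frequency trajectories.
* Kernel parameters are shared across prey by default; per-prey widths
  are supported in the library API but not in the config schema.
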