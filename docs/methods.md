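# Methods

## The model

The package simulates a predator population feeding on two prey species, each
of which carries its own trophically transmitted parasite. Densities follow
Lotka–Volterra ecology; two quantitative traits of the predator evolve by the
Lande gradient equation.

State variables: predator density `P`, prey densities `N1, N2`, mean
ecomorphological (diet) trait `x̄`, mean immune trait `ȳ`. Individual-level
rates:

- attack rate on prey *i*: `a_i(x) = α_i exp(−(x−θ_i)² / 2ζ_i²)` — a Gaussian
  kernel with optimum `θ_i` and width `ζ_i`. Small `ζ_i` means a strong
  foraging trade-off: only near-specialists capture prey *i* efficiently.
- susceptibility to parasite *i*: `S_i(y) = β_i − (β_i−γ_i) exp(−(y−φ_i)² /
  2τ_i²)` — an inverted Gaussian with minimum `γ_i` at the immune optimum
  `φ_i`, saturating at `β_i`. Small `τ_i` means a strong immune trade-off.
  Immunity is constitutive (always expressed); there is no induced response.

A fraction `c_i` of prey *i* is infected; an ingested parasite reduces
predator fecundity by up to `m_i`, scaled by susceptibility. The two traits
are genetically independent and normally distributed with fixed phenotypic
variances `σ_x², σ_y²`, of which `σ_{x,G}², σ_{y,G}²` are genetic. Averaging
the kernels over these normal distributions has a closed form (a Gaussian
kernel convolved with a normal is again Gaussian with width inflated from
`ζ²` to `σ² + ζ²`), giving the population-level rates `ā_i(x̄)`, `S̄_i(ȳ)`
and the mean predator growth rate

    W̄ = Σ_i (b_i − c_i m_i S̄_i(ȳ)) ā_i(x̄) N_i − d.

The full five-dimensional system couples `dP/dt = P W̄`, logistic prey growth
minus predation, and trait dynamics `dx̄/dt = σ_{x,G}² ∂W̄/∂x̄`,
`dȳ/dt = σ_{y,G}² ∂W̄/∂ȳ`. Both gradients are implemented in closed form
and verified against finite differences of `W̄`; the 5×5 Jacobian is analytic
(with a finite-difference cross-check in the tests) because Lyapunov
estimation integrates the variational equations along it.

## Trade-off classification

For equal prey contributions, `W̄` as a function of one trait is an
equal-weight mixture of two Gaussians with common effective width
`s = √(σ² + w²)` (`w` = kernel width). Such a mixture is unimodal exactly
when the separation of the optima is below `2s`; the package classifies a
trade-off as *weak* when `|θ_1−θ_2| < 2√(σ_x²+ζ²)` (and analogously for the
immune trait). The brute-force grid-scan oracle in the acceptance suite
sweeps widths across this threshold and confirms the classification on both
traits. When the two prey have unequal kernel widths — a case the theory
does not cover exactly — the condition is evaluated at each width and
summarised conservatively (weak only if it holds at both), with a warning.

## Two-timescale reduction

With small genetic variances the densities equilibrate while the traits
barely move. The frozen-trait ecological subsystem is Lotka–Volterra with
logistic prey and a linear functional response; it admits a diagonal
Lyapunov function, so its attractor is always an equilibrium — one of
coexistence, predator exclusion, or single-prey exclusion, all available in
closed form. Attractor selection uses feasibility (all required densities
positive) plus uninvadability (every absent species has negative invasion
growth); this picks a unique candidate away from measure-zero parameter
boundaries. Degenerate cases fall back to direct simulation of the 3-D
subsystem and nearest-candidate matching. When the fast attractor is a
boundary equilibrium, the reduced trait dynamics use its densities with the
excluded species at exactly zero.

The reduced system evaluates the Lande gradients at the attractor densities
`N_i*(x̄, ȳ)`. The phase-portrait toolkit finds its equilibria by multi-start
root finding (21×21 seed grid over the niche box expanded 20%, duplicates
merged within 1e−6), classifies them by the eigenvalues of a central
finite-difference 2×2 Jacobian (|Re λ| < 1e−8 flagged degenerate — this also
absorbs spurious flat-tail roots where a strong trade-off kernel underflows),
traces nullclines by marching squares on a trait grid, and computes
separatrices by backward integration from `saddle ± ε·v_stable` with
`ε = 1e−6`.

One geometric subtlety: even for a fully symmetric community the diet
nullcline is *not* exactly the vertical midline. Off the symmetry axis the
immune state makes the two prey unequally valuable (`S̄_1 ≠ S̄_2`), bending
the nullcline by a few thousandths of a trait unit. The symmetry that does
hold exactly is the point reflection `(x̄,ȳ,N_1,N_2) → (−x̄,−ȳ,N_2,N_1)`,
which the tests verify at machine precision on trajectories.

## Numerical integration

Trajectories use adaptive Runge–Kutta 4(5) with `rtol = 1e−8`,
`atol = 1e−10` by default. Densities are integrated raw (no log transform,
so exact extinction is representable); when one crosses the extinction
threshold (default 1e−12) from above, integration stops at the event, the
population is clamped to exactly zero — the boundary faces are invariant —
and integration restarts, with the event logged in the trajectory.

The ecological-subsystem oracle (used to validate attractor selection)
integrates into the attractor's basin, then polishes with a Newton solve on
the 3-D vector field; the polished root is accepted only if it is close to
the trajectory endpoint, non-negative, and linearly stable (a slow transit
past a saddle can otherwise trigger the residual test prematurely). If the
polish is rejected the integration continues to a strict residual bound.

## Lyapunov exponents

The maximal exponent is estimated with a single tangent vector propagated by
the variational equations (analytic Jacobian) and renormalised every 1 time
unit; the exponent is the time average of the log stretch factors after a
discarded transient. Defaults are 500 time units of transient and 5000 of
accumulation; the regime-structure checks in the acceptance suite use 300 /
1500, which the convergence diagnostic (drift of the running estimate over
its last quartile below `max(5%·|λ|, 0.005)`) accepts in all reported cells.
At a stable equilibrium the estimate converges to the leading eigenvalue's
real part; with a complex leading pair the running estimate oscillates with
amplitude `O(1/T)`, so the validation at random stable equilibria adapts the
horizon to `max(400, 50/|Re λ₁|)` and seeds the tangent with the leading
eigenvector.

## Parameter sets

Supplementary baseline tables were not available, so the package defines and
documents its own:

- **Symmetric baseline** (`default_community`): two mirror-image prey,
  `r = K = 1`, `α = 2`, `θ = φ = ±1/2`, `b = 1`, `c = m = 1/2`, `β = 1`,
  `γ = 0.1`, predator `d = 0.1`, `σ_x² = σ_y² = 0.01`, heritability 1/2 for
  both traits. The predator persists on either prey alone in all four
  trade-off regimes, and widths 0.01 / 1 classify as strong / weak under the
  unimodality conditions. Quantities like `σ_{x,G} = 0.005` are interpreted
  as genetic *variances* (the quantity that multiplies the gradient in the
  Lande equation); a switch treats them as standard deviations instead.
- **Timescale-asymmetry fixtures** give one trait genetic variance 0.005 and
  the other 0.25. A genetic variance above the baseline phenotypic variance
  forces that trait's phenotypic variance up to match (variance components
  must nest), implying heritability 1 for the fast trait; this preserves the
  intended rate asymmetry, which is what these fixtures exemplify.
- **Chaotic reference regime** (`chaos_reference_community`): the symmetric
  baseline family contains no cyclic or chaotic attractors anywhere in the
  (τ, h_y²) plane — all lifted trait equilibria are linearly stable — so a
  distinct regime was located by a systematic eigenvalue survey followed by
  Lyapunov confirmation: `r = 0.9`, `K = 4`, `α = 9`, `ζ = 0.25`, `b = 0.7`,
  `c = 0.9`, `m = 0.65`, `γ = 0.13`, `d = 0.3`, `σ_x² = 0.1`,
  `σ_{x,G}² = 0.065`, `σ_y² = 0.5`. High productivity keeps prey far below
  carrying capacity, making the predator–prey interaction weakly damped, and
  the prevalent, virulent parasites give the fast-evolving immune trait real
  leverage on prey value. The regime structure mirrors the model's headline
  claim: for `τ ≤ 0.2` every exponent is negative at all heritabilities;
  from `τ ≈ 0.3` the equilibria destabilise, with the exemplar cell
  (`τ = 0.3`, `h_y² = 0.9`) at `λ ≈ +0.026`. The boundary's exact location
  is parameter-set dependent and is not asserted anywhere, only the signs.

## Latin-hypercube studies

Each study fixes one trade-off quadrant `(ζ, τ)` and draws `n` parameter
sets by Latin-hypercube sampling (one sample per equal-probability stratum
per dimension, reproducible from a seed): carrying-capacity ratio `K1/K2 ∈
[1/4, 4]` on a log scale with the geometric mean preserved, attack rates
`α_i ∈ [1, 4]`, prevalences and virulences `c_i, m_i ∈ [0.05, 0.95]`, growth
rates `r_i ∈ [0.5, 2]`, and initial traits across the niche interval plus a
0.25 margin; prey parameters vary independently per prey. Per draw the
reduced system runs until the trait speed drops below 1e−8 (horizon 1e6,
cycling draws flagged unconverged), and the record keeps the trait
equilibrium, attractor kind and densities, and the relative intake, exposure
and infection shares. The full design size is 4000 draws; the shipped
acceptance checks use 200 per quadrant, which is ample for the regime-level
contrasts they assert (all margins are a factor of two or more).

What the generator does *not* emulate: demographic stochasticity, spatial
structure, dynamic parasite prevalence (infection fractions are constants),
genetic covariance between the traits, and within-population variance
evolution. Passing tests therefore speak to the deterministic
constant-prevalence model, not to data from finite, structured populations.

## Interpreting the quadrant statistics

With strong foraging trade-offs the evolved diets are pure specialists, so
intake, exposure and infection shares all sit at 0 or 1 and the 1:1
intake–infection relationship is exact. With weak foraging trade-offs the
endpoints spread across the niche axis — a central generalist mass (absent
entirely in the strong-foraging quadrants) plus boundary specialists created
by apparent-competition exclusion under strongly asymmetric draws. The
compatibility filter's contribution is isolated as the mean absolute gap
between infection and exposure shares: with a strong immune trade-off the
phenotypic variance flattens the susceptibility dip, making the filter nearly
neutral (gap ≲ 0.007 at baseline); with a weak trade-off the evolved
immunity bends infection away from exposure (gap ≈ 0.08), and recomputing
the shares with a common susceptibility removes the distortion to rounding
error. Restricting any quadrant to coexistence draws leaves the sign of the
mean intake–infection deviation unchanged.

## Known limitations

- Attractor selection assumes the fast subsystem's attractor is an
  equilibrium; this is proven for the linear-response Lotka–Volterra
  structure used here but would not survive a saturating functional
  response.
- Near regime boundaries (invasion growth ≈ 0) the ecological relaxation
  time diverges; the simulation oracle skips draws that fail to settle
  rather than reporting an unconverged comparison.
- The Lyapunov estimator reports the maximal exponent only; no spectrum, no
  attractor dimension, and no rigorous (computer-assisted) chaos proof.
- Trait-equilibrium search is grid-seeded; equilibria far outside the niche
  box, or distinct equilibria closer than the merge tolerance, would be
  missed or merged.
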