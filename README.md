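# eei — eco-evo-immuno dynamics of predators and their trophically acquired parasites

When a predator eats, it inherits its prey's parasites. A predator
population's diet (set by an ecomorphological trait such as gill-raker or
gape morphology in stickleback) therefore controls which parasites it is
*exposed* to, while its immune traits control which exposures become
*infections*. Because both filters feed back on fitness through the same
prey, diet and immunity evolve jointly even when they are genetically
independent. `eei` is a simulator and analysis toolkit for the minimal model
of this feedback: one predator with two evolving quantitative traits, two
prey species, and one parasite per prey.

## The model

Densities follow Lotka–Volterra ecology; trait means follow the Lande
equation:

    dP/dt  = P · W̄(x̄, ȳ, N₁, N₂)
    dNᵢ/dt = Nᵢ · [ rᵢ(1 − Nᵢ/Kᵢ) − āᵢ(x̄) P ]
    dx̄/dt  = σ²x,G · ∂W̄/∂x̄
    dȳ/dt  = σ²y,G · ∂W̄/∂ȳ

with `W̄ = Σᵢ (bᵢ − cᵢ mᵢ S̄ᵢ(ȳ)) āᵢ(x̄) Nᵢ − d`. The attack rate
`āᵢ(x̄)` is a Gaussian kernel of the diet trait around prey *i*'s optimum θᵢ
(width ζᵢ: small = strong foraging trade-off); susceptibility `S̄ᵢ(ȳ)` is an
inverted Gaussian of the immune trait around φᵢ (width τᵢ); both are
averaged in closed form over the population's normal trait distributions.

The package provides:

- `eei.dynamics` — the full 5-D system with analytic Jacobian, adaptive
  RK45 integration and an exact extinction clamp;
- `eei.reduction` — the slow-evolution limit: closed-form ecological
  equilibria with feasibility/invasion flags, attractor selection, the
  reduced 2-D trait flow, and a phase-portrait toolkit (equilibria,
  nullclines, separatrices);
- `eei.chaos` — maximal Lyapunov exponents (tangent-vector method), chaos
  maps over (immune heritability × trade-off width), and extrema diagrams;
- `eei.lhs` — seeded Latin-hypercube parameter studies of the relative
  intake / exposure / infection shares at evolutionary equilibrium;
- `eei.config` / `eei.cli` — TOML/JSON parameter files, named regime
  fixtures, and the `eei` command-line tool.

## A worked example

Weak trade-offs in both traits (ζ = τ = 1) on the symmetric baseline: the
predator evolves a generalist diet and generalist immunity, and the ecology
settles at coexistence.

```python
from eei import default_community, select_attractor, find_trait_equilibria

com = default_community(zeta=1.0, tau=1.0)
eq = select_attractor(0.0, 0.0, com)          # ecology at the trait midpoint
print(eq.kind, round(eq.P_star, 4), round(eq.N1_star, 4))
for te in find_trait_equilibria(com):
    print(te.stability, round(te.xbar_star, 4), round(te.ybar_star, 4))
```

prints

```
coexistence 0.5516 0.03
stable -0.0 -0.0
```

— predator density 0.5516 with both prey suppressed to 0.03 of their unit
carrying capacity, and a single stable evolutionary equilibrium at the niche
midpoint (0, 0): a generalist in both traits. Rerun with `zeta=0.01,
tau=0.01` and the stable equilibria move to (±0.5, ±0.5): diet specialists
whose immunity matches their diet.

The chaotic reference regime shows the other face of the model — with a weak
immune trade-off and highly heritable immunity, the eco-evolutionary feedback
destabilises the community:

```python
from eei import chaos_reference_community, lyapunov_exponent, LyapunovConfig
from eei.chaos import perturbed_coexistence_state

com = chaos_reference_community(tau=0.3, h_y2=0.9)
res = lyapunov_exponent(com, perturbed_coexistence_state(com),
                        LyapunovConfig(transient=300, total_time=1500))
print(round(res.exponent, 4), res.converged)
```

prints `0.0247 True` — a positive maximal Lyapunov exponent (chaos). The
same community with a strong immune trade-off (`tau=0.01`) gives a negative
exponent at every heritability.

The same analyses are available from the shell, e.g.

```sh
eei fixtures --out fixtures/
eei simulate --config fixtures/chaos_exemplar.toml --t-end 2000 --out traj.csv
eei lhs --config fixtures/weak_foraging_strong_immune.toml \
    --zeta 1.0 --tau 0.01 --n 4000 --seed 42 --out study.csv
```

(config files are either full run configs or bare community parameter files;
every command writes a JSON manifest sufficient to rerun it).

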