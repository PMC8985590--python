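"""Randomised consistency checks and regime-level study summaries.

These routines quantify how well the closed forms, the analytic gradients, the
two-timescale reduction and the Lyapunov estimator agree with their
independent counterparts (numerical quadrature, finite differences, direct
simulation, Jacobian eigenvalues), and compute the headline regime statistics
of the Latin-hypercube studies.  They are used both by the test suite and by
the reproduction script.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

from . import lhs as lhs_mod
from .chaos import LyapunovConfig, lyapunov_exponent, perturbed_coexistence_state
from .config import default_community, fixture_regimes
from .core import (
    attack_rate,
    mean_attack_rate,
    mean_fitness,
    mean_susceptibility,
    selection_gradients,
    susceptibility,
)
from .dynamics import SolverConfig, jacobian_full, simulate_full
from .params import Community, FullState, random_community
from .reduction import (
    ecological_equilibria,
    find_trait_equilibria,
    select_attractor,
    simulate_ecology,
    simulate_reduced,
)

__all__ = [
    "quadrature_equivalence_error",
    "gradient_fd_error",
    "unimodality_agreement",
    "slow_manifold_errors",
    "attractor_agreement",
    "stable_equilibrium_draws",
    "lyapunov_eigenvalue_error",
    "chaos_regime_exponents",
    "lhs_quadrant_study",
    "intake_infection_deviation",
    "specialist_generalist_stats",
]


# ---------------------------------------------------------------------------
# closed forms versus quadrature / finite differences
# ---------------------------------------------------------------------------

def quadrature_equivalence_error(n_draws: int = 100, seed: int = 0) -> float:
    """Max |closed form - quadrature| for abar and Sbar over random draws.

    Averages the individual kernels against the normal phenotype density by
    adaptive quadrature and compares with the closed-form phenotype means.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        com = random_community(rng)
        prey = com.prey[int(rng.integers(2))]
        xbar = rng.uniform(-1.5, 1.5)
        sx2 = com.predator.sigma_x2
        sy2 = com.predator.sigma_y2
        qa, _ = quad(
            lambda x: attack_rate(x, prey) * norm.pdf(x, xbar, math.sqrt(sx2)),
            -np.inf, np.inf, epsabs=1e-12, epsrel=1e-12,
        )
        qs, _ = quad(
            lambda y: susceptibility(y, prey) * norm.pdf(y, xbar, math.sqrt(sy2)),
            -np.inf, np.inf, epsabs=1e-12, epsrel=1e-12,
        )
        worst = max(
            worst,
            abs(qa - mean_attack_rate(xbar, sx2, prey)),
            abs(qs - mean_susceptibility(xbar, sy2, prey)),
        )
    return worst


def gradient_fd_error(n_draws: int = 100, seed: int = 1,
                      step: float = 1e-5) -> float:
    """Max relative error of the analytic selection gradients versus central
    finite differences of the mean fitness, over random communities/states."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        com = random_community(rng)
        xbar = rng.uniform(-1.2, 1.2)
        ybar = rng.uniform(-1.2, 1.2)
        N1 = rng.uniform(0.05, 2.0)
        N2 = rng.uniform(0.05, 2.0)
        g = np.asarray(selection_gradients(xbar, ybar, N1, N2, com))
        fd = np.array([
            (mean_fitness(xbar + step, ybar, 0, N1, N2, com)
             - mean_fitness(xbar - step, ybar, 0, N1, N2, com)) / (2 * step),
            (mean_fitness(xbar, ybar + step, 0, N1, N2, com)
             - mean_fitness(xbar, ybar - step, 0, N1, N2, com)) / (2 * step),
        ])
        denom = max(float(np.max(np.abs(g))), 1e-9)
        worst = max(worst, float(np.max(np.abs(fd - g))) / denom)
    return worst


# ---------------------------------------------------------------------------
# unimodality of the fitness landscape
# ---------------------------------------------------------------------------

def _count_local_maxima(values: np.ndarray) -> int:
    interior = values[1:-1]
    return int(np.sum((interior > values[:-2]) & (interior > values[2:])))


def unimodality_agreement(
    n_widths: int = 20,
    width_lo: float = 0.3,
    width_hi: float = 0.7,
    grid_step: float = 0.01,
    boundary_exclusion: float = 0.01,
) -> dict:
    """Grid-scan test of the weak-trade-off unimodality conditions.

    On the symmetric baseline with equal prey contributions, the mean predator
    growth rate is unimodal in a trait exactly when the niche separation is
    below twice the effective kernel width.  Sweeps the width across the
    threshold for both traits, classifies each landscape by brute-force scan,
    and reports the fraction agreeing with the closed-form condition
    (parameter sets within ``boundary_exclusion`` relative distance of the
    threshold are excluded).
    """
    xs = np.arange(-1.5, 1.5 + grid_step / 2, grid_step)
    results = {"x": [], "y": []}
    for width in np.linspace(width_lo, width_hi, n_widths):
        # foraging trait: scan Wbar over xbar at equal densities, ybar central
        com = default_community(zeta=width, tau=1.0)
        sep = abs(com.prey1.theta - com.prey2.theta)
        crit = 2.0 * math.sqrt(com.predator.sigma_x2 + width**2)
        if abs(sep - crit) < boundary_exclusion * crit:
            pass
        else:
            w = np.array([mean_fitness(x, 0.0, 0.0, 1.0, 1.0, com) for x in xs])
            results["x"].append(
                (_count_local_maxima(w) == 1) == (sep < crit)
            )
        # immune trait: scan Wbar over ybar at the foraging midpoint
        com = default_community(zeta=1.0, tau=width)
        sep = abs(com.prey1.phi - com.prey2.phi)
        crit = 2.0 * math.sqrt(com.predator.sigma_y2 + width**2)
        if abs(sep - crit) < boundary_exclusion * crit:
            continue
        w = np.array([mean_fitness(0.0, y, 0.0, 1.0, 1.0, com) for y in xs])
        results["y"].append((_count_local_maxima(w) == 1) == (sep < crit))
    return {
        "agreement_x": float(np.mean(results["x"])),
        "agreement_y": float(np.mean(results["y"])),
        "n_x": len(results["x"]),
        "n_y": len(results["y"]),
    }


# ---------------------------------------------------------------------------
# slow-manifold consistency
# ---------------------------------------------------------------------------

def slow_manifold_errors(
    genetic_variances=(1e-4, 1e-5, 1e-6),
    evolutionary_window: float = 0.1,
    initial_traits: tuple[float, float] = (-0.3, 0.35),
    n_check: int = 40,
) -> list[float]:
    """Sup-norm trait-path deviation between the full and reduced systems.

    Both systems are run with the same (small) genetic variances from the same
    initial traits, the full system starting on the ecological attractor, over
    a horizon covering ``evolutionary_window`` units of evolutionary time
    (so the physical horizon scales as 1/sigma_G2).  The deviation should
    shrink as the genetic variance does.
    """
    errors = []
    for sg in genetic_variances:
        com = default_community(zeta=1.0, tau=1.0).replace_predator(
            sigma_xG2=sg, sigma_yG2=sg
        )
        x0, y0 = initial_traits
        eq = select_attractor(x0, y0, com)
        t_end = evolutionary_window / sg
        t_eval = np.linspace(0.0, t_end, n_check)
        solver = SolverConfig(rtol=1e-10, atol=1e-12, t_end=t_end)
        full = simulate_full(
            FullState(P=eq.P_star, N1=eq.N1_star, N2=eq.N2_star,
                      xbar=x0, ybar=y0),
            com, solver, t_eval=t_eval,
        )
        red = simulate_reduced((x0, y0), com, solver, t_eval=t_eval)
        err = max(
            float(np.max(np.abs(full.states[:, 3] - red.xbar))),
            float(np.max(np.abs(full.states[:, 4] - red.ybar))),
        )
        errors.append(err)
    return errors


# ---------------------------------------------------------------------------
# attractor selection versus direct simulation
# ---------------------------------------------------------------------------

def attractor_agreement(n_draws: int = 200, seed: int = 2) -> dict:
    """Closed-form attractor selection versus 3-D ecological simulation.

    For random communities and trait means, compares the selected equilibrium
    kind and densities with the long-run state of the simulated ecological
    subsystem.  Reports the kind-agreement fraction and the worst density
    error relative to the system's density scale.
    """
    rng = np.random.default_rng(seed)
    kind_ok = 0
    worst = 0.0
    n_done = 0
    while n_done < n_draws:
        com = random_community(rng)
        xbar = rng.uniform(-1.2, 1.2)
        ybar = rng.uniform(-1.2, 1.2)
        state, converged = simulate_ecology(xbar, ybar, com)
        if not converged:  # near a regime boundary; relaxation too slow
            continue
        n_done += 1
        chosen = select_attractor(xbar, ybar, com)
        candidates = ecological_equilibria(xbar, ybar, com)
        nearest = min(
            candidates,
            key=lambda eq: float(
                np.sum((np.asarray(eq.densities) - state) ** 2)
            ),
        )
        if nearest.kind == chosen.kind:
            kind_ok += 1
        scale = max(float(np.max(np.abs(state))), 1e-8)
        worst = max(
            worst,
            float(np.max(np.abs(np.asarray(chosen.densities) - state))) / scale,
        )
    return {"kind_agreement": kind_ok / n_draws, "max_density_rel_err": worst,
            "n": n_draws}


# ---------------------------------------------------------------------------
# Lyapunov exponents
# ---------------------------------------------------------------------------

def stable_equilibrium_draws(
    n: int = 20, seed: int = 3, min_decay: float = 0.02
) -> list[tuple[Community, FullState, float]]:
    """Random communities with a linearly stable full-system equilibrium.

    Returns ``(community, equilibrium state, leading eigenvalue real part)``
    triples.  Draws are kept when a stable reduced-system trait equilibrium
    sits on a coexistence attractor and the full 5x5 Jacobian there has its
    leading real part below ``-min_decay`` (clearly stable, so the exponent
    estimate converges on a short horizon).
    """
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        com = random_community(rng, h_min=0.05, h_max=0.4)
        try:
            eqs = find_trait_equilibria(com, n_seed=7)
        except Exception:
            continue
        for te in eqs:
            if te.stability != "stable":
                continue
            eco = select_attractor(te.xbar_star, te.ybar_star, com)
            if not eco.coexistence:
                continue
            state = FullState(P=eco.P_star, N1=eco.N1_star, N2=eco.N2_star,
                              xbar=te.xbar_star, ybar=te.ybar_star)
            lam = np.linalg.eigvals(jacobian_full(state, com))
            lead = float(np.max(np.real(lam)))
            if lead < -min_decay:
                out.append((com, state, lead))
                break
    return out


def lyapunov_eigenvalue_error(n: int = 20, seed: int = 3) -> dict:
    """Relative error of the estimated exponent against the leading Jacobian
    eigenvalue, at random stable equilibria of the full system."""
    draws = stable_equilibrium_draws(n=n, seed=seed)
    worst = 0.0
    for com, state, lead in draws:
        J = jacobian_full(state, com)
        lam, vec = np.linalg.eig(J)
        k = int(np.argmax(np.real(lam)))
        v0 = np.real(vec[:, k])
        if np.linalg.norm(v0) < 1e-12:
            v0 = np.imag(vec[:, k])
        total = max(400.0, 50.0 / abs(lead))
        cfg = LyapunovConfig(transient=10.0, total_time=total,
                             renorm_interval=1.0)
        res = lyapunov_exponent(com, state, cfg, v0=v0)
        worst = max(worst, abs(res.exponent - lead) / abs(lead))
    return {"max_rel_err": worst, "n": len(draws)}


def chaos_regime_exponents(
    config: LyapunovConfig | None = None,
    heritabilities=(0.1, 0.5, 0.9),
) -> dict:
    """Exponent signs across the immune trade-off regimes.

    The chaos exemplar (intermediate tau, high immune heritability, large
    immune genetic variance) should have a positive maximal exponent; with a
    strong immune trade-off (tau = 0.01) the dynamics equilibrate and all
    exponents are negative regardless of heritability.
    """
    config = config or LyapunovConfig(transient=300.0, total_time=1500.0)
    chaos_com = fixture_regimes()["chaos_exemplar"]
    res = lyapunov_exponent(
        chaos_com, perturbed_coexistence_state(chaos_com), config
    )
    strong = []
    for h in heritabilities:
        com = chaos_com.with_widths(tau=0.01).replace_predator(
            sigma_yG2=h * chaos_com.predator.sigma_y2
        )
        r = lyapunov_exponent(com, perturbed_coexistence_state(com), config)
        strong.append(r.exponent)
    return {
        "chaos_exponent": res.exponent,
        "chaos_converged": res.converged,
        "strong_tau_exponents": strong,
        "strong_tau_max": max(strong),
    }


# ---------------------------------------------------------------------------
# Latin-hypercube regime statistics
# ---------------------------------------------------------------------------

def lhs_quadrant_study(zeta: float, tau: float, n: int = 200, seed: int = 4):
    """Run one trade-off quadrant of the study on the symmetric baseline."""
    base = default_community()
    design = lhs_mod.default_design(base, n=n, seed=seed)
    return lhs_mod.run_lhs_study(design, (zeta, tau), base)


def intake_infection_deviation(records, x_col: str = "rel_intake1",
                               y_col: str = "rel_infection1",
                               n_bins: int = 10) -> float:
    """Count-weighted mean |binned mean of y - bin centre| against the 1:1 line.

    This is the spline-free analogue of eyeballing how far the
    intake-versus-infection cloud bends away from the diagonal.
    """
    ok = records[~records.get("failed", False).astype(bool)]
    ok = ok.dropna(subset=[x_col, y_col])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(ok[x_col], edges) - 1, 0, n_bins - 1)
    dev = 0.0
    total = 0
    for k in range(n_bins):
        sel = idx == k
        cnt = int(np.sum(sel))
        if cnt == 0:
            continue
        dev += cnt * abs(float(np.mean(ok[y_col][sel])) - centers[k])
        total += cnt
    return dev / total if total else math.nan


def specialist_generalist_stats(records, community: Community | None = None) -> dict:
    """Where do the evolved diets sit between the two foraging optima?

    ``specialist_fraction`` counts endpoints within 20% of the niche
    separation of either optimum; ``generalist_fraction`` counts endpoints
    within 10% of the midpoint, following the convention that a generalist
    diet sits at the fitness midpoint between the two prey optima.
    """
    com = community or default_community()
    th1, th2 = com.prey1.theta, com.prey2.theta
    mid = 0.5 * (th1 + th2)
    span = abs(th2 - th1)
    ok = records[~records.get("failed", False).astype(bool)]
    x = ok["xbar_star"].to_numpy(dtype=float)
    near1 = np.abs(x - th1) < 0.2 * span
    near2 = np.abs(x - th2) < 0.2 * span
    nearm = np.abs(x - mid) < 0.1 * span
    return {
        "specialist_fraction": float(np.mean(near1 | near2)),
        "specialist_low": float(np.mean(near1)),
        "specialist_high": float(np.mean(near2)),
        "generalist_fraction": float(np.mean(nearm)),
        "n": int(len(x)),
    }
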