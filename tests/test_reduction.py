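import math

import numpy as np
import pytest

from eei import default_community
from eei.core import mean_fitness, prey_mean_growth, selection_gradients
from eei.dynamics import SolverConfig
from eei.params import random_community
from eei.reduction import (
    ecological_equilibria,
    evolve_to_equilibrium,
    find_trait_equilibria,
    make_reduced_field,
    nullclines,
    phase_portrait,
    reduced_vector_field,
    select_attractor,
    separatrices,
    simulate_ecology,
    simulate_reduced,
)


class TestEcologicalEquilibria:
    def test_symmetric_weak_weak_coexistence_densities(self, weak_weak):
        """Frozen closed-form values for the symmetric baseline at the trait
        midpoint (cross-checked against direct simulation below)."""
        eq = select_attractor(0.0, 0.0, weak_weak)
        assert eq.kind == "coexistence"
        assert eq.P_star == pytest.approx(0.55162, abs=1e-4)
        assert eq.N1_star == pytest.approx(0.03001, abs=1e-4)
        assert eq.N2_star == pytest.approx(eq.N1_star, rel=1e-12)

    def test_starvation_limit_leaves_only_predator_exclusion(self, weak_weak):
        com = weak_weak.replace_predator(d=10.0)
        eqs = {e.kind: e for e in ecological_equilibria(0.0, 0.0, com)}
        winners = [e for e in eqs.values() if e.feasible and e.uninvadable]
        assert len(winners) == 1
        assert winners[0].kind == "predator_exclusion"
        assert winners[0].densities == (0.0, weak_weak.prey1.K,
                                        weak_weak.prey2.K)

    def test_feasible_candidates_zero_their_defining_equations(self, rng):
        checked = 0
        for _ in range(1000):
            com = random_community(rng)
            x, y = rng.uniform(-1.2, 1.2, 2)
            for eq in ecological_equilibria(x, y, com):
                if not eq.feasible:
                    continue
                checked += 1
                if eq.P_star > 0:
                    assert abs(mean_fitness(x, y, eq.P_star, eq.N1_star,
                                            eq.N2_star, com)) < 1e-10
                for i, N in ((1, eq.N1_star), (2, eq.N2_star)):
                    if N > 0:
                        assert abs(prey_mean_growth(i, x, eq.P_star, N, com)) \
                            < 1e-10
        assert checked > 1000  # multiple feasible candidates per draw

    def test_excluded_species_have_exactly_zero_density(self, rng):
        for _ in range(50):
            com = random_community(rng)
            for eq in ecological_equilibria(*rng.uniform(-1, 1, 2), com):
                if eq.kind == "predator_exclusion":
                    assert eq.P_star == 0.0
                elif eq.kind == "prey1_exclusion":
                    assert eq.N1_star == 0.0
                elif eq.kind == "prey2_exclusion":
                    assert eq.N2_star == 0.0


class TestAttractorSelection:
    def test_agrees_with_direct_simulation(self, rng):
        for _ in range(15):
            com = random_community(rng)
            x, y = rng.uniform(-1.0, 1.0, 2)
            state, converged = simulate_ecology(x, y, com)
            if not converged:
                continue
            chosen = select_attractor(x, y, com)
            scale = max(np.max(np.abs(state)), 1e-8)
            assert np.max(np.abs(np.asarray(chosen.densities) - state)) \
                < 1e-4 * scale

    def test_specialist_diet_releases_the_other_prey(self):
        com = default_community(zeta=0.01, tau=1.0)
        eq = select_attractor(com.prey1.theta, 0.0, com)
        # prey 2 is effectively uncoupled, so it sits at carrying capacity
        assert eq.N2_star == pytest.approx(com.prey2.K, rel=1e-3)
        assert eq.P_star > 0


class TestReducedField:
    def test_symmetry_point_is_stationary(self, weak_weak):
        f = reduced_vector_field(0.0, 0.0, weak_weak)
        assert np.max(np.abs(f)) < 1e-14

    def test_fast_path_matches_reference(self, rng):
        for _ in range(10):
            com = random_community(rng)
            field = make_reduced_field(com)
            for _ in range(10):
                x, y = rng.uniform(-1.2, 1.2, 2)
                assert np.allclose(field(x, y),
                                   reduced_vector_field(x, y, com),
                                   rtol=1e-12, atol=1e-300)

    def test_equals_scaled_gradient_at_attractor_densities(self, rng):
        com = random_community(rng)
        x, y = 0.3, -0.2
        eq = select_attractor(x, y, com)
        gx, gy = selection_gradients(x, y, eq.N1_star, eq.N2_star, com)
        fx, fy = reduced_vector_field(x, y, com)
        assert fx == pytest.approx(com.predator.sigma_xG2 * gx, rel=1e-12)
        assert fy == pytest.approx(com.predator.sigma_yG2 * gy, rel=1e-12)

    def test_single_prey_region_pulls_diet_to_its_optimum(self):
        com = default_community(zeta=0.3, tau=1.0)
        # diet far toward prey 1 excludes prey 2 via apparent competition
        eq = select_attractor(com.prey1.theta, 0.0, com)
        if eq.N2_star == 0.0:
            fx, _ = reduced_vector_field(com.prey1.theta + 0.05, 0.0, com)
            assert fx < 0  # pushed back toward theta1


class TestTraitEquilibria:
    def test_weak_weak_has_single_stable_generalist(self, weak_weak):
        eqs = find_trait_equilibria(weak_weak, n_seed=9)
        stable = [e for e in eqs if e.stability == "stable"]
        assert len(stable) == 1
        assert abs(stable[0].xbar_star) < 1e-6
        assert abs(stable[0].ybar_star) < 1e-6

    def test_strong_strong_has_specialist_pair(self, strong_strong):
        eqs = find_trait_equilibria(strong_strong, n_seed=9)
        stable = sorted((e for e in eqs if e.stability == "stable"),
                        key=lambda e: e.xbar_star)
        assert len(stable) >= 2
        assert stable[0].xbar_star == pytest.approx(-0.5, abs=0.02)
        assert stable[-1].xbar_star == pytest.approx(+0.5, abs=0.02)

    def test_headline_asymmetry_between_the_mixed_regimes(self):
        # weak foraging + strong immunity: generalist diet, specialist immunity
        com = default_community(zeta=1.0, tau=0.01)
        stable = [e for e in find_trait_equilibria(com, n_seed=9)
                  if e.stability == "stable"]
        assert stable
        for e in stable:
            assert abs(e.xbar_star) < 0.05  # within 10% of the midpoint
            assert min(abs(e.ybar_star - 0.5), abs(e.ybar_star + 0.5)) < 0.1
        # strong foraging + weak immunity: immunity co-locates with the diet
        com = default_community(zeta=0.01, tau=1.0)
        stable = [e for e in find_trait_equilibria(com, n_seed=9)
                  if e.stability == "stable"]
        assert stable
        for e in stable:
            assert min(abs(e.xbar_star - 0.5), abs(e.xbar_star + 0.5)) < 0.05
            assert abs(e.ybar_star - e.xbar_star) < 0.1

    def test_roots_satisfy_the_residual_bound(self, weak_weak):
        field = make_reduced_field(weak_weak)
        for e in find_trait_equilibria(weak_weak, n_seed=9):
            assert np.max(np.abs(field(e.xbar_star, e.ybar_star))) < 1e-9


class TestPhasePortrait:
    def test_symmetric_x_nullcline_is_near_vertical_through_origin(self, weak_weak):
        """For the symmetric community the diet nullcline hugs the trait
        midpoint (it bends off it only where the immune state makes the two
        prey unequally valuable) and passes through the symmetric point."""
        from eei.reduction import make_reduced_field

        field = make_reduced_field(weak_weak)
        assert abs(field(0.0, 0.0)[0]) < 1e-14
        pp = nullclines(weak_weak, n_grid=41)
        pts = np.vstack(pp.x_nullcline)
        assert np.max(np.abs(pts[:, 0])) < 0.05  # 5% of the niche separation
        assert pts[:, 1].max() - pts[:, 1].min() > 1.0

    def test_equilibria_lie_on_both_nullclines(self):
        com = default_community(zeta=1.0, tau=0.01)
        pp = phase_portrait(com, n_grid=81, n_seed=9)
        (x_lo, x_hi) = (-0.7, 0.7)
        cell = (x_hi - x_lo) / 80
        for e in pp.equilibria:
            if e.stability == "degenerate":
                continue
            z = np.array([e.xbar_star, e.ybar_star])
            for curves in (pp.x_nullcline, pp.y_nullcline):
                d = min(np.min(np.hypot(*(c - z).T)) for c in curves)
                assert d < 2 * cell

    def test_separatrix_splits_the_immune_basins(self):
        """Weak foraging, strong immunity: the saddle's stable manifold is the
        horizontal symmetry axis; starts on either side reach different
        specialist immune states."""
        com = default_community(zeta=1.0, tau=0.01)
        eqs = find_trait_equilibria(com, n_seed=9)
        saddles = [e for e in eqs if e.stability == "saddle"]
        assert saddles
        curves = separatrices(saddles, com, eps=1e-6)
        assert len(curves) == 2 * len(saddles)
        up, _, _ = evolve_to_equilibrium((0.2, 0.15), com, t_max=1e5)
        down, _, _ = evolve_to_equilibrium((0.2, -0.15), com, t_max=1e5)
        assert up[1] == pytest.approx(0.5, abs=0.05)
        assert down[1] == pytest.approx(-0.5, abs=0.05)

    def test_separatrix_insensitive_to_epsilon(self):
        com = default_community(zeta=1.0, tau=0.01)
        saddles = [e for e in find_trait_equilibria(com, n_seed=9)
                   if e.stability == "saddle"]
        a = separatrices(saddles[:1], com, eps=1e-6)[0]
        b = separatrices(saddles[:1], com, eps=5e-7)[0]
        # compare the endpoints (both should leave the box at the same place)
        assert np.allclose(a[-1], b[-1], atol=1e-3)

    def test_non_saddle_input_rejected(self, weak_weak):
        stable = [e for e in find_trait_equilibria(weak_weak, n_seed=5)
                  if e.stability == "stable"]
        with pytest.raises(ValueError, match="saddle"):
            separatrices(stable, weak_weak)


class TestReducedTrajectories:
    def test_stable_equilibrium_is_stationary(self, weak_weak):
        traj = simulate_reduced((0.0, 0.0), weak_weak,
                                SolverConfig(t_end=1e4))
        assert abs(traj.xbar[-1]) < 1e-9
        assert abs(traj.ybar[-1]) < 1e-9

    def test_convergence_flag_and_endpoint(self, weak_weak):
        (x, y), converged, t = evolve_to_equilibrium((0.3, 0.3), weak_weak,
                                                     grad_tol=1e-9)
        assert converged
        # endpoint distance is bounded by grad_tol over the slowest decay rate
        assert x == pytest.approx(0.0, abs=1e-4)
        assert y == pytest.approx(0.0, abs=1e-4)

    def test_matches_full_system_at_tiny_genetic_variance(self, weak_weak):
        """Slow-manifold check: see the acceptance suite for the refinement
        study; here a single coarse comparison."""
        from eei.diagnostics import slow_manifold_errors

        errs = slow_manifold_errors(genetic_variances=(1e-4,),
                                    evolutionary_window=0.05)
        assert errs[0] < 1e-5
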