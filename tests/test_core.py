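import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from eei.core import (
    attack_rate,
    fitness_pointwise,
    mean_attack_rate,
    mean_fitness,
    mean_susceptibility,
    prey_mean_growth,
    rate_bundle,
    selection_gradients,
    susceptibility,
    assess_foraging_tradeoff,
    assess_immune_tradeoff,
    tradeoff_is_weak_foraging,
    tradeoff_is_weak_immune,
)
from eei.params import PreyParasitePair, random_community
from eei import default_community

traits = st.floats(-3.0, 3.0)


class TestKernels:
    @pytest.mark.parametrize(
        "x_offset,expected",
        [
            (0.0, 2.0),                       # kernel maximum alpha at theta
            (0.5, 2.0 * math.exp(-0.5)),      # one half-width out
            (50.0, 0.0),                      # deep Gaussian tail
        ],
    )
    def test_attack_rate_values(self, x_offset, expected):
        prey = PreyParasitePair(alpha=2.0, theta=0.3, zeta=0.5)
        assert attack_rate(prey.theta + x_offset, prey) == pytest.approx(
            expected, abs=1e-12
        )

    def test_susceptibility_spans_gamma_to_beta(self):
        prey = PreyParasitePair(beta=1.0, gamma=0.1, phi=-0.2, tau=0.5)
        assert susceptibility(prey.phi, prey) == pytest.approx(0.1)
        assert susceptibility(prey.phi + 50, prey) == pytest.approx(1.0)
        assert susceptibility(prey.phi + 0.5, prey) == pytest.approx(
            1.0 - 0.9 * math.exp(-0.5)
        )

    @given(x=traits)
    def test_kernel_bounds(self, x):
        prey = PreyParasitePair(alpha=2.0, zeta=0.3, beta=0.9, gamma=0.2,
                                tau=0.4)
        assert 0.0 < attack_rate(x, prey) <= prey.alpha
        assert prey.gamma <= susceptibility(x, prey) <= prey.beta


class TestPhenotypeAverages:
    def test_zero_variance_reduces_to_individual_kernels(self):
        prey = PreyParasitePair(alpha=1.7, theta=0.2, zeta=0.4, beta=0.8,
                                gamma=0.05, phi=-0.3, tau=0.6)
        for t in (-0.5, 0.0, 0.7):
            assert mean_attack_rate(t, 0.0, prey) == pytest.approx(
                attack_rate(t, prey)
            )
            assert mean_susceptibility(t, 0.0, prey) == pytest.approx(
                susceptibility(t, prey)
            )

    def test_known_values(self):
        prey = PreyParasitePair(alpha=2.0, theta=0.0, zeta=1.0)
        assert mean_attack_rate(0.0, 0.01, prey) == pytest.approx(
            2.0 / math.sqrt(1.01), rel=1e-12
        )
        prey = PreyParasitePair(beta=1.0, gamma=0.1, phi=0.0, tau=0.01)
        assert mean_susceptibility(0.0, 0.0001, prey) == pytest.approx(
            1.0 - 0.9 * 0.01 / math.sqrt(0.0002), rel=1e-12
        )

    def test_mean_attack_maximised_at_theta(self):
        prey = PreyParasitePair(theta=0.4, zeta=0.3)
        peak = mean_attack_rate(prey.theta, 0.02, prey)
        for t in (-1.0, 0.0, 0.39, 0.41, 2.0):
            if t != prey.theta:
                assert mean_attack_rate(t, 0.02, prey) < peak

    def test_closed_forms_match_quadrature(self, rng):
        """The phenotype averages equal the integral of the individual kernels
        against the normal trait density."""
        worst = 0.0
        for _ in range(100):
            com = random_community(rng)
            prey = com.prey[int(rng.integers(2))]
            t = rng.uniform(-1.5, 1.5)
            sx2, sy2 = com.predator.sigma_x2, com.predator.sigma_y2
            qa, _ = quad(lambda x: attack_rate(x, prey)
                         * norm.pdf(x, t, math.sqrt(sx2)),
                         -np.inf, np.inf, epsabs=1e-12, epsrel=1e-12)
            qs, _ = quad(lambda y: susceptibility(y, prey)
                         * norm.pdf(y, t, math.sqrt(sy2)),
                         -np.inf, np.inf, epsabs=1e-12, epsrel=1e-12)
            worst = max(worst,
                        abs(qa - mean_attack_rate(t, sx2, prey)),
                        abs(qs - mean_susceptibility(t, sy2, prey)))
        assert worst < 1e-8


class TestFitness:
    def test_starvation_rate_without_prey(self, weak_weak):
        assert fitness_pointwise(0.1, 0.2, 1.0, 0.0, 0.0, weak_weak) == \
            pytest.approx(-weak_weak.predator.d)
        assert mean_fitness(0.1, 0.2, 1.0, 0.0, 0.0, weak_weak) == \
            pytest.approx(-weak_weak.predator.d)

    def test_mean_fitness_reduces_to_pointwise_without_variance(self, rng):
        com = random_community(rng).replace_predator(
            sigma_x2=0.0, sigma_xG2=0.0, sigma_y2=0.0, sigma_yG2=0.0
        )
        for _ in range(10):
            x, y = rng.uniform(-1, 1, 2)
            N1, N2 = rng.uniform(0, 2, 2)
            assert mean_fitness(x, y, 0.5, N1, N2, com) == pytest.approx(
                fitness_pointwise(x, y, 0.5, N1, N2, com), rel=1e-12
            )

    def test_mean_fitness_equals_double_quadrature(self, rng):
        """Wbar is the double integral of W against both trait densities."""
        for _ in range(5):
            com = random_community(rng)
            x, y = rng.uniform(-0.8, 0.8, 2)
            N1, N2 = rng.uniform(0.1, 1.5, 2)
            sx = math.sqrt(com.predator.sigma_x2)
            sy = math.sqrt(com.predator.sigma_y2)
            inner, _ = quad(
                lambda yy: quad(
                    lambda xx: fitness_pointwise(xx, yy, 0.0, N1, N2, com)
                    * norm.pdf(xx, x, sx),
                    x - 8 * sx, x + 8 * sx, epsabs=1e-11,
                )[0] * norm.pdf(yy, y, sy),
                y - 8 * sy, y + 8 * sy, epsabs=1e-11,
            )
            assert inner == pytest.approx(
                mean_fitness(x, y, 0.0, N1, N2, com), abs=1e-8
            )

    def test_prey_growth_logistic_limits(self, weak_weak):
        prey = weak_weak.prey1
        assert prey_mean_growth(1, 0.0, 0.0, prey.K, weak_weak) == 0.0
        assert prey_mean_growth(1, 0.0, 0.0, 0.0, weak_weak) == prey.r


class TestSelectionGradients:
    def test_vanish_by_symmetry_at_the_midpoint(self, weak_weak):
        gx, gy = selection_gradients(0.0, 0.0, 0.7, 0.7, weak_weak)
        assert gx == pytest.approx(0.0, abs=1e-14)
        assert gy == pytest.approx(0.0, abs=1e-14)

    def test_single_prey_gradient_points_at_its_optimum(self, weak_weak):
        theta1 = weak_weak.prey1.theta
        for x in (-1.2, -0.6, 0.0, 0.3):
            gx, _ = selection_gradients(x, 0.0, 1.0, 0.0, weak_weak)
            assert math.copysign(1, gx) == math.copysign(1, theta1 - x)

    def test_match_finite_differences_of_mean_fitness(self, rng):
        step = 1e-5
        worst = 0.0
        for _ in range(100):
            com = random_community(rng)
            x, y = rng.uniform(-1.2, 1.2, 2)
            N1, N2 = rng.uniform(0.05, 2.0, 2)
            g = np.asarray(selection_gradients(x, y, N1, N2, com))
            fd = np.array([
                (mean_fitness(x + step, y, 0, N1, N2, com)
                 - mean_fitness(x - step, y, 0, N1, N2, com)) / (2 * step),
                (mean_fitness(x, y + step, 0, N1, N2, com)
                 - mean_fitness(x, y - step, 0, N1, N2, com)) / (2 * step),
            ])
            worst = max(worst, float(np.max(np.abs(fd - g)))
                        / max(float(np.max(np.abs(g))), 1e-9))
        assert worst < 1e-6


class TestTradeoffClassification:
    def test_baseline_widths_classify_as_named(self):
        weak = default_community(zeta=1.0, tau=1.0)
        strong = default_community(zeta=0.01, tau=0.01)
        assert tradeoff_is_weak_foraging(weak)
        assert tradeoff_is_weak_immune(weak)
        assert not tradeoff_is_weak_foraging(strong)
        assert not tradeoff_is_weak_immune(strong)

    def test_zero_separation_is_always_weak(self):
        com = default_community(zeta=0.01, tau=0.01)
        com = com.replace_prey(1, theta=0.5, phi=0.5)  # same optima as prey 2
        assert tradeoff_is_weak_foraging(com)
        assert tradeoff_is_weak_immune(com)

    def test_unequal_widths_warn_and_summarise_conservatively(self):
        com = default_community(zeta=1.0, tau=1.0).replace_prey(1, zeta=0.01)
        with pytest.warns(UserWarning, match="widths differ"):
            assessment = assess_foraging_tradeoff(com)
        assert not assessment.common_width
        assert assessment.per_width == (False, True)
        assert not assessment.weak

    def test_threshold_location(self):
        # separation 1, sigma_x2=0.01: critical width solves 4(s2+z2)=1
        z_crit = math.sqrt(0.25 - 0.01)
        assert not tradeoff_is_weak_foraging(
            default_community(zeta=0.99 * z_crit)
        )
        assert tradeoff_is_weak_foraging(
            default_community(zeta=1.01 * z_crit)
        )
        with pytest.warns(UserWarning):
            assess_immune_tradeoff(
                default_community().replace_prey(2, tau=0.2)
            )


class TestRateBundle:
    def test_symmetric_state_splits_evenly(self, weak_weak):
        b = rate_bundle(0.0, 0.0, 0.5, 0.5, weak_weak)
        assert b.relative_intake == pytest.approx((0.5, 0.5))
        assert b.relative_exposure == pytest.approx((0.5, 0.5))
        assert b.relative_infection == pytest.approx((0.5, 0.5))
        assert b.degenerate == (False, False, False)

    def test_prevalence_ratio_sets_exposure_share(self, weak_weak):
        com = weak_weak.replace_prey(1, c=0.5).replace_prey(2, c=0.1)
        b = rate_bundle(0.0, 0.0, 0.5, 0.5, com)
        assert b.relative_intake[0] == pytest.approx(0.5)
        assert b.relative_exposure[0] == pytest.approx(5.0 / 6.0)

    def test_equal_prevalence_cancels(self, weak_weak, rng):
        for _ in range(10):
            x, y = rng.uniform(-1, 1, 2)
            N1, N2 = rng.uniform(0.05, 2, 2)
            b = rate_bundle(x, y, N1, N2, weak_weak)
            assert b.relative_exposure == pytest.approx(b.relative_intake)

    def test_empty_community_is_flagged_degenerate(self, weak_weak):
        b = rate_bundle(0.0, 0.0, 0.0, 0.0, weak_weak)
        assert b.degenerate == (True, True, True)
        assert math.isnan(b.relative_intake[0])
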