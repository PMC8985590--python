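"""Closed-form building blocks of the model.

Attack and susceptibility kernels, their phenotype averages over the normal
trait distributions, predator and prey per-capita growth rates, the Lande
selection gradients, trade-off classification, and the intake / exposure /
infection rate statistics.

All functions operate on scalars; grid scans in the analysis modules simply
loop.  Closed-form phenotype averages are exact: a Gaussian kernel averaged
against a normal density with variance ``sigma2`` is again Gaussian with the
width inflated from ``zeta**2`` to ``sigma2 + zeta**2`` and amplitude scaled
by ``zeta / sqrt(sigma2 + zeta**2)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .params import Community, PreyParasitePair

__all__ = [
    "attack_rate",
    "susceptibility",
    "mean_attack_rate",
    "mean_susceptibility",
    "fitness_pointwise",
    "mean_fitness",
    "prey_mean_growth",
    "selection_gradients",
    "TradeoffAssessment",
    "assess_foraging_tradeoff",
    "assess_immune_tradeoff",
    "tradeoff_is_weak_foraging",
    "tradeoff_is_weak_immune",
    "RateBundle",
    "rate_bundle",
]


def attack_rate(x: float, prey: PreyParasitePair) -> float:
    """Individual attack rate a_i(x) = alpha * exp(-(x-theta)^2 / (2 zeta^2))."""
    dx = x - prey.theta
    return prey.alpha * math.exp(-dx * dx / (2.0 * prey.zeta**2))


def susceptibility(y: float, prey: PreyParasitePair) -> float:
    """Individual susceptibility S_i(y) = beta - (beta-gamma) exp(-(y-phi)^2/(2 tau^2)).

    Minimised (``gamma``) at the immune optimum ``phi``, saturating at
    ``beta`` far from it.
    """
    dy = y - prey.phi
    return prey.beta - (prey.beta - prey.gamma) * math.exp(
        -dy * dy / (2.0 * prey.tau**2)
    )


def mean_attack_rate(xbar: float, sigma_x2: float, prey: PreyParasitePair) -> float:
    """Phenotype-averaged attack rate of a normal trait distribution.

    abar_i(xbar) = alpha * zeta/sqrt(sigma_x2+zeta^2)
                 * exp(-(xbar-theta)^2 / (2 (sigma_x2+zeta^2))).
    Reduces to :func:`attack_rate` at ``sigma_x2 == 0``.
    """
    v = sigma_x2 + prey.zeta**2
    dx = xbar - prey.theta
    return prey.alpha * prey.zeta / math.sqrt(v) * math.exp(-dx * dx / (2.0 * v))


def mean_susceptibility(ybar: float, sigma_y2: float, prey: PreyParasitePair) -> float:
    """Phenotype-averaged susceptibility of a normal trait distribution.

    Sbar_i(ybar) = beta - (beta-gamma) * tau/sqrt(sigma_y2+tau^2)
                 * exp(-(ybar-phi)^2 / (2 (sigma_y2+tau^2))).
    """
    v = sigma_y2 + prey.tau**2
    dy = ybar - prey.phi
    return prey.beta - (prey.beta - prey.gamma) * prey.tau / math.sqrt(v) * math.exp(
        -dy * dy / (2.0 * v)
    )


def fitness_pointwise(
    x: float, y: float, P: float, N1: float, N2: float, community: Community
) -> float:
    """Per-capita growth rate W(x, y, P, N1, N2) of a single predator phenotype.

    Each consumed prey contributes its conversion value ``b_i`` minus the
    expected parasite cost ``c_i * m_i * S_i(y)``.
    """
    del P  # the predator's growth rate is density independent in P
    total = -community.predator.d
    for prey, N in zip(community.prey, (N1, N2)):
        total += (prey.b - prey.c * prey.m * susceptibility(y, prey)) * attack_rate(
            x, prey
        ) * N
    return total


def mean_fitness(
    xbar: float, ybar: float, P: float, N1: float, N2: float, community: Community
) -> float:
    """Population mean per-capita growth rate Wbar of the predator.

    Equals the double integral of :func:`fitness_pointwise` against the two
    independent normal trait densities; coincides with it when both
    phenotypic variances vanish.
    """
    del P
    pred = community.predator
    total = -pred.d
    for prey, N in zip(community.prey, (N1, N2)):
        Sbar = mean_susceptibility(ybar, pred.sigma_y2, prey)
        abar = mean_attack_rate(xbar, pred.sigma_x2, prey)
        total += (prey.b - prey.c * prey.m * Sbar) * abar * N
    return total


def prey_mean_growth(
    i: int, xbar: float, P: float, Ni: float, community: Community
) -> float:
    """Per-capita growth rate Ybar_i of prey i: logistic minus mean predation."""
    prey = community.pair(i)
    abar = mean_attack_rate(xbar, community.predator.sigma_x2, prey)
    return prey.r * (1.0 - Ni / prey.K) - abar * P


def selection_gradients(
    xbar: float, ybar: float, N1: float, N2: float, community: Community
) -> tuple[float, float]:
    """The two components of the Lande selection gradient of Wbar.

    dWbar/dxbar = sum_i (b_i - m_i c_i Sbar_i) abar_i N_i (theta_i - xbar)
                  / (sigma_x2 + zeta_i^2)
    dWbar/dybar = sum_i m_i c_i abar_i N_i (beta_i - Sbar_i) (phi_i - ybar)
                  / (sigma_y2 + tau_i^2)
    """
    pred = community.predator
    gx = 0.0
    gy = 0.0
    for prey, N in zip(community.prey, (N1, N2)):
        vx = pred.sigma_x2 + prey.zeta**2
        vy = pred.sigma_y2 + prey.tau**2
        abar = mean_attack_rate(xbar, pred.sigma_x2, prey)
        Sbar = mean_susceptibility(ybar, pred.sigma_y2, prey)
        gx += (prey.b - prey.m * prey.c * Sbar) * abar * N * (prey.theta - xbar) / vx
        gy += prey.m * prey.c * abar * N * (prey.beta - Sbar) * (prey.phi - ybar) / vy
    return gx, gy


# ---------------------------------------------------------------------------
# trade-off classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TradeoffAssessment:
    """Weak/strong classification of one trade-off.

    ``per_width`` evaluates the unimodality condition at each prey's kernel
    width separately; ``weak`` is the conservative summary (true only when the
    condition holds at every width).  ``common_width`` records whether the two
    widths agree, the only case the condition is stated for exactly.
    """

    weak: bool
    per_width: tuple[bool, bool]
    common_width: bool

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.weak


def _assess(separation: float, widths: tuple[float, float], sigma2: float,
            label: str) -> TradeoffAssessment:
    # Unimodality of an equal-weight two-Gaussian mixture with common sd s
    # fails exactly when the separation of the means exceeds 2 s.
    per = tuple(
        separation < 2.0 * math.sqrt(sigma2 + w**2) for w in widths
    )
    common = widths[0] == widths[1]
    if not common:
        warnings.warn(
            f"{label} kernel widths differ between prey; the weak-trade-off "
            "condition is evaluated at each width and summarised "
            "conservatively (weak only if it holds at both)",
            stacklevel=3,
        )
    return TradeoffAssessment(weak=all(per), per_width=per, common_width=common)


def assess_foraging_tradeoff(community: Community) -> TradeoffAssessment:
    """Is the foraging trade-off weak relative to phenotypic variation in x?

    Weak means |theta1 - theta2| < 2 sqrt(sigma_x2 + zeta^2): the mean
    predator growth rate is then unimodal in xbar whenever the two prey
    contribute equally to it.
    """
    p1, p2 = community.prey
    return _assess(
        abs(p1.theta - p2.theta),
        (p1.zeta, p2.zeta),
        community.predator.sigma_x2,
        "foraging",
    )


def assess_immune_tradeoff(community: Community) -> TradeoffAssessment:
    """Is the immune trade-off weak relative to phenotypic variation in y?

    Weak means |phi1 - phi2| < 2 sqrt(sigma_y2 + tau^2).
    """
    p1, p2 = community.prey
    return _assess(
        abs(p1.phi - p2.phi),
        (p1.tau, p2.tau),
        community.predator.sigma_y2,
        "immune",
    )


def tradeoff_is_weak_foraging(community: Community) -> bool:
    return assess_foraging_tradeoff(community).weak


def tradeoff_is_weak_immune(community: Community) -> bool:
    return assess_immune_tradeoff(community).weak


# ---------------------------------------------------------------------------
# intake / exposure / infection statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateBundle:
    """Absolute and relative intake, exposure and infection rates.

    Intake of prey i is ``abar_i N_i`` (the encounter side of the diet);
    exposure to parasite i multiplies by the infected fraction ``c_i``
    (encounter filter), and infection further multiplies by the mean
    susceptibility ``Sbar_i`` (compatibility filter).  Relative pairs are
    normalised to sum to one; a pair whose absolute rates are both zero is
    flagged degenerate and reported as NaN.
    """

    intake: tuple[float, float]
    exposure: tuple[float, float]
    infection: tuple[float, float]
    relative_intake: tuple[float, float]
    relative_exposure: tuple[float, float]
    relative_infection: tuple[float, float]
    degenerate: tuple[bool, bool, bool]


def _normalise(pair: tuple[float, float]) -> tuple[tuple[float, float], bool]:
    total = pair[0] + pair[1]
    if total <= 0.0:
        return (math.nan, math.nan), True
    return (pair[0] / total, pair[1] / total), False


def rate_bundle(
    xbar: float, ybar: float, N1: float, N2: float, community: Community
) -> RateBundle:
    """Intake, exposure and infection rates of the two prey/parasite types."""
    pred = community.predator
    intake = []
    exposure = []
    infection = []
    for prey, N in zip(community.prey, (N1, N2)):
        abar = mean_attack_rate(xbar, pred.sigma_x2, prey)
        Sbar = mean_susceptibility(ybar, pred.sigma_y2, prey)
        intake.append(abar * N)
        exposure.append(abar * N * prey.c)
        infection.append(abar * N * prey.c * Sbar)
    intake = (intake[0], intake[1])
    exposure = (exposure[0], exposure[1])
    infection = (infection[0], infection[1])
    rel_in, deg_in = _normalise(intake)
    rel_ex, deg_ex = _normalise(exposure)
    rel_inf, deg_inf = _normalise(infection)
    return RateBundle(
        intake=intake,
        exposure=exposure,
        infection=infection,
        relative_intake=rel_in,
        relative_exposure=rel_ex,
        relative_infection=rel_inf,
        degenerate=(deg_in, deg_ex, deg_inf),
    )
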