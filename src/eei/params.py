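"""Parameter and state containers for the predator–two-prey–parasite community.

The model couples Lotka–Volterra ecology (one predator, two logistically
growing prey) with quantitative-genetic evolution of two predator traits: an
ecomorphological trait ``x`` that sets prey-specific attack rates through a
Gaussian kernel, and an immune trait ``y`` that sets susceptibility to each
prey's trophically transmitted parasite through an inverted Gaussian kernel.
Trait means evolve by the Lande gradient equation; the genetic variances
``sigma_xG2`` and ``sigma_yG2`` are the evolutionary rate constants.

All containers are frozen dataclasses validated at construction time.  The
flat ASCII field naming used for serialization (``r1``, ``zeta1``,
``sigma_x2`` …) transliterates the standard symbols of the model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParameterError",
    "PreyParasitePair",
    "PredatorParams",
    "Community",
    "FullState",
    "random_community",
]


class ParameterError(ValueError):
    """A parameter set violates a model invariant; the message names the rule."""


def _require(condition: bool, rule: str) -> None:
    if not condition:
        raise ParameterError(f"parameter invariant violated: {rule}")


@dataclass(frozen=True)
class PreyParasitePair:
    """One prey species together with its trophically transmitted parasite.

    Parameters
    ----------
    r : float
        Intrinsic prey growth rate (1/time).
    K : float
        Prey carrying capacity (density).
    alpha : float
        Maximal attack rate of the predator on this prey (1/(density·time)).
    theta : float
        Predator trait value that maximises the attack rate (trait units).
    zeta : float
        Width of the Gaussian attack kernel; a small ``zeta`` means a strong
        foraging trade-off (specialisation strongly favoured).
    b : float
        Conversion efficiency (predator offspring per prey consumed).
    c : float
        Fraction of this prey's population infected with its parasite.
    m : float
        Maximal parasite-induced fecundity loss (same units as ``b``).
    beta : float
        Maximal susceptibility to the parasite (attained far from ``phi``).
    gamma : float
        Minimal susceptibility (attained at ``y == phi``).
    phi : float
        Immune trait value that minimises susceptibility (trait units).
    tau : float
        Width of the susceptibility kernel; small ``tau`` = strong immune
        trade-off.
    """

    r: float = 1.0
    K: float = 1.0
    alpha: float = 2.0
    theta: float = 0.0
    zeta: float = 1.0
    b: float = 1.0
    c: float = 0.5
    m: float = 0.5
    beta: float = 1.0
    gamma: float = 0.1
    phi: float = 0.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        _require(self.r > 0, "r>0")
        _require(self.K > 0, "K>0")
        _require(self.alpha > 0, "alpha>0")
        _require(self.zeta > 0, "zeta>0")
        _require(self.tau > 0, "tau>0")
        _require(0.0 <= self.c <= 1.0, "0<=c<=1")
        _require(self.m >= 0, "m>=0")
        _require(self.b > 0, "b>0")
        _require(
            0.0 <= self.gamma < self.beta <= 1.0, "0<=gamma<beta<=1"
        )

    def replace(self, **changes) -> "PreyParasitePair":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PredatorParams:
    """Predator demography and the variance decomposition of both traits.

    Environmental variances are derived quantities (``sigma_x2 - sigma_xG2``)
    and never stored independently.
    """

    d: float = 0.1
    sigma_x2: float = 0.01
    sigma_xG2: float = 0.005
    sigma_y2: float = 0.01
    sigma_yG2: float = 0.005

    def __post_init__(self) -> None:
        _require(self.d > 0, "d>0")
        _require(
            0.0 <= self.sigma_xG2 <= self.sigma_x2, "0<=sigma_xG2<=sigma_x2"
        )
        _require(
            0.0 <= self.sigma_yG2 <= self.sigma_y2, "0<=sigma_yG2<=sigma_y2"
        )

    @property
    def sigma_xE2(self) -> float:
        """Environmental variance of the foraging trait."""
        return self.sigma_x2 - self.sigma_xG2

    @property
    def sigma_yE2(self) -> float:
        """Environmental variance of the immune trait."""
        return self.sigma_y2 - self.sigma_yG2

    @property
    def h_x2(self) -> float:
        """Heritability of the foraging trait, sigma_xG2 / sigma_x2."""
        return self.sigma_xG2 / self.sigma_x2

    @property
    def h_y2(self) -> float:
        """Heritability of the immune trait, sigma_yG2 / sigma_y2."""
        return self.sigma_yG2 / self.sigma_y2

    def replace(self, **changes) -> "PredatorParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class Community:
    """Two prey–parasite pairs sharing one evolving predator.

    Prey are indexed 1 and 2 throughout all outputs; ``pair(i)`` accepts the
    1-based index used in the model notation.
    """

    prey: tuple[PreyParasitePair, PreyParasitePair]
    predator: PredatorParams

    def __post_init__(self) -> None:
        _require(len(self.prey) == 2, "exactly two prey entries")

    @property
    def prey1(self) -> PreyParasitePair:
        return self.prey[0]

    @property
    def prey2(self) -> PreyParasitePair:
        return self.prey[1]

    def pair(self, i: int) -> PreyParasitePair:
        if i not in (1, 2):
            raise IndexError("prey index must be 1 or 2")
        return self.prey[i - 1]

    def replace_prey(self, i: int, **changes) -> "Community":
        new = list(self.prey)
        new[i - 1] = new[i - 1].replace(**changes)
        return Community(prey=(new[0], new[1]), predator=self.predator)

    def replace_predator(self, **changes) -> "Community":
        return Community(prey=self.prey, predator=self.predator.replace(**changes))

    def with_widths(
        self, zeta: float | None = None, tau: float | None = None
    ) -> "Community":
        """Return a copy with the trade-off widths of *both* prey replaced."""
        changes = {}
        if zeta is not None:
            changes["zeta"] = zeta
        if tau is not None:
            changes["tau"] = tau
        new = tuple(p.replace(**changes) for p in self.prey)
        return Community(prey=new, predator=self.predator)

    # -- flat serialization (field names transliterate the model symbols) --

    def to_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for i, p in enumerate(self.prey, start=1):
            for name in (
                "r", "K", "alpha", "theta", "zeta", "b",
                "c", "m", "beta", "gamma", "phi", "tau",
            ):
                out[f"{name}{i}"] = float(getattr(p, name))
        for name in ("d", "sigma_x2", "sigma_xG2", "sigma_y2", "sigma_yG2"):
            out[name] = float(getattr(self.predator, name))
        return out

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "Community":
        data = dict(data)
        prey = []
        for i in (1, 2):
            kwargs = {}
            for name in (
                "r", "K", "alpha", "theta", "zeta", "b",
                "c", "m", "beta", "gamma", "phi", "tau",
            ):
                key = f"{name}{i}"
                if key in data:
                    kwargs[name] = float(data.pop(key))
            prey.append(PreyParasitePair(**kwargs))
        pred_kwargs = {}
        for name in ("d", "sigma_x2", "sigma_xG2", "sigma_y2", "sigma_yG2"):
            if name in data:
                pred_kwargs[name] = float(data.pop(name))
        if data:
            unknown = ", ".join(sorted(data))
            raise ParameterError(f"unknown community fields: {unknown}")
        return cls(prey=(prey[0], prey[1]), predator=PredatorParams(**pred_kwargs))


@dataclass(frozen=True)
class FullState:
    """The five dynamical variables (P, N1, N2, xbar, ybar).

    Densities are non-negative; trait means are unbounded reals.
    """

    P: float
    N1: float
    N2: float
    xbar: float
    ybar: float

    def __post_init__(self) -> None:
        _require(self.P >= 0, "P>=0")
        _require(self.N1 >= 0, "N1>=0")
        _require(self.N2 >= 0, "N2>=0")

    def to_array(self) -> np.ndarray:
        return np.array([self.P, self.N1, self.N2, self.xbar, self.ybar])

    @classmethod
    def from_array(cls, u) -> "FullState":
        P, N1, N2, xbar, ybar = (float(v) for v in u)
        return cls(P=P, N1=N1, N2=N2, xbar=xbar, ybar=ybar)


STATE_COLUMNS = ("P", "N1", "N2", "xbar", "ybar")


def random_community(rng: np.random.Generator, h_min: float = 0.1,
                     h_max: float = 0.9) -> Community:
    """Draw a random but biologically sensible community.

    Used by randomized consistency checks (quadrature, finite-difference and
    attractor-versus-simulation comparisons).  Trait optima are separated so
    the two prey occupy distinct niches; widths span strong to weak
    trade-offs.
    """

    def pair(theta: float, phi: float) -> PreyParasitePair:
        gamma = rng.uniform(0.0, 0.3)
        beta = rng.uniform(gamma + 0.3, 1.0)
        return PreyParasitePair(
            r=rng.uniform(0.5, 2.0),
            K=rng.uniform(0.5, 2.0),
            alpha=rng.uniform(1.0, 4.0),
            theta=theta,
            zeta=rng.uniform(0.05, 1.5),
            b=rng.uniform(0.5, 1.5),
            c=rng.uniform(0.05, 0.95),
            m=rng.uniform(0.05, 0.95),
            beta=beta,
            gamma=gamma,
            phi=phi,
            tau=rng.uniform(0.05, 1.5),
        )

    theta1 = rng.uniform(-1.0, -0.2)
    theta2 = rng.uniform(0.2, 1.0)
    phi1 = rng.uniform(-1.0, -0.2)
    phi2 = rng.uniform(0.2, 1.0)
    sigma_x2 = rng.uniform(1e-4, 0.25)
    sigma_y2 = rng.uniform(1e-4, 0.25)
    predator = PredatorParams(
        d=rng.uniform(0.05, 0.5),
        sigma_x2=sigma_x2,
        sigma_xG2=rng.uniform(h_min, h_max) * sigma_x2,
        sigma_y2=sigma_y2,
        sigma_yG2=rng.uniform(h_min, h_max) * sigma_y2,
    )
    return Community(prey=(pair(theta1, phi1), pair(theta2, phi2)),
                     predator=predator)
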