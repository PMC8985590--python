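"""Default parameter sets, named regime fixtures, and config file round-trips.

The package ships a documented symmetric baseline: two mirror-image prey at
trait optima ±1/2 with unit growth rates and carrying capacities, a predator
that persists on either prey alone, and phenotypic variances small relative to
the niche separation.  Trade-off widths of 0.01 (strong) and 1 (weak) realise
the four qualitative regimes of the model; the weak/strong classification of
every fixture is verified by the unimodality conditions in ``core``.

Config files are TOML or JSON with flat ASCII field names transliterating the
model symbols (``r1``, ``zeta1``, ``sigma_x2`` …).
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .chaos import LyapunovConfig
from .dynamics import SolverConfig
from .params import Community, ParameterError, PredatorParams, PreyParasitePair

__all__ = [
    "default_community",
    "chaos_reference_community",
    "fixture_regimes",
    "RunConfig",
    "load_config",
    "save_config",
    "load_community",
    "save_community",
]

#: Baseline symmetric parameter values; trade-off widths are supplied per regime.
BASELINE = dict(
    r=1.0, K=1.0, alpha=2.0, b=1.0, c=0.5, m=0.5, beta=1.0, gamma=0.1,
    theta_half_separation=0.5, phi_half_separation=0.5,
    d=0.1, sigma_x2=0.01, sigma_y2=0.01, heritability=0.5,
)


def default_community(
    zeta: float = 1.0,
    tau: float = 1.0,
    sigma_x2: float = 0.01,
    sigma_y2: float = 0.01,
    h_x2: float = 0.5,
    h_y2: float = 0.5,
    c: float = 0.5,
    m: float = 0.5,
) -> Community:
    """The symmetric baseline community with the given trade-off widths."""
    def prey(sign: float) -> PreyParasitePair:
        return PreyParasitePair(
            r=BASELINE["r"], K=BASELINE["K"], alpha=BASELINE["alpha"],
            theta=sign * BASELINE["theta_half_separation"], zeta=zeta,
            b=BASELINE["b"], c=c, m=m,
            beta=BASELINE["beta"], gamma=BASELINE["gamma"],
            phi=sign * BASELINE["phi_half_separation"], tau=tau,
        )

    predator = PredatorParams(
        d=BASELINE["d"],
        sigma_x2=sigma_x2, sigma_xG2=h_x2 * sigma_x2,
        sigma_y2=sigma_y2, sigma_yG2=h_y2 * sigma_y2,
    )
    return Community(prey=(prey(-1.0), prey(+1.0)), predator=predator)


def chaos_reference_community(tau: float = 0.3, h_y2: float = 0.9) -> Community:
    """The package's chaotic reference regime.

    A high-productivity community (large carrying capacities and attack rates,
    so prey sit far below carrying capacity and the predator–prey interaction
    is weakly damped) with prevalent, virulent parasites and a fast-evolving
    immune trait.  Strong immune trade-offs (tau of order 0.01–0.2) leave
    every trait equilibrium stable; from tau about 0.3 upward the equilibria
    destabilise and the attractor is cyclic or chaotic, increasingly so at
    high immune heritability.  The default (tau = 0.3, immune heritability
    0.9) has a clearly positive maximal Lyapunov exponent.
    """
    def prey(sign: float) -> PreyParasitePair:
        return PreyParasitePair(
            r=0.9, K=4.0, alpha=9.0, theta=0.5 * sign, zeta=0.25,
            b=0.7, c=0.9, m=0.65, beta=1.0, gamma=0.13,
            phi=0.5 * sign, tau=tau,
        )

    predator = PredatorParams(
        d=0.3, sigma_x2=0.1, sigma_xG2=0.065,
        sigma_y2=0.5, sigma_yG2=h_y2 * 0.5,
    )
    return Community(prey=(prey(-1.0), prey(+1.0)), predator=predator)


def fixture_regimes(genetic_values_are_sd: bool = False) -> dict[str, Community]:
    """Named parameter sets realising the model's qualitative regimes.

    The 2x2 grid crosses strong/weak foraging (zeta = 0.01 / 1) with
    strong/weak immune (tau = 0.01 / 1) trade-offs.  The asymmetric-rate
    variants give one trait a much larger genetic variance than the other
    (0.005 versus 0.25; ``genetic_values_are_sd=True`` squares-down these
    numbers, treating them as standard deviations instead).  The
    weak-selection variant reduces parasite prevalence and virulence to
    m = c = 0.1.  The chaos exemplar (tau = 0.3, immune heritability 0.9,
    large immune phenotypic variance) sits in the cyclic/chaotic regime of
    the full system.
    """
    g_slow, g_fast = (0.005, 0.25)
    if genetic_values_are_sd:
        g_slow, g_fast = g_slow**2, g_fast**2

    fixtures = {
        "strong_foraging_strong_immune": default_community(zeta=0.01, tau=0.01),
        "strong_foraging_weak_immune": default_community(zeta=0.01, tau=1.0),
        "weak_foraging_strong_immune": default_community(zeta=1.0, tau=0.01),
        "weak_foraging_weak_immune": default_community(zeta=1.0, tau=1.0),
        # timescale asymmetry: one trait's genetic variance dwarfs the other's.
        # The larger genetic variance forces the matching phenotypic variance
        # up (variance components must nest), with heritability 1 there.
        "slow_foraging_fast_immune": default_community(
            zeta=0.01, tau=0.01,
            sigma_x2=max(0.01, g_slow), sigma_y2=max(0.01, g_fast),
        ).replace_predator(sigma_xG2=g_slow, sigma_yG2=g_fast),
        "fast_foraging_slow_immune": default_community(
            zeta=0.01, tau=0.01,
            sigma_x2=max(0.01, g_fast), sigma_y2=max(0.01, g_slow),
        ).replace_predator(sigma_xG2=g_fast, sigma_yG2=g_slow),
        "weak_selection": default_community(zeta=0.01, tau=0.01, c=0.1, m=0.1),
        "chaos_exemplar": chaos_reference_community(tau=0.3, h_y2=0.9),
    }
    return fixtures


# ---------------------------------------------------------------------------
# run configuration and file round-trips
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Everything needed to rerun an analysis: community, solver settings,
    Lyapunov horizons and the top-level seed."""

    community: Community
    solver: SolverConfig = dc_field(default_factory=SolverConfig)
    lyapunov: LyapunovConfig = dc_field(default_factory=LyapunovConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "community": self.community.to_dict(),
            "solver": dataclasses.asdict(self.solver),
            "lyapunov": dataclasses.asdict(self.lyapunov),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "community" in data:
            community = Community.from_dict(data.pop("community"))
        elif "r1" in data:
            # a bare community parameter file: wrap it with default settings
            community_keys = set(default_community().to_dict())
            flat = {k: data.pop(k) for k in list(data) if k in community_keys}
            community = Community.from_dict(flat)
        else:
            raise ParameterError("config is missing the [community] section")
        solver = SolverConfig(**data.pop("solver", {}))
        lyapunov = LyapunovConfig(**data.pop("lyapunov", {}))
        seed = int(data.pop("seed", 0))
        if data:
            raise ParameterError(
                "unknown config sections: " + ", ".join(sorted(data))
            )
        return cls(community=community, solver=solver, lyapunov=lyapunov,
                   seed=seed)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(float(v)) if isinstance(v, float) else str(v)
    if isinstance(v, str):
        return json.dumps(v)
    raise TypeError(f"cannot serialise {type(v)} to TOML")


def _toml_dumps(data: dict) -> str:
    """Minimal TOML emitter for one level of tables with scalar values."""
    lines = []
    scalars = {k: v for k, v in data.items() if not isinstance(v, dict)}
    tables = {k: v for k, v in data.items() if isinstance(v, dict)}
    for k, v in scalars.items():
        lines.append(f"{k} = {_toml_value(v)}")
    for name, table in tables.items():
        lines.append("")
        lines.append(f"[{name}]")
        for k, v in table.items():
            lines.append(f"{k} = {_toml_value(v)}")
    return "\n".join(lines) + "\n"


def _read_file(path: Path) -> dict:
    if path.suffix == ".json":
        return json.loads(path.read_text())
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def load_config(path) -> RunConfig:
    """Load and validate a run configuration (TOML or JSON by suffix).

    All parameter invariants are enforced at load time; violations raise
    :class:`~eei.params.ParameterError` naming the violated rule.
    """
    return RunConfig.from_dict(_read_file(Path(path)))


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(_toml_dumps(data))


def load_community(path) -> Community:
    """Load a bare community parameter file (flat fields, TOML or JSON)."""
    data = _read_file(Path(path))
    if "community" in data:
        data = data["community"]
    return Community.from_dict(data)


def save_community(community: Community, path) -> None:
    path = Path(path)
    data = community.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(_toml_dumps(data))
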