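"""Lyapunov exponents, chaos maps and extrema diagrams for the full system.

The maximal Lyapunov exponent is estimated by the classic single-tangent
method: the variational equations are integrated along the reference
trajectory and the tangent vector is renormalised at fixed intervals, the
average log stretch giving the exponent.  A positive exponent marks chaotic
eco-evolutionary dynamics, a negative one a stable attractor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import make_rhs, make_tangent_rhs
from .params import Community, FullState
from .reduction import select_attractor

__all__ = [
    "LyapunovConfig",
    "LyapunovResult",
    "ChaosMap",
    "ExtremaDiagram",
    "lyapunov_exponent",
    "chaos_map",
    "extrema_diagram",
    "perturbed_coexistence_state",
]


@dataclass(frozen=True)
class LyapunovConfig:
    """Horizons and tolerances for the tangent-vector estimator.

    ``transient`` time units are discarded before accumulation starts;
    ``total_time`` is the accumulation window; the tangent is renormalised
    every ``renorm_interval``.  ``converged`` requires the running estimate to
    drift less than ``max(conv_rtol * |estimate|, conv_atol)`` over its last
    quartile.
    """

    transient: float = 500.0
    total_time: float = 5000.0
    renorm_interval: float = 1.0
    rtol: float = 1e-8
    atol: float = 1e-10
    conv_rtol: float = 0.05
    conv_atol: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_time <= 0 or self.renorm_interval <= 0:
            raise ValueError("total_time and renorm_interval must be positive")


@dataclass
class LyapunovResult:
    exponent: float
    transient_discarded: float
    total_time: float
    renorm_interval: float
    convergence_series: np.ndarray
    converged: bool
    final_state: np.ndarray | None = None


def lyapunov_exponent(
    community: Community,
    initial: FullState | np.ndarray,
    config: LyapunovConfig | None = None,
    v0: np.ndarray | None = None,
) -> LyapunovResult:
    """Maximal Lyapunov exponent of the full five-dimensional system.

    ``v0`` seeds the tangent direction (a random unit vector by default; any
    generic direction converges to the leading exponent).  Non-convergence is
    reported through ``converged=False``, never silently.
    """
    config = config or LyapunovConfig()
    u = (initial.to_array() if isinstance(initial, FullState)
         else np.asarray(initial, dtype=float).copy())

    rhs = make_rhs(community)
    if config.transient > 0:
        sol = solve_ivp(rhs, (0.0, config.transient), u, method="RK45",
                        rtol=config.rtol, atol=config.atol)
        if sol.status != 0:
            raise RuntimeError(f"transient integration failed: {sol.message}")
        u = sol.y[:, -1]

    if v0 is None:
        rng = np.random.default_rng(config.seed)
        v = rng.normal(size=5)
    else:
        v = np.asarray(v0, dtype=float).copy()
    v /= np.linalg.norm(v)

    g = make_tangent_rhs(community)
    n_steps = int(round(config.total_time / config.renorm_interval))
    logs = np.empty(n_steps)
    t = 0.0
    w = np.concatenate([u, v])
    for k in range(n_steps):
        sol = solve_ivp(
            g, (t, t + config.renorm_interval), w, method="RK45",
            rtol=config.rtol, atol=config.atol,
        )
        if sol.status != 0:
            raise RuntimeError(f"variational integration failed: {sol.message}")
        w = sol.y[:, -1]
        t = float(sol.t[-1])
        norm = np.linalg.norm(w[5:])
        logs[k] = math.log(norm)
        w[5:] /= norm

    elapsed = (np.arange(1, n_steps + 1)) * config.renorm_interval
    series = np.cumsum(logs) / elapsed
    exponent = float(series[-1])
    tail = series[3 * n_steps // 4:]
    drift = float(np.max(np.abs(tail - exponent))) if tail.size else math.inf
    converged = drift < max(config.conv_rtol * abs(exponent), config.conv_atol)
    return LyapunovResult(
        exponent=exponent,
        transient_discarded=config.transient,
        total_time=config.total_time,
        renorm_interval=config.renorm_interval,
        convergence_series=series,
        converged=converged,
        final_state=w[:5],
    )


def perturbed_coexistence_state(
    community: Community, offset: tuple[float, float] = (0.05, 0.05)
) -> FullState:
    """Shared initial condition for parameter sweeps.

    The ecological coexistence state at the trait-space midpoint, with the
    trait means displaced by a fixed ``offset`` so sweeps do not start exactly
    on a symmetry axis.
    """
    p1, p2 = community.prey
    x_mid = 0.5 * (p1.theta + p2.theta)
    y_mid = 0.5 * (p1.phi + p2.phi)
    eq = select_attractor(x_mid, y_mid, community)
    P = eq.P_star if eq.P_star > 0 else 0.1
    N1 = eq.N1_star if eq.N1_star > 0 else 0.1 * p1.K
    N2 = eq.N2_star if eq.N2_star > 0 else 0.1 * p2.K
    return FullState(P=P, N1=N1, N2=N2,
                     xbar=x_mid + offset[0], ybar=y_mid + offset[1])


def _with_cell(community: Community, tau: float, value: float,
               axis_mode: str) -> Community:
    com = community.with_widths(tau=tau)
    pred = com.predator
    if axis_mode == "h_y2":
        sigma_yG2 = value * pred.sigma_y2
    elif axis_mode == "sigma_yG2":
        sigma_yG2 = value
    else:
        raise ValueError("axis_mode must be 'h_y2' or 'sigma_yG2'")
    return com.replace_predator(sigma_yG2=sigma_yG2)


@dataclass
class ChaosMap:
    """Grid of maximal Lyapunov exponents over (immune genetics x tau)."""

    axis1: np.ndarray          # heritability or genetic-variance grid
    axis2: np.ndarray          # tau grid
    axis1_mode: str
    exponents: np.ndarray      # shape (len(axis1), len(axis2)); NaN = failed
    converged: np.ndarray
    failures: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a1 in enumerate(self.axis1):
            for j, a2 in enumerate(self.axis2):
                rows.append(
                    {
                        self.axis1_mode: a1,
                        "tau": a2,
                        "exponent": self.exponents[i, j],
                        "converged": bool(self.converged[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def chaos_map(
    community: Community,
    axis1_values,
    axis2_values,
    config: LyapunovConfig | None = None,
    axis1_mode: str = "h_y2",
) -> ChaosMap:
    """Lyapunov exponents over a (immune genetics x immune trade-off) grid.

    ``axis1_mode`` selects whether axis 1 is the immune heritability
    (``sigma_yG2 = h_y2 * sigma_y2``) or the genetic variance directly.  All
    cells share the same initial-condition policy
    (:func:`perturbed_coexistence_state`); per-cell failures are recorded and
    the map is still returned.
    """
    config = config or LyapunovConfig()
    a1 = np.asarray(axis1_values, dtype=float)
    a2 = np.asarray(axis2_values, dtype=float)
    if a1.size == 0 or a2.size == 0:
        raise ValueError("axis grids must be non-empty")
    exps = np.full((a1.size, a2.size), np.nan)
    conv = np.zeros((a1.size, a2.size), dtype=bool)
    failures = []
    for i, val in enumerate(a1):
        for j, tau in enumerate(a2):
            try:
                com = _with_cell(community, float(tau), float(val), axis1_mode)
                init = perturbed_coexistence_state(com)
                res = lyapunov_exponent(com, init, config)
                exps[i, j] = res.exponent
                conv[i, j] = res.converged
            except Exception as exc:  # per-cell failure, map still returned
                failures.append((float(val), float(tau), repr(exc)))
    return ChaosMap(axis1=a1, axis2=a2, axis1_mode=axis1_mode,
                    exponents=exps, converged=conv, failures=failures)


@dataclass
class ExtremaDiagram:
    """Local extrema of the diet trait after a transient, per tau value."""

    tau_values: np.ndarray
    extrema: list[np.ndarray]
    h_y2: float
    transient: float
    window: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tau, ext in zip(self.tau_values, self.extrema):
            for v in ext:
                rows.append({"tau": tau, "extremum": v})
        return pd.DataFrame(rows, columns=["tau", "extremum"])


def extrema_diagram(
    community: Community,
    tau_values,
    h_y2: float,
    config: LyapunovConfig | None = None,
    sample_dt: float = 0.2,
) -> ExtremaDiagram:
    """Bifurcation-style diagram: post-transient local extrema of ``xbar``.

    A fixed point contributes a single value, a limit cycle two, and chaos a
    set that keeps growing with the observation window.
    """
    config = config or LyapunovConfig()
    taus = np.asarray(tau_values, dtype=float)
    rhs_horizon = config.transient + config.total_time
    out = []
    for tau in taus:
        com = _with_cell(community, float(tau), h_y2, "h_y2")
        init = perturbed_coexistence_state(com)
        rhs = make_rhs(com)
        t_eval = np.arange(config.transient, rhs_horizon, sample_dt)
        sol = solve_ivp(rhs, (0.0, rhs_horizon), init.to_array(),
                        method="RK45", rtol=config.rtol, atol=config.atol,
                        t_eval=t_eval)
        if sol.status != 0:
            out.append(np.array([]))
            continue
        x = sol.y[3]
        interior = x[1:-1]
        is_max = (interior > x[:-2]) & (interior > x[2:])
        is_min = (interior < x[:-2]) & (interior < x[2:])
        ext = interior[is_max | is_min]
        if ext.size == 0:  # equilibrium: the single asymptotic value
            ext = np.array([x[-1]])
        out.append(ext)
    return ExtremaDiagram(tau_values=taus, extrema=out, h_y2=h_y2,
                          transient=config.transient, window=config.total_time)
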