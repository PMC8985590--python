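"""The full five-dimensional coupled ecological + trait dynamics.

State ordering is ``(P, N1, N2, xbar, ybar)`` throughout.  Densities follow
Lotka–Volterra ecology driven by the phenotype-averaged rates; trait means
follow the Lande equation, each gradient scaled by its genetic variance.

The right-hand side and its analytic Jacobian are generated as closures over
plain floats (``make_rhs`` / ``make_rhs_jacobian`` / ``make_tangent_rhs``) so
that long integrations — Lyapunov estimation in particular — avoid attribute
lookups and array packing in the hot loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import Community, FullState, STATE_COLUMNS

__all__ = [
    "SolverConfig",
    "Trajectory",
    "IntegrationError",
    "full_vector_field",
    "jacobian_full",
    "make_rhs",
    "make_rhs_jacobian",
    "make_tangent_rhs",
    "simulate_full",
]


class IntegrationError(RuntimeError):
    """Integration failed; ``last_state`` holds the last finite state reached."""

    def __init__(self, message: str, t: float, last_state: np.ndarray):
        super().__init__(message)
        self.t = t
        self.last_state = last_state


@dataclass(frozen=True)
class SolverConfig:
    """Tolerances and horizon for trajectory integration.

    ``extinction_threshold`` is the density below which a population is
    clamped to exactly zero (the boundary faces are invariant, so a clamped
    population stays extinct).
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    t_end: float = 1000.0
    max_step: float = math.inf
    extinction_threshold: float = 1e-12

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("rtol and atol must be positive")
        if self.extinction_threshold < 0:
            raise ValueError("extinction_threshold must be >= 0")


@dataclass
class Trajectory:
    """A solved trajectory of the full system."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 5)
    events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_COLUMNS))
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        """Trajectory plus solver metadata and event log as one JSON document."""
        import json

        payload = {
            "meta": self.meta,
            "events": [[t, name] for t, name in self.events],
            "columns": ["t", *STATE_COLUMNS],
            "data": np.column_stack([self.times, self.states]).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @property
    def final_state(self) -> FullState:
        return FullState.from_array(self.states[-1])


def _constants(community: Community):
    """Flatten a community into plain floats for closure-based RHS functions."""
    pred = community.predator
    cs = []
    for p in community.prey:
        vx = pred.sigma_x2 + p.zeta**2
        vy = pred.sigma_y2 + p.tau**2
        cs.append(
            (
                p.r, p.K, p.theta, p.phi,
                p.alpha * p.zeta / math.sqrt(vx),   # abar prefactor
                vx,
                p.beta,
                (p.beta - p.gamma) * p.tau / math.sqrt(vy),  # Sbar dip prefactor
                vy,
                p.b, p.c * p.m,
            )
        )
    return cs, pred.d, pred.sigma_xG2, pred.sigma_yG2


def make_rhs(community: Community) -> Callable[[float, np.ndarray], list]:
    """Return ``f(t, u)`` computing the five time-derivatives."""
    (c1, c2), d, sxG, syG = _constants(community)
    r1, K1, th1, ph1, pa1, vx1, be1, ps1, vy1, b1, cm1 = c1
    r2, K2, th2, ph2, pa2, vx2, be2, ps2, vy2, b2, cm2 = c2
    exp = math.exp

    def rhs(t, u):
        P, N1, N2, xb, yb = u
        dx1 = xb - th1
        dx2 = xb - th2
        a1 = pa1 * exp(-dx1 * dx1 / (2.0 * vx1))
        a2 = pa2 * exp(-dx2 * dx2 / (2.0 * vx2))
        dy1 = yb - ph1
        dy2 = yb - ph2
        S1 = be1 - ps1 * exp(-dy1 * dy1 / (2.0 * vy1))
        S2 = be2 - ps2 * exp(-dy2 * dy2 / (2.0 * vy2))
        e1 = b1 - cm1 * S1
        e2 = b2 - cm2 * S2
        W = e1 * a1 * N1 + e2 * a2 * N2 - d
        Y1 = r1 * (1.0 - N1 / K1) - a1 * P
        Y2 = r2 * (1.0 - N2 / K2) - a2 * P
        gx = e1 * a1 * N1 * (-dx1) / vx1 + e2 * a2 * N2 * (-dx2) / vx2
        gy = (
            cm1 * a1 * N1 * (be1 - S1) * (-dy1) / vy1
            + cm2 * a2 * N2 * (be2 - S2) * (-dy2) / vy2
        )
        return [P * W, N1 * Y1, N2 * Y2, sxG * gx, syG * gy]

    return rhs


def make_rhs_jacobian(community: Community):
    """Return ``fj(u) -> (f, J)`` sharing all subexpressions.

    The Jacobian is analytic; it is exercised against central finite
    differences of the vector field in the test suite.
    """
    (c1, c2), d, sxG, syG = _constants(community)
    prey_const = (c1, c2)
    exp = math.exp

    def fj(u):
        P, N1, N2, xb, yb = u
        a = [0.0, 0.0]
        S = [0.0, 0.0]
        e = [0.0, 0.0]
        dxv = [0.0, 0.0]   # (theta_i - xb)/vx_i
        dyv = [0.0, 0.0]   # (phi_i - yb)/vy_i
        for i, (r, K, th, ph, pa, vx, be, ps, vy, b, cm) in enumerate(prey_const):
            dx = xb - th
            dy = yb - ph
            a[i] = pa * exp(-dx * dx / (2.0 * vx))
            S[i] = be - ps * exp(-dy * dy / (2.0 * vy))
            e[i] = b - cm * S[i]
            dxv[i] = -dx / vx
            dyv[i] = -dy / vy
        (r1, K1, _, _, _, vx1, be1, _, vy1, _, cm1) = c1
        (r2, K2, _, _, _, vx2, be2, _, vy2, _, cm2) = c2
        N = (N1, N2)
        W = e[0] * a[0] * N1 + e[1] * a[1] * N2 - d
        Y1 = r1 * (1.0 - N1 / K1) - a[0] * P
        Y2 = r2 * (1.0 - N2 / K2) - a[1] * P
        # selection gradients
        gx = e[0] * a[0] * N1 * dxv[0] + e[1] * a[1] * N2 * dxv[1]
        gy = (
            cm1 * a[0] * N1 * (be1 - S[0]) * dyv[0]
            + cm2 * a[1] * N2 * (be2 - S[1]) * dyv[1]
        )
        f = np.array([P * W, N1 * Y1, N2 * Y2, sxG * gx, syG * gy])

        # derivative helpers: da_i/dx = a_i*dxv_i ; dS_i/dy = -(be_i-S_i)*dyv_i
        cmv = (cm1, cm2)
        bev = (be1, be2)
        vxv = (vx1, vx2)
        vyv = (vy1, vy2)
        # dW/dx = gx ; dW/dy = gy (by construction of the gradients)
        J = np.zeros((5, 5))
        # row 0: d(P W)
        J[0, 0] = W
        J[0, 1] = P * e[0] * a[0]
        J[0, 2] = P * e[1] * a[1]
        J[0, 3] = P * gx
        J[0, 4] = P * gy
        # rows 1-2: d(N_i Y_i)
        J[1, 0] = -N1 * a[0]
        J[1, 1] = Y1 - r1 * N1 / K1
        J[1, 3] = -N1 * P * a[0] * dxv[0]
        J[2, 0] = -N2 * a[1]
        J[2, 2] = Y2 - r2 * N2 / K2
        J[2, 3] = -N2 * P * a[1] * dxv[1]
        # row 3: d(sxG * gx)
        dgx_dx = 0.0
        dgx_dy = 0.0
        for i in range(2):
            dgx_dx += e[i] * a[i] * N[i] * (dxv[i] * dxv[i] - 1.0 / vxv[i])
            dgx_dy += cmv[i] * (bev[i] - S[i]) * dyv[i] * a[i] * N[i] * dxv[i]
        J[3, 1] = sxG * e[0] * a[0] * dxv[0]
        J[3, 2] = sxG * e[1] * a[1] * dxv[1]
        J[3, 3] = sxG * dgx_dx
        J[3, 4] = sxG * dgx_dy
        # row 4: d(syG * gy)
        dgy_dx = 0.0
        dgy_dy = 0.0
        for i in range(2):
            dgy_dx += cmv[i] * a[i] * dxv[i] * N[i] * (bev[i] - S[i]) * dyv[i]
            dgy_dy += cmv[i] * a[i] * N[i] * (bev[i] - S[i]) * (
                dyv[i] * dyv[i] - 1.0 / vyv[i]
            )
        J[4, 1] = syG * cmv[0] * a[0] * (bev[0] - S[0]) * dyv[0]
        J[4, 2] = syG * cmv[1] * a[1] * (bev[1] - S[1]) * dyv[1]
        J[4, 3] = syG * dgy_dx
        J[4, 4] = syG * dgy_dy
        return f, J

    return fj


def make_tangent_rhs(community: Community):
    """Return ``g(t, w)`` for the 10-dimensional variational system.

    ``w`` stacks the state ``u`` and a tangent vector ``v``; the tangent
    evolves as ``dv/dt = J(u) v`` along the reference trajectory.
    """
    fj = make_rhs_jacobian(community)

    def g(t, w):
        u = w[:5]
        v = w[5:]
        f, J = fj(u)
        return np.concatenate([f, J @ v])

    return g


def full_vector_field(state, community: Community) -> np.ndarray:
    """The five time-derivatives at ``state`` (a :class:`FullState` or array)."""
    u = state.to_array() if isinstance(state, FullState) else np.asarray(state, float)
    return np.asarray(make_rhs(community)(0.0, u))


def jacobian_full(state, community: Community) -> np.ndarray:
    """Analytic 5x5 Jacobian of the full vector field at ``state``."""
    u = state.to_array() if isinstance(state, FullState) else np.asarray(state, float)
    _, J = make_rhs_jacobian(community)(u)
    return J


def simulate_full(
    initial: FullState | np.ndarray,
    community: Community,
    solver: SolverConfig | None = None,
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the full system with RK45 and an extinction clamp.

    Integration restarts whenever a density crosses the extinction threshold
    from above; that population is set to exactly zero (the face is invariant)
    and the event is logged.  Raises :class:`IntegrationError` on solver
    failure or non-finite states.
    """
    solver = solver or SolverConfig()
    rhs = make_rhs(community)
    u = (initial.to_array() if isinstance(initial, FullState)
         else np.asarray(initial, dtype=float).copy())
    thresh = solver.extinction_threshold
    for k in range(3):
        if 0.0 < u[k] <= thresh:
            u[k] = 0.0

    t0 = 0.0
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    events_log: list[tuple[float, str]] = []

    def density_event(k):
        def ev(t, y):
            return y[k] - thresh
        ev.terminal = True
        ev.direction = -1.0
        return ev

    while True:
        active = [k for k in range(3) if u[k] > 0.0]
        evs = [density_event(k) for k in active]
        if t_eval is not None:
            chunk_eval = t_eval[(t_eval >= t0) & (t_eval <= solver.t_end)]
            if len(chunk_eval) == 0 or chunk_eval[0] > t0:
                chunk_eval = np.concatenate([[t0], chunk_eval])
        else:
            chunk_eval = None
        sol = solve_ivp(
            rhs,
            (t0, solver.t_end),
            u,
            method="RK45",
            rtol=solver.rtol,
            atol=solver.atol,
            max_step=solver.max_step,
            events=evs,
            t_eval=chunk_eval,
        )
        if sol.status == -1 or not np.all(np.isfinite(sol.y)):
            last = sol.y[:, -1] if sol.y.size else u
            raise IntegrationError(
                f"integration failed at t={sol.t[-1] if sol.t.size else t0}: "
                f"{sol.message}",
                t=float(sol.t[-1]) if sol.t.size else t0,
                last_state=np.asarray(last),
            )
        ts.append(sol.t)
        ys.append(sol.y)
        if sol.status == 1:  # extinction event
            t_ev = float(sol.t[-1])
            u = sol.y[:, -1].copy()
            for idx, k in enumerate(active):
                if sol.t_events[idx].size:
                    u[k] = 0.0
                    events_log.append((t_ev, f"extinction:{STATE_COLUMNS[k]}"))
            t0 = t_ev
            if t0 >= solver.t_end:
                break
        else:
            break

    times = np.concatenate(ts)
    states = np.concatenate(ys, axis=1).T
    # drop duplicated restart points
    keep = np.ones(len(times), dtype=bool)
    keep[1:] = np.diff(times) > 0
    times = times[keep]
    states = states[keep]
    if t_eval is not None:
        requested = np.isin(times, t_eval)
        times = times[requested]
        states = states[requested]
    states[:, :3] = np.maximum(states[:, :3], 0.0)
    meta = {
        "rtol": solver.rtol,
        "atol": solver.atol,
        "t_end": solver.t_end,
        "extinction_threshold": solver.extinction_threshold,
    }
    return Trajectory(times=times, states=states, events=events_log, meta=meta)
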