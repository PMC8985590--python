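"""Two-timescale reduction: fast ecological equilibria and slow trait dynamics.

When heritabilities are small, the densities relax to an ecological attractor
while the trait means barely move.  For this model the fast subsystem is
Lotka–Volterra with logistically self-limited prey and a linear functional
response, so the attractor is always one of four equilibria: coexistence,
predator exclusion, or exclusion of one prey.  The trait means then evolve on
the slow timescale down the Lande gradient evaluated at the attractor's
densities.

This module provides the closed-form equilibria with feasibility/invasion
flags, attractor selection (with a direct-simulation fallback for degenerate
cases), the reduced two-dimensional trait vector field, and the phase-portrait
toolkit: trait-space equilibria, nullclines and separatrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .core import selection_gradients
from .dynamics import SolverConfig, _constants
from .params import Community

__all__ = [
    "EcoEquilibrium",
    "TraitEquilibrium",
    "PhasePortrait",
    "AttractorAmbiguityError",
    "ecological_equilibria",
    "select_attractor",
    "reduced_vector_field",
    "make_reduced_field",
    "find_trait_equilibria",
    "nullclines",
    "separatrices",
    "phase_portrait",
    "simulate_reduced",
    "evolve_to_equilibrium",
    "default_trait_box",
]

ECO_KINDS = (
    "coexistence",
    "predator_exclusion",
    "prey1_exclusion",
    "prey2_exclusion",
)


class AttractorAmbiguityError(RuntimeError):
    """Closed-form selection was degenerate and simulation did not settle."""


@dataclass(frozen=True)
class EcoEquilibrium:
    """One of the four fast-subsystem equilibria for fixed trait means.

    ``feasible`` means every required density is positive; ``uninvadable``
    means every absent species has negative invasion growth.  The attractor of
    the fast subsystem is the unique feasible, uninvadable candidate.
    """

    kind: str
    P_star: float
    N1_star: float
    N2_star: float
    feasible: bool
    uninvadable: bool

    @property
    def densities(self) -> tuple[float, float, float]:
        return (self.P_star, self.N1_star, self.N2_star)

    @property
    def coexistence(self) -> bool:
        return self.kind == "coexistence"


def _mean_rates(xbar: float, ybar: float, community: Community):
    """(abar_i, Sbar_i, e_i) for both prey; e_i = b_i - c_i m_i Sbar_i."""
    (c1, c2), d, _, _ = _constants(community)
    out = []
    for (r, K, th, ph, pa, vx, be, ps, vy, b, cm) in (c1, c2):
        dx = xbar - th
        dy = ybar - ph
        a = pa * math.exp(-dx * dx / (2.0 * vx))
        S = be - ps * math.exp(-dy * dy / (2.0 * vy))
        out.append((a, S, b - cm * S))
    return out, d


def ecological_equilibria(
    xbar: float, ybar: float, community: Community
) -> list[EcoEquilibrium]:
    """Closed forms for all four candidate equilibria, with flags.

    A prey whose net value to the predator ``e_i = b_i - c_i m_i Sbar_i`` is
    non-positive cannot sustain the predator alone; the corresponding
    predator–prey equilibrium is marked infeasible rather than failing.
    """
    rates, d = _mean_rates(xbar, ybar, community)
    (a1, _, e1), (a2, _, e2) = rates
    p1, p2 = community.prey
    out = []

    # predator exclusion: (0, K1, K2); invaded by the predator iff Wbar > 0
    invasion_pred = e1 * a1 * p1.K + e2 * a2 * p2.K - d
    out.append(
        EcoEquilibrium(
            kind="predator_exclusion",
            P_star=0.0,
            N1_star=p1.K,
            N2_star=p2.K,
            feasible=True,
            uninvadable=invasion_pred < 0.0,
        )
    )

    # prey-j exclusion: predator persists on prey i alone
    for kind, (prey, a, e), (a_other,) in (
        ("prey2_exclusion", (p1, a1, e1), (a2,)),
        ("prey1_exclusion", (p2, a2, e2), (a1,)),
    ):
        if e > 0.0 and a > 0.0:
            Ni = d / (e * a)
            P = (prey.r / a) * (1.0 - Ni / prey.K)
            feasible = 0.0 < Ni < prey.K and P > 0.0
        else:
            Ni, P, feasible = math.nan, math.nan, False
        other = community.prey2 if kind == "prey2_exclusion" else community.prey1
        uninvadable = feasible and (other.r - a_other * P < 0.0)
        if kind == "prey2_exclusion":
            N1s, N2s = (Ni, 0.0)
        else:
            N1s, N2s = (0.0, Ni)
        out.append(
            EcoEquilibrium(
                kind=kind,
                P_star=P if feasible else (P if math.isfinite(P) else 0.0),
                N1_star=N1s if math.isfinite(Ni) else 0.0,
                N2_star=N2s if math.isfinite(Ni) else 0.0,
                feasible=feasible,
                uninvadable=uninvadable,
            )
        )

    # coexistence: substitute N_i = K_i (1 - abar_i P / r_i) into Wbar = 0
    denom = e1 * a1**2 * p1.K / p1.r + e2 * a2**2 * p2.K / p2.r
    if denom > 0.0:
        P = (e1 * a1 * p1.K + e2 * a2 * p2.K - d) / denom
        N1 = p1.K * (1.0 - a1 * P / p1.r)
        N2 = p2.K * (1.0 - a2 * P / p2.r)
        feasible = P > 0.0 and N1 > 0.0 and N2 > 0.0
    else:
        P, N1, N2, feasible = 0.0, 0.0, 0.0, False
    out.append(
        EcoEquilibrium(
            kind="coexistence",
            P_star=P,
            N1_star=N1,
            N2_star=N2,
            feasible=feasible,
            uninvadable=feasible,  # no species is absent
        )
    )
    order = {k: i for i, k in enumerate(ECO_KINDS)}
    out.sort(key=lambda eq: order[eq.kind])
    return out


def _eco_rhs(xbar: float, ybar: float, community: Community):
    rates, d = _mean_rates(xbar, ybar, community)
    (a1, _, e1), (a2, _, e2) = rates
    p1, p2 = community.prey
    r1, K1, r2, K2 = p1.r, p1.K, p2.r, p2.K

    def rhs(t, u):
        P, N1, N2 = u
        return [
            P * (e1 * a1 * N1 + e2 * a2 * N2 - d),
            N1 * (r1 * (1.0 - N1 / K1) - a1 * P),
            N2 * (r2 * (1.0 - N2 / K2) - a2 * P),
        ]

    return rhs


def simulate_ecology(
    xbar: float,
    ybar: float,
    community: Community,
    initial: tuple[float, float, float] | None = None,
    grad_tol: float = 1e-9,
    t_max: float = 1e5,
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> tuple[np.ndarray, bool]:
    """Integrate the 3-D ecological subsystem (traits frozen) to convergence.

    Returns ``(state, converged)``; convergence is an infinity-norm bound on
    the vector field at the endpoint.
    """
    rhs = _eco_rhs(xbar, ybar, community)
    if initial is None:
        p1, p2 = community.prey
        initial = (0.05 * (p1.K + p2.K), 0.5 * p1.K, 0.5 * p2.K)
    u = np.asarray(initial, dtype=float)
    scale = max(1e-8, float(np.max(np.abs(u))))

    def make_settled(tol):
        def settled(t, y):
            return max(abs(v) for v in rhs(t, y)) - tol
        settled.terminal = True
        settled.direction = -1.0
        return settled

    # Phase 1: integrate into the attractor's basin (coarse residual target),
    # then polish with Newton — the root finder only refines the equilibrium
    # the trajectory has already committed to.
    coarse = make_settled(max(grad_tol, 1e-6 * scale))
    t0, chunk = 0.0, 500.0
    while t0 < t_max:
        t1 = min(t0 + chunk, t_max)
        sol = solve_ivp(rhs, (t0, t1), u, method="RK45", rtol=rtol, atol=atol,
                        events=coarse)
        u = sol.y[:, -1]
        t0 = float(sol.t[-1])
        if sol.status == 1:
            break
        chunk *= 2.0
    scale = max(scale, float(np.max(np.abs(u))))
    polish = root(lambda y: rhs(0.0, y), u, method="hybr",
                  options={"xtol": 1e-13})
    if (
        polish.success
        and float(np.min(polish.x)) > -1e-10
        and float(np.max(np.abs(polish.x - u))) < 0.1 * scale
    ):
        z = np.maximum(polish.x, 0.0)
        # reject saddles: a slow transit past an unstable equilibrium can
        # trigger the coarse residual event
        h = 1e-7 * scale
        J = np.empty((3, 3))
        for j in range(3):
            ep = np.zeros(3)
            ep[j] = h
            J[:, j] = (np.asarray(rhs(0.0, z + ep))
                       - np.asarray(rhs(0.0, z - ep))) / (2 * h)
        stable = float(np.max(np.real(np.linalg.eigvals(J)))) < 1e-6
        if stable and max(abs(v) for v in rhs(0.0, z)) <= grad_tol * 10:
            return z, True

    # Fallback: keep integrating to the strict residual target.
    strict = make_settled(grad_tol)
    chunk = 2000.0
    while t0 < t_max:
        t1 = min(t0 + chunk, t_max)
        sol = solve_ivp(rhs, (t0, t1), u, method="RK45", rtol=rtol, atol=atol,
                        events=strict)
        u = sol.y[:, -1]
        t0 = float(sol.t[-1])
        if sol.status == 1:
            return u, True
        chunk *= 2.0
    return u, max(abs(v) for v in rhs(0.0, u)) <= grad_tol * 10


def select_attractor(
    xbar: float, ybar: float, community: Community
) -> EcoEquilibrium:
    """The attractor of the fast ecological subsystem for fixed traits.

    With logistic prey and a linear functional response the unique feasible,
    uninvadable equilibrium is globally attracting (the system admits a
    diagonal Lyapunov function), so closed-form selection suffices away from
    measure-zero boundaries.  If zero or several candidates pass, the 3-D
    subsystem is simulated from an interior point and matched to the nearest
    candidate.
    """
    candidates = ecological_equilibria(xbar, ybar, community)
    winners = [eq for eq in candidates if eq.feasible and eq.uninvadable]
    if len(winners) == 1:
        return winners[0]
    state, converged = simulate_ecology(xbar, ybar, community)
    if not converged:
        raise AttractorAmbiguityError(
            f"degenerate attractor selection at (xbar={xbar}, ybar={ybar}) "
            "and ecological simulation did not settle"
        )
    best = min(
        candidates,
        key=lambda eq: float(np.sum((np.asarray(eq.densities) - state) ** 2)),
    )
    return best


def make_reduced_field(community: Community):
    """Build a fast ``field(xbar, ybar) -> (dxbar/dt, dybar/dt)`` closure.

    Captures all parameters as plain floats and performs closed-form attractor
    selection inline, deferring to :func:`select_attractor` (and hence the
    simulation fallback) only when the closed-form selection is degenerate.
    """
    (c1, c2), d, sxG, syG = _constants(community)
    r1, K1, th1, ph1, pa1, vx1, be1, ps1, vy1, b1, cm1 = c1
    r2, K2, th2, ph2, pa2, vx2, be2, ps2, vy2, b2, cm2 = c2
    exp = math.exp

    def field(xb: float, yb: float) -> tuple[float, float]:
        dx1 = xb - th1
        dx2 = xb - th2
        dy1 = yb - ph1
        dy2 = yb - ph2
        a1 = pa1 * exp(-dx1 * dx1 / (2.0 * vx1))
        a2 = pa2 * exp(-dx2 * dx2 / (2.0 * vx2))
        S1 = be1 - ps1 * exp(-dy1 * dy1 / (2.0 * vy1))
        S2 = be2 - ps2 * exp(-dy2 * dy2 / (2.0 * vy2))
        e1 = b1 - cm1 * S1
        e2 = b2 - cm2 * S2

        winners = []
        if e1 * a1 * K1 + e2 * a2 * K2 - d < 0.0:
            winners.append((0.0, K1, K2))
        if e1 > 0.0 and a1 > 0.0:
            N1 = d / (e1 * a1)
            if 0.0 < N1 < K1:
                P = (r1 / a1) * (1.0 - N1 / K1)
                if r2 - a2 * P < 0.0:
                    winners.append((P, N1, 0.0))
        if e2 > 0.0 and a2 > 0.0:
            N2 = d / (e2 * a2)
            if 0.0 < N2 < K2:
                P = (r2 / a2) * (1.0 - N2 / K2)
                if r1 - a1 * P < 0.0:
                    winners.append((P, 0.0, N2))
        denom = e1 * a1 * a1 * K1 / r1 + e2 * a2 * a2 * K2 / r2
        if denom > 0.0 and (a1 > 0.0 or a2 > 0.0):
            P = (e1 * a1 * K1 + e2 * a2 * K2 - d) / denom
            N1 = K1 * (1.0 - a1 * P / r1)
            N2 = K2 * (1.0 - a2 * P / r2)
            if P > 0.0 and N1 > 0.0 and N2 > 0.0:
                winners.append((P, N1, N2))
        if len(winners) == 1:
            _, N1s, N2s = winners[0]
        else:
            eq = select_attractor(xb, yb, community)
            N1s, N2s = eq.N1_star, eq.N2_star

        gx = e1 * a1 * N1s * (-dx1) / vx1 + e2 * a2 * N2s * (-dx2) / vx2
        gy = (
            cm1 * a1 * N1s * (be1 - S1) * (-dy1) / vy1
            + cm2 * a2 * N2s * (be2 - S2) * (-dy2) / vy2
        )
        return (sxG * gx, syG * gy)

    return field


def reduced_vector_field(
    xbar: float, ybar: float, community: Community
) -> tuple[float, float]:
    """Slow trait dynamics: Lande gradients at the fast attractor's densities,
    scaled by the genetic variances."""
    eq = select_attractor(xbar, ybar, community)
    gx, gy = selection_gradients(xbar, ybar, eq.N1_star, eq.N2_star, community)
    pred = community.predator
    return (pred.sigma_xG2 * gx, pred.sigma_yG2 * gy)


# ---------------------------------------------------------------------------
# phase-portrait toolkit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitEquilibrium:
    """A root of the reduced trait vector field with its local classification."""

    xbar_star: float
    ybar_star: float
    eigenvalues: tuple[complex, complex]
    stability: str  # stable | saddle | unstable | degenerate
    basin_id: str = ""


@dataclass
class PhasePortrait:
    """Nullclines, equilibria and separatrices of the reduced system."""

    x_nullcline: list[np.ndarray] = field(default_factory=list)
    y_nullcline: list[np.ndarray] = field(default_factory=list)
    equilibria: list[TraitEquilibrium] = field(default_factory=list)
    separatrices: list[np.ndarray] = field(default_factory=list)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(curves, equilibria) as tidy tables."""
        rows = []
        for label, curves in (
            ("x_nullcline", self.x_nullcline),
            ("y_nullcline", self.y_nullcline),
            ("separatrix", self.separatrices),
        ):
            for j, curve in enumerate(curves):
                for x, y in curve:
                    rows.append((f"{label}_{j}", x, y))
        curves_df = pd.DataFrame(rows, columns=["curve_id", "xbar", "ybar"])
        eq_df = pd.DataFrame(
            [
                {
                    "xbar_star": e.xbar_star,
                    "ybar_star": e.ybar_star,
                    "stability": e.stability,
                    "re_lambda1": e.eigenvalues[0].real,
                    "im_lambda1": e.eigenvalues[0].imag,
                    "re_lambda2": e.eigenvalues[1].real,
                    "im_lambda2": e.eigenvalues[1].imag,
                }
                for e in self.equilibria
            ]
        )
        return curves_df, eq_df


def default_trait_box(community: Community, margin: float = 0.2):
    """[theta-range] x [phi-range] expanded by ``margin`` on each side."""
    p1, p2 = community.prey
    lo_x, hi_x = sorted((p1.theta, p2.theta))
    lo_y, hi_y = sorted((p1.phi, p2.phi))
    span_x = max(hi_x - lo_x, 0.5)
    span_y = max(hi_y - lo_y, 0.5)
    return (
        (lo_x - margin * span_x, hi_x + margin * span_x),
        (lo_y - margin * span_y, hi_y + margin * span_y),
    )


def _gradient_field(community: Community):
    """Gradients at the attractor (unscaled by sigma_G2), for root finding."""
    field = make_reduced_field(community)
    pred = community.predator
    sg = np.array([pred.sigma_xG2, pred.sigma_yG2])

    def g(z):
        return np.asarray(field(z[0], z[1])) / sg

    return g


def reduced_jacobian(
    xbar: float, ybar: float, community: Community, step: float = 1e-6,
    field=None,
) -> np.ndarray:
    """Central finite-difference 2x2 Jacobian of the reduced vector field."""
    field = field or make_reduced_field(community)
    J = np.zeros((2, 2))
    for j, (dx, dy) in enumerate(((step, 0.0), (0.0, step))):
        fp = field(xbar + dx, ybar + dy)
        fm = field(xbar - dx, ybar - dy)
        J[:, j] = (np.asarray(fp) - np.asarray(fm)) / (2.0 * step)
    return J


def _classify(eigenvalues: np.ndarray, degenerate_tol: float = 1e-8) -> str:
    re = np.real(eigenvalues)
    if np.any(np.abs(re) < degenerate_tol):
        return "degenerate"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def find_trait_equilibria(
    community: Community,
    box=None,
    n_seed: int = 21,
    residual_tol: float = 1e-9,
    merge_tol: float = 1e-6,
    degenerate_tol: float = 1e-8,
) -> list[TraitEquilibrium]:
    """Multi-start root finding on the reduced trait vector field.

    Seeds form an ``n_seed x n_seed`` grid over the trait box (the rectangle
    spanned by the kernel optima, expanded 20%).  Converged roots are filtered
    by the residual of the reduced field, merged within ``merge_tol``, and
    classified by the eigenvalues of the finite-difference Jacobian.
    Non-converging seeds are skipped.
    """
    if box is None:
        box = default_trait_box(community)
    (x_lo, x_hi), (y_lo, y_hi) = box
    g = _gradient_field(community)
    pred = community.predator
    sg = np.array([pred.sigma_xG2, pred.sigma_yG2])
    roots: list[np.ndarray] = []
    for x0 in np.linspace(x_lo, x_hi, n_seed):
        for y0 in np.linspace(y_lo, y_hi, n_seed):
            try:
                sol = root(g, np.array([x0, y0]), method="hybr",
                           options={"xtol": 1e-13})
            except AttractorAmbiguityError:
                continue
            if not sol.success:
                continue
            z = sol.x
            if not (x_lo <= z[0] <= x_hi and y_lo <= z[1] <= y_hi):
                continue
            if np.max(np.abs(sg * g(z))) > residual_tol:
                continue
            if any(np.hypot(*(z - r)) < merge_tol for r in roots):
                continue
            roots.append(z)
    fast = make_reduced_field(community)
    out = []
    for z in roots:
        J = reduced_jacobian(z[0], z[1], community, field=fast)
        eig = np.linalg.eigvals(J)
        out.append(
            TraitEquilibrium(
                xbar_star=float(z[0]),
                ybar_star=float(z[1]),
                eigenvalues=(complex(eig[0]), complex(eig[1])),
                stability=_classify(eig, degenerate_tol),
            )
        )
    out.sort(key=lambda e: (e.xbar_star, e.ybar_star))
    return out


def nullclines(
    community: Community, box=None, n_grid: int = 101
) -> PhasePortrait:
    """Zero-level contours of each component of the reduced field.

    Contours are traced by marching squares on an ``n_grid x n_grid``
    evaluation of the field over the trait box.
    """
    from skimage import measure

    if box is None:
        box = default_trait_box(community)
    (x_lo, x_hi), (y_lo, y_hi) = box
    xs = np.linspace(x_lo, x_hi, n_grid)
    ys = np.linspace(y_lo, y_hi, n_grid)
    FX = np.empty((n_grid, n_grid))
    FY = np.empty((n_grid, n_grid))
    field = make_reduced_field(community)
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            fx, fy = field(x, y)
            FX[i, j] = fx
            FY[i, j] = fy

    def trace(Z):
        curves = []
        for contour in measure.find_contours(Z, 0.0):
            cx = np.interp(contour[:, 0], np.arange(n_grid), xs)
            cy = np.interp(contour[:, 1], np.arange(n_grid), ys)
            curves.append(np.column_stack([cx, cy]))
        return curves

    return PhasePortrait(x_nullcline=trace(FX), y_nullcline=trace(FY))


def separatrices(
    saddles: list[TraitEquilibrium],
    community: Community,
    box=None,
    eps: float = 1e-6,
    box_margin: float = 0.5,
    t_factor: float = 1e4,
) -> list[np.ndarray]:
    """Stable manifolds of saddles, by backward integration from ``±eps``
    along the stable eigenvector.  Returns both branches per saddle."""
    if box is None:
        box = default_trait_box(community)
    (x_lo, x_hi), (y_lo, y_hi) = box
    mx = box_margin * (x_hi - x_lo)
    my = box_margin * (y_hi - y_lo)
    bounds = (x_lo - mx, x_hi + mx, y_lo - my, y_hi + my)
    pred = community.predator
    t_max = t_factor / max(min(pred.sigma_xG2, pred.sigma_yG2), 1e-12)
    field = make_reduced_field(community)

    def backward(t, z):
        fx, fy = field(z[0], z[1])
        return [-fx, -fy]

    def exits(t, z):
        return min(
            z[0] - bounds[0], bounds[1] - z[0], z[1] - bounds[2], bounds[3] - z[1]
        )

    exits.terminal = True
    exits.direction = -1.0

    curves = []
    for s in saddles:
        if s.stability != "saddle":
            raise ValueError("separatrices() requires saddle equilibria")
        J = reduced_jacobian(s.xbar_star, s.ybar_star, community, field=field)
        eig, vec = np.linalg.eig(J)
        stable_idx = int(np.argmin(np.real(eig)))
        v = np.real(vec[:, stable_idx])
        v = v / np.linalg.norm(v)
        z_star = np.array([s.xbar_star, s.ybar_star])
        for sign in (+1.0, -1.0):
            sol = solve_ivp(
                backward,
                (0.0, t_max),
                z_star + sign * eps * v,
                method="RK45",
                rtol=1e-8,
                atol=1e-12,
                events=exits,
            )
            branch = np.column_stack([sol.t, sol.y[0], sol.y[1]])[:, 1:]
            curves.append(branch)
    return curves


def phase_portrait(
    community: Community, box=None, n_grid: int = 101, n_seed: int = 21
) -> PhasePortrait:
    """Assemble nullclines, equilibria and separatrices for the trait box."""
    portrait = nullclines(community, box=box, n_grid=n_grid)
    portrait.equilibria = find_trait_equilibria(community, box=box, n_seed=n_seed)
    saddles = [e for e in portrait.equilibria if e.stability == "saddle"]
    if saddles:
        portrait.separatrices = separatrices(saddles, community, box=box)
    return portrait


# ---------------------------------------------------------------------------
# reduced-system trajectories
# ---------------------------------------------------------------------------

@dataclass
class ReducedTrajectory:
    times: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "xbar": self.xbar, "ybar": self.ybar})

    @property
    def final(self) -> tuple[float, float]:
        return (float(self.xbar[-1]), float(self.ybar[-1]))


def simulate_reduced(
    initial: tuple[float, float],
    community: Community,
    solver: SolverConfig | None = None,
    t_eval: np.ndarray | None = None,
) -> ReducedTrajectory:
    """Integrate the reduced trait dynamics for a fixed horizon."""
    solver = solver or SolverConfig(t_end=1e4)
    field = make_reduced_field(community)

    def rhs(t, z):
        return field(z[0], z[1])

    sol = solve_ivp(
        rhs,
        (0.0, solver.t_end),
        np.asarray(initial, dtype=float),
        method="RK45",
        rtol=solver.rtol,
        atol=solver.atol,
        t_eval=t_eval,
    )
    if sol.status != 0:
        raise RuntimeError(f"reduced integration failed: {sol.message}")
    return ReducedTrajectory(
        times=sol.t, xbar=sol.y[0], ybar=sol.y[1],
        meta={"rtol": solver.rtol, "atol": solver.atol},
    )


def evolve_to_equilibrium(
    initial: tuple[float, float],
    community: Community,
    grad_tol: float = 1e-8,
    t_max: float = 1e6,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> tuple[tuple[float, float], bool, float]:
    """Run the reduced system until the trait velocity falls below ``grad_tol``.

    Returns ``((xbar, ybar), converged, t_elapsed)``.  Some parameter sets
    cycle and never satisfy the criterion; they return ``converged=False`` at
    the horizon.
    """
    field = make_reduced_field(community)

    def rhs(t, z):
        return field(z[0], z[1])

    def settled(t, z):
        fx, fy = rhs(t, z)
        return max(abs(fx), abs(fy)) - grad_tol

    settled.terminal = True
    settled.direction = -1.0

    z = np.asarray(initial, dtype=float)
    t0, chunk = 0.0, 200.0
    while t0 < t_max:
        t1 = min(t0 + chunk, t_max)
        sol = solve_ivp(rhs, (t0, t1), z, method="RK45", rtol=rtol, atol=atol,
                        events=settled)
        z = sol.y[:, -1]
        t0 = float(sol.t[-1])
        if sol.status == 1:
            return (float(z[0]), float(z[1])), True, t0
        chunk *= 4.0
    fx, fy = rhs(0.0, z)
    return (float(z[0]), float(z[1])), max(abs(fx), abs(fy)) <= grad_tol, t0
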