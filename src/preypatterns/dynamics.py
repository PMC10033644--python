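"""Local stability, bifurcations and phase-plane machinery.

Stability of an equilibrium follows from the trace/determinant of the
Jacobian (Routh-Hurwitz in 2D: stable iff tr < 0 and det > 0); saddles have
det < 0; focus vs node is decided by the sign of ``tr^2 - 4 det``.

Two codimension-one bifurcations in the capture rate ``beta`` are located:

* **Hopf** at the coexistence state ``E3``: ``tr(J) = 0`` with
  ``det(J) > 0``, eigenvalues ``+/- i omega0`` with
  ``omega0 = sqrt(det J)``, plus a nonzero transversal drift of the real
  part.  Crossing it swaps a stable focus for an unstable one surrounded by
  a stable limit cycle.
* **Fold (saddle-node)**: two interior equilibria collide where the quartic
  ``Q`` has a double root (``Q = Q' = 0``), i.e. the nullclines touch
  tangentially; the coexistence count jumps by 2.

Phase-plane helpers integrate trajectories (adaptive Dormand-Prince),
detect limit cycles via a Poincare section, trace separatrices (stable
manifolds of saddles, backward integration) and classify basins of
attraction on a grid of initial conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from ._errors import (
    BranchDiscontinuityError,
    DomainError,
    NoFoldError,
    NotASaddleError,
    NumericalInstabilityError,
)
from .equilibria import (
    Equilibrium,
    coexistence_equilibria,
    no_allee_equilibrium,
    quartic_coefficients,
)
from .model_core import ModelParams, jacobian, reaction_rhs

__all__ = [
    "HopfResult",
    "FoldResult",
    "Trajectory",
    "Separatrix",
    "classify",
    "hopf_critical_beta",
    "fold_beta",
    "integrate",
    "detect_limit_cycle",
    "separatrix",
    "basin_classify",
]

_TR_TOL = 1e-9
_DET_TOL = 1e-12
_BLOWUP = 1e6
_NEG_CLIP = -1e-12


# ---------------------------------------------------------------------------
# classification

def classify(eq: Equilibrium, p: ModelParams) -> Equilibrium:
    """Return ``eq`` with eigenvalues and a stability label filled in."""
    J = jacobian(eq.x, eq.y, p)
    tr = J[0, 0] + J[1, 1]
    det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    eig = np.linalg.eigvals(J)
    if abs(det) < _DET_TOL or (abs(tr) < _TR_TOL and det > 0):
        label = "marginal"
    elif det < 0:
        label = "saddle"
    else:
        focus = tr * tr - 4.0 * det < 0
        if tr < 0:
            label = "stable focus" if focus else "stable node"
        else:
            label = "unstable focus" if focus else "unstable node"
    order = np.argsort(eig.real)
    return eq.with_stability(eig[order], label)


def _interior(p: ModelParams) -> list[Equilibrium]:
    return coexistence_equilibria(p) if p.allee else no_allee_equilibrium(p)


# ---------------------------------------------------------------------------
# Hopf bifurcation

@dataclass(frozen=True)
class HopfResult:
    """Hopf point in beta: critical value, frequency, transversality."""

    found: bool
    beta_c: float | None = None
    omega0: float | None = None
    transversality: float | None = None
    valid: bool = False
    equilibrium: Equilibrium | None = None


def _track_branch(p_base: ModelParams, beta: float, x_prev: float) -> Equilibrium:
    """Interior equilibrium at this beta nearest in x to the tracked branch."""
    eqs = _interior(replace(p_base, beta=beta))
    if not eqs:
        raise BranchDiscontinuityError(
            f"the tracked coexistence branch vanished at beta={beta}"
        )
    i = int(np.argmin([abs(e.x - x_prev) for e in eqs]))
    return eqs[i]


def hopf_critical_beta(
    p_base: ModelParams,
    bracket: tuple[float, float],
    branch: int | None = None,
    n_scan: int = 64,
    xtol: float = 1e-12,
) -> HopfResult:
    """Locate the Hopf point of the tracked coexistence branch in ``beta``.

    The branch is the interior equilibrium continuous in beta from the
    bracket's left endpoint (``branch`` selects among several, ascending in
    x; required when the count there exceeds one).  ``tr(J)`` is followed
    along the branch; a sign change is refined by Brent's method.  Returns a
    not-found result when the trace keeps one sign over the whole bracket.

    The reported ``transversality`` is the centred finite-difference slope
    of ``tr(J)`` with respect to beta along the branch at the critical
    point; ``valid`` additionally requires ``det(J) > 0`` there.
    """
    lo, hi = bracket
    eqs0 = _interior(replace(p_base, beta=lo))
    if not eqs0:
        raise BranchDiscontinuityError(f"no coexistence equilibrium at beta={lo}")
    if branch is None:
        if len(eqs0) > 1:
            raise DomainError(
                f"{len(eqs0)} coexistence equilibria at beta={lo}; "
                "pass branch= to select one"
            )
        branch = 0
    x_ref = eqs0[branch].x

    def trace_at(beta: float, x_near: float) -> tuple[float, Equilibrium]:
        eq = _track_branch(p_base, beta, x_near)
        J = jacobian(eq.x, eq.y, replace(p_base, beta=beta))
        return float(J[0, 0] + J[1, 1]), eq

    betas = np.linspace(lo, hi, n_scan)
    traces = np.empty(n_scan)
    x_near = x_ref
    xs = np.empty(n_scan)
    for i, b in enumerate(betas):
        tr, eq = trace_at(b, x_near)
        traces[i] = tr
        x_near = eq.x
        xs[i] = eq.x
    sign_change = np.nonzero(np.diff(np.signbit(traces)))[0]
    if sign_change.size == 0:
        return HopfResult(found=False)
    i = int(sign_change[0])

    def f(b: float) -> float:
        # nearest-x seed interpolated from the scan keeps the branch identity
        x_seed = float(np.interp(b, betas, xs))
        return trace_at(b, x_seed)[0]

    beta_c = brentq(f, betas[i], betas[i + 1], xtol=xtol)
    x_seed = float(np.interp(beta_c, betas, xs))
    eq_c = _track_branch(p_base, beta_c, x_seed)
    p_c = replace(p_base, beta=beta_c)
    J = jacobian(eq_c.x, eq_c.y, p_c)
    det = float(np.linalg.det(J))
    valid = det > 0
    omega0 = float(np.sqrt(det)) if valid else None
    h = 1e-6 * max(1.0, abs(beta_c))
    trans = (f(beta_c + h) - f(beta_c - h)) / (2.0 * h)
    return HopfResult(
        found=True,
        beta_c=float(beta_c),
        omega0=omega0,
        transversality=float(trans),
        valid=valid,
        equilibrium=classify(eq_c, p_c),
    )


# ---------------------------------------------------------------------------
# fold (saddle-node) bifurcation

@dataclass(frozen=True)
class FoldResult:
    """Fold in beta: collision point of two interior equilibria."""

    beta_sn: float
    x_tangency: float
    y_tangency: float
    count_below: int
    count_above: int


def fold_beta(
    p_base: ModelParams,
    bracket: tuple[float, float],
    bisect_tol: float = 1e-10,
) -> FoldResult:
    """Locate the beta at which two coexistence equilibria collide.

    Bisects on the coexistence-equilibrium count over ``bracket`` (the
    counts at the endpoints must differ), then refines by Newton iteration
    on the 2x2 system ``Q(x; beta) = 0``, ``dQ/dx(x; beta) = 0`` seeded
    from the last bisection state.  Only beta enters ``Q`` linearly (through
    the coefficient of x), which makes the Newton system well conditioned.
    """
    if not p_base.allee:
        raise DomainError("fold tracking uses the Allee-variant quartic")

    def count(beta: float) -> int:
        return sum(e.multiplicity for e in coexistence_equilibria(replace(p_base, beta=beta)))

    lo, hi = bracket
    c_lo, c_hi = count(lo), count(hi)
    if c_lo == c_hi:
        raise NoFoldError(
            f"coexistence count is {c_lo} at both endpoints of {bracket}"
        )
    while hi - lo > bisect_tol:
        mid = 0.5 * (lo + hi)
        if count(mid) == c_lo:
            lo = mid
        else:
            hi = mid
    beta_mid = 0.5 * (lo + hi)

    # seed x at the near-double root: the pair of roots closest together
    # on the side of the (narrowed) bracket that still has the extra pair
    beta_seed = lo if c_lo > c_hi else hi
    eqs = coexistence_equilibria(replace(p_base, beta=beta_seed))
    xs = [e.x for e in eqs]
    doubles = [e.x for e in eqs if e.multiplicity >= 2]
    if doubles:
        x0 = doubles[0]
    elif len(xs) >= 2:
        gaps = np.diff(xs)
        j = int(np.argmin(gaps))
        x0 = 0.5 * (xs[j] + xs[j + 1])
    else:
        x0 = xs[0] if xs else 0.5

    # Newton on F(x, beta) = (Q, Q') with dQ/dbeta = x, dQ'/dbeta = 1
    x, beta = float(x0), float(beta_mid)
    for _ in range(100):
        q = quartic_coefficients(replace(p_base, beta=beta))
        c = q.coeffs()
        dc = np.polyder(c)
        F = np.array([np.polyval(c, x), np.polyval(dc, x)])
        Jn = np.array(
            [
                [np.polyval(dc, x), x],
                [np.polyval(np.polyder(dc), x), 1.0],
            ]
        )
        try:
            step = np.linalg.solve(Jn, F)
        except np.linalg.LinAlgError:
            break
        x -= step[0]
        beta -= step[1]
        if np.max(np.abs(step)) < 1e-14:
            break
    if abs(beta - beta_mid) > 1e-6 * max(1.0, abs(beta_mid)):
        # Newton wandered off the bisection bracket; fall back to bisection limit
        x, beta = x0, beta_mid
    from .equilibria import predator_nullcline_y

    y_t = float(predator_nullcline_y(x, replace(p_base, beta=beta)))
    lo_c = count(beta - 1e-7)
    hi_c = count(beta + 1e-7)
    return FoldResult(
        beta_sn=float(beta),
        x_tangency=float(x),
        y_tangency=y_t,
        count_below=lo_c,
        count_above=hi_c,
    )


# ---------------------------------------------------------------------------
# trajectories

@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # shape (n, 2)

    @property
    def end(self) -> np.ndarray:
        return self.states[-1]


def _rhs(t, s, p: ModelParams):
    return reaction_rhs(s[0], s[1], p)


def integrate(
    p: ModelParams,
    s0,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_eval=None,
    backward: bool = False,
) -> Trajectory:
    """Integrate the reaction ODE with adaptive RK45 (Dormand-Prince).

    Initial states must lie in the nonnegative quadrant.  Components that
    dip into [-1e-12, 0) are clipped to zero; a trajectory exceeding 1e6 in
    magnitude raises :class:`NumericalInstabilityError`.
    """
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 < _NEG_CLIP):
        raise DomainError(f"initial state {s0} outside the nonnegative quadrant")
    s0 = np.clip(s0, 0.0, None)

    fun = (lambda t, s: [-v for v in _rhs(t, s, p)]) if backward else (
        lambda t, s: _rhs(t, s, p)
    )

    def blowup(t, s):
        return float(np.max(np.abs(s)) - _BLOWUP)

    blowup.terminal = True
    sol = solve_ivp(
        fun,
        (0.0, t_end),
        s0,
        method="RK45",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        events=blowup,
        dense_output=False,
    )
    states = sol.y.T
    if sol.status == 1:  # blow-up event fired
        raise NumericalInstabilityError(
            f"trajectory magnitude exceeded {_BLOWUP:g} at t={sol.t[-1]:.4g}"
        )
    if np.any(states < _NEG_CLIP * 1e3):
        # far negative means the integrator genuinely left the quadrant
        raise NumericalInstabilityError("trajectory left the nonnegative quadrant")
    return Trajectory(times=sol.t, states=np.clip(states, 0.0, None))


# ---------------------------------------------------------------------------
# limit cycles

@dataclass(frozen=True)
class CycleReport:
    found: bool
    x_extent: tuple[float, float] | None = None
    y_extent: tuple[float, float] | None = None
    period: float | None = None
    section_y: float | None = None


def detect_limit_cycle(
    p: ModelParams,
    eq: Equilibrium,
    offset: float = 1e-2,
    t_transient: float = 2000.0,
    t_observe: float = 2000.0,
    rel_tol: float = 1e-4,
    min_separation: float = 1e-3,
) -> CycleReport:
    """Detect a stable limit cycle around a coexistence equilibrium.

    Integrates from the equilibrium plus a small radial offset, discards a
    transient, then records upward crossings of the Poincare section
    ``x = x*``.  A cycle is reported when successive crossing y-values
    converge (relative change < ``rel_tol``) to a value bounded away from
    ``y*``; a spiral back into the equilibrium gives ``found=False``.
    """
    s0 = np.array([eq.x * (1.0 + offset), eq.y * (1.0 + offset)])
    tra = integrate(p, s0, t_transient, rtol=1e-9, atol=1e-11)
    # observe with dense sampling for crossing detection
    t_eval = np.linspace(0.0, t_observe, int(t_observe * 20))
    tra = integrate(p, tra.end, t_observe, rtol=1e-9, atol=1e-11, t_eval=t_eval)
    x, y = tra.states[:, 0], tra.states[:, 1]
    # one increasing-x crossing of the section x = x* per revolution
    up = (x[:-1] < eq.x) & (x[1:] >= eq.x)
    idx = np.nonzero(up)[0]
    if idx.size < 3:
        return CycleReport(found=False)
    # linear interpolation of the crossing y and time
    frac = (eq.x - x[idx]) / (x[idx + 1] - x[idx])
    y_cross = y[idx] + frac * (y[idx + 1] - y[idx])
    t_cross = tra.times[idx] + frac * (tra.times[idx + 1] - tra.times[idx])
    y1, y2 = y_cross[-2], y_cross[-1]
    converged = abs(y2 - y1) < rel_tol * max(1.0, abs(y2))
    away = abs(y2 - eq.y) > min_separation * max(1.0, eq.y)
    if not (converged and away):
        return CycleReport(found=False)
    period = float(t_cross[-1] - t_cross[-2])
    # one more period to measure amplitude extents
    n = max(int(period * 50), 100)
    tra2 = integrate(
        p, tra.end, 1.5 * period, rtol=1e-9, atol=1e-11,
        t_eval=np.linspace(0.0, 1.5 * period, n),
    )
    return CycleReport(
        found=True,
        x_extent=(float(tra2.states[:, 0].min()), float(tra2.states[:, 0].max())),
        y_extent=(float(tra2.states[:, 1].min()), float(tra2.states[:, 1].max())),
        period=period,
        section_y=float(y2),
    )


# ---------------------------------------------------------------------------
# separatrix and basins

@dataclass(frozen=True)
class Separatrix:
    saddle: Equilibrium
    branches: tuple[np.ndarray, np.ndarray]  # two (n, 2) polylines


def separatrix(
    p: ModelParams,
    saddle: Equilibrium,
    t_back: float = 200.0,
    eps: float = 1e-6,
    box=((0.0, 1.5), (0.0, None)),
) -> Separatrix:
    """Stable manifold of a saddle, by backward integration.

    Seeds at ``saddle +/- eps * v_stable`` and integrates the reversed flow,
    truncating when a branch leaves the box (default x in [0, 1.5], y >= 0
    with an automatic upper limit).
    """
    J = jacobian(saddle.x, saddle.y, p)
    lam, V = np.linalg.eig(J)
    if not np.isreal(lam).all() or not (lam.real.min() < 0 < lam.real.max()):
        raise NotASaddleError(f"equilibrium at {saddle.state} is not a saddle: {lam}")
    v = np.real(V[:, np.argmin(lam.real)])
    v = v / np.linalg.norm(v)
    (x_lo, x_hi), (y_lo, y_hi) = box
    if y_hi is None:
        y_hi = 10.0 * max(1.0, saddle.y)

    branches = []
    for sgn in (+1.0, -1.0):
        s0 = saddle.state + sgn * eps * v
        if np.any(s0 < 0):
            s0 = np.clip(s0, 0.0, None)
        t_eval = np.linspace(0.0, t_back, 4000)
        try:
            tra = integrate(p, s0, t_back, t_eval=t_eval, backward=True)
            pts = tra.states
        except NumericalInstabilityError:
            # backward flow is expansive; keep what was computed up to blow-up
            sol = solve_ivp(
                lambda t, s: [-u for u in _rhs(t, s, p)],
                (0.0, t_back), s0, method="RK45", rtol=1e-8, atol=1e-10,
                events=_make_box_event(x_lo, x_hi, y_lo, y_hi),
            )
            pts = sol.y.T
        inside = (
            (pts[:, 0] >= x_lo - 1e-9)
            & (pts[:, 0] <= x_hi)
            & (pts[:, 1] >= y_lo - 1e-9)
            & (pts[:, 1] <= y_hi)
        )
        cut = np.argmin(inside) if not inside.all() else len(pts)
        branches.append(pts[: max(cut, 2)])
    return Separatrix(saddle=saddle, branches=(branches[0], branches[1]))


def _make_box_event(x_lo, x_hi, y_lo, y_hi):
    def ev(t, s):
        return min(s[0] - x_lo + 0.1, x_hi + 0.1 - s[0], s[1] - y_lo + 0.1, y_hi - s[1])

    ev.terminal = True
    return ev


def basin_classify(
    p: ModelParams,
    initial_states,
    attractors: list[Equilibrium],
    cycle: CycleReport | None = None,
    t_end: float = 2000.0,
    tol: float = 1e-3,
) -> list[str]:
    """Label each initial state by the attractor its trajectory approaches.

    ``attractors`` are point attractors labelled ``"E:<x>,<y>"``; a
    detected cycle is labelled ``"cycle"`` when the endpoint falls inside
    its bounding box (inflated by ``tol``).  Anything else is
    ``"unresolved"``.
    """
    labels = []
    for s0 in initial_states:
        try:
            tra = integrate(p, s0, t_end, rtol=1e-8, atol=1e-10)
        except NumericalInstabilityError:
            labels.append("unresolved")
            continue
        end = tra.end
        label = "unresolved"
        for eq in attractors:
            if np.linalg.norm(end - eq.state) < tol:
                label = f"E:{eq.x:.6g},{eq.y:.6g}"
                break
        if label == "unresolved" and cycle is not None and cycle.found:
            (x0, x1), (y0, y1) = cycle.x_extent, cycle.y_extent
            if x0 - tol <= end[0] <= x1 + tol and y0 - tol <= end[1] <= y1 + tol:
                label = "cycle"
        labels.append(label)
    return labels
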