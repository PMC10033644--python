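"""Explicit 2D reaction-diffusion simulation and pattern statistics.

The spatial model adds Fickian diffusion (``d1`` prey, ``d2`` predator) to
the reaction terms on a square domain with zero-flux (Neumann) boundaries.
Time stepping is explicit Euler with a five-point Laplacian; zero flux is
imposed by mirrored ghost cells (second order).  Defaults follow the
reference protocol: 200x200 grid, spacing ``h = 1``, step ``dt = 0.01``,
initial data a small seeded random perturbation of the homogeneous
coexistence state.  An explicit scheme needs the diffusive stability bound
``dt <= h^2 / (4 max(d1, d2))``, checked at configuration time.

Pattern morphology (hot spots / cold spots / stripes-labyrinthine /
mixture) is summarized from the prey field via moments of the deviation
from the spatial mean and the shape of its 4-connected excursion
components: spot phases form many compact components of one sign, striped
phases form few elongated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import skew

from ._errors import CFLViolationError, DomainError, NumericalInstabilityError
from .equilibria import coexistence_equilibria, no_allee_equilibrium
from .model_core import DiffusionParams, ModelParams, reaction_rhs

__all__ = [
    "SimConfig",
    "SimState",
    "PatternSummary",
    "laplacian_neumann",
    "step",
    "simulate",
    "pattern_summary",
]


@dataclass(frozen=True)
class SimConfig:
    """Grid, stepping, horizon and seeding for one simulation run."""

    n: int = 200
    h: float = 1.0
    dt: float = 0.01
    t_end: float = 5000.0
    seed: int = 0
    perturb_amp: float = 0.01
    snapshot_times: tuple[float, ...] = ()

    def validate(self, dp: DiffusionParams) -> None:
        if self.n < 3:
            raise DomainError(f"grid must be at least 3x3, got n={self.n}")
        if self.dt <= 0 or self.h <= 0 or self.t_end <= 0:
            raise DomainError("dt, h and t_end must be positive")
        cfl = self.h**2 / (4.0 * max(dp.d1, dp.d2))
        if self.dt > cfl * (1.0 + 1e-12):
            raise CFLViolationError(
                f"dt={self.dt} violates the explicit-diffusion stability bound "
                f"h^2/(4 max(d1,d2)) = {cfl:.6g}"
            )


@dataclass
class SimState:
    """Prey and predator fields at simulation time ``t``."""

    x_field: np.ndarray
    y_field: np.ndarray
    t: float = 0.0
    clip_count: int = 0

    def copy(self) -> "SimState":
        return SimState(self.x_field.copy(), self.y_field.copy(), self.t, self.clip_count)


@dataclass(frozen=True)
class PatternSummary:
    """Moments and morphology label of a scalar field."""

    mean: float
    variance: float
    skewness: float
    n_hot: int
    n_cold: int
    label: str


def laplacian_neumann(u: np.ndarray, h: float = 1.0) -> np.ndarray:
    """Five-point Laplacian with mirrored ghost cells (zero normal flux).

    The mirror makes the boundary flux vanish, so the Laplacian sums to
    zero over the grid (discrete divergence theorem).
    """
    u = np.asarray(u)
    if u.ndim != 2 or min(u.shape) < 3:
        raise DomainError(f"field must be 2D with each side >= 3, got shape {u.shape}")
    p = np.pad(u, 1, mode="edge")  # ghost cell = mirrored boundary cell
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * u) / (h * h)


def step(
    state: SimState, p: ModelParams, dp: DiffusionParams, dt: float, h: float = 1.0
) -> SimState:
    """One explicit Euler step, in place on copies of the fields.

    Small negative undershoots are clipped to zero and counted in
    ``clip_count``; non-finite values or magnitudes beyond 1e6 raise
    :class:`NumericalInstabilityError`.
    """
    u, v = state.x_field, state.y_field
    fu, fv = reaction_rhs(u, v, p)
    nu = u + dt * (fu + dp.d1 * laplacian_neumann(u, h))
    nv = v + dt * (fv + dp.d2 * laplacian_neumann(v, h))
    if not (np.isfinite(nu).all() and np.isfinite(nv).all()):
        raise NumericalInstabilityError(f"non-finite field value at t={state.t + dt:.4g}")
    if max(np.abs(nu).max(), np.abs(nv).max()) > 1e6:
        raise NumericalInstabilityError(f"field magnitude exceeded 1e6 at t={state.t + dt:.4g}")
    clips = int((nu < 0).sum() + (nv < 0).sum())
    np.clip(nu, 0.0, None, out=nu)
    np.clip(nv, 0.0, None, out=nv)
    return SimState(nu, nv, state.t + dt, state.clip_count + clips)


def initial_state(
    eq_xy: tuple[float, float], cfg: SimConfig
) -> SimState:
    """Homogeneous coexistence state plus seeded uniform perturbation."""
    from .fixtures import perturbed_initial_condition

    x_f, y_f = perturbed_initial_condition(eq_xy, cfg.n, cfg.perturb_amp, cfg.seed)
    return SimState(x_f, y_f, 0.0)


def simulate(
    p: ModelParams,
    dp: DiffusionParams,
    cfg: SimConfig,
    state0: SimState | None = None,
    summarize: bool = True,
):
    """Run the reaction-diffusion model; return snapshots and summaries.

    The initial state (unless supplied) is the unique coexistence
    equilibrium perturbed multiplicatively by seeded uniform noise of
    amplitude ``cfg.perturb_amp``.  Snapshots are taken at
    ``cfg.snapshot_times`` (plus the final time) and returned as
    ``(time, SimState)`` pairs together with a :class:`PatternSummary` of
    the prey field per snapshot.
    """
    cfg.validate(dp)
    if state0 is None:
        eqs = coexistence_equilibria(p) if p.allee else no_allee_equilibrium(p)
        if len(eqs) != 1:
            raise DomainError(
                f"need a unique coexistence equilibrium to seed the run, found {len(eqs)}"
            )
        state0 = initial_state((eqs[0].x, eqs[0].y), cfg)
    state = state0.copy()
    n_steps = int(round(cfg.t_end / cfg.dt))
    snap_steps = sorted({int(round(t / cfg.dt)) for t in cfg.snapshot_times} | {n_steps})
    snapshots: list[tuple[float, SimState]] = []
    summaries: list[PatternSummary] = []
    for k in range(1, n_steps + 1):
        state = step(state, p, dp, cfg.dt, cfg.h)
        if k in snap_steps:
            snap = state.copy()
            snapshots.append((snap.t, snap))
            if summarize:
                summaries.append(pattern_summary(snap.x_field))
    return snapshots, summaries


# ---------------------------------------------------------------------------
# pattern morphology

#: a connected component participates in shape statistics above this area
_MIN_BLOB_AREA = 4
#: grid-circularity above this means compact (blob); below, elongated
_CIRCULARITY_THRESHOLD = 0.45
#: at least this many compact components of one sign to call a spot phase
_MIN_SPOT_COUNT = 5
_HOMOG_REL_VAR = 1e-10


def _component_stats(mask: np.ndarray):
    """(count, median grid-circularity) of 4-connected components of a mask."""
    labels, n = ndimage.label(mask)  # default structure = 4-connectivity
    if n == 0:
        return 0, 0.0
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    # perimeter = count of exposed cell edges, via neighbor differences
    circ = []
    for i, area in enumerate(areas, start=1):
        if area < _MIN_BLOB_AREA:
            continue
        m = labels == i
        per = (
            np.count_nonzero(m[:, :1]) + np.count_nonzero(m[:, -1:])
            + np.count_nonzero(m[:1, :]) + np.count_nonzero(m[-1:, :])
            + np.count_nonzero(m[:, 1:] != m[:, :-1]) * 1
            + np.count_nonzero(m[1:, :] != m[:-1, :]) * 1
        )
        # 4*pi*A/P^2 ~ pi^2/16 ~ 0.62 for a rasterized disk (taxicab perimeter 8r)
        circ.append(4.0 * np.pi * area / (per * per))
    if not circ:
        return n, 0.0
    return n, float(np.median(circ))


def pattern_summary(field: np.ndarray) -> PatternSummary:
    """Moments plus a morphology label for a (prey) field.

    The deviation from the spatial mean is thresholded at zero; the sign
    whose excursion set forms many compact components names a spot phase
    (hot = above-mean prey, cold = below-mean).  Elongated components of
    both signs give stripes/labyrinthine; compact components of both signs,
    a mixture.
    """
    field = np.asarray(field, dtype=float)
    mean = float(field.mean())
    var = float(field.var())
    if var <= _HOMOG_REL_VAR * max(mean * mean, 1e-300):
        return PatternSummary(mean, var, 0.0, 0, 0, "homogeneous")
    sk = float(skew(field, axis=None))
    dev = field - mean
    n_hot, circ_hot = _component_stats(dev > 0)
    n_cold, circ_cold = _component_stats(dev < 0)
    hot_blobby = circ_hot > _CIRCULARITY_THRESHOLD and n_hot >= _MIN_SPOT_COUNT
    cold_blobby = circ_cold > _CIRCULARITY_THRESHOLD and n_cold >= _MIN_SPOT_COUNT
    if hot_blobby and not cold_blobby:
        label = "hot spots"
    elif cold_blobby and not hot_blobby:
        label = "cold spots"
    elif not hot_blobby and not cold_blobby:
        label = "stripes/labyrinthine"
    else:
        label = "mixture"
    return PatternSummary(mean, var, sk, int(n_hot), int(n_cold), label)
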