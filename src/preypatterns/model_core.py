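"""Core predator-prey model with Allee effect and Crowley-Martin response.

The dimensional model couples a prey population ``X`` whose growth is
logistic with a multiplicative Allee term, ``R X (1 - X/K)(X - L)``, to a
predator ``Y`` feeding through a Crowley-Martin functional response

    f(X, Y) = M X / (1 + A X + B Y + A B X Y),

whose denominator factors as ``(1 + A X)(1 + B Y)``: predators interfere
with each other even while handling prey.  After rescaling ``x = X/K``,
``y = Y/(K E)``, ``t = K R T`` the reaction part becomes

    dx/dt = x (1 - x)(x - l) - beta x y / ((1 + a x)(1 + b y)),
    dy/dt = beta x y / ((1 + a x)(1 + b y)) - d y,

with ``l = L/K``, ``beta = M E / R``, ``a = A K``, ``b = B K E`` and
``d = D/(K R)``.  ``l > 0`` is a strong Allee effect (extinction threshold),
``-1 < l <= 0`` a weak one.  Setting ``allee=False`` replaces the growth
term by plain logistic ``x (1 - x)``.

This module holds the parameter containers, the reaction right-hand side,
its analytic Jacobian, and the nondimensionalization map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from ._errors import DomainError

__all__ = [
    "DimensionalParams",
    "ModelParams",
    "DiffusionParams",
    "nondimensionalize",
    "predation_rate",
    "reaction_rhs",
    "jacobian",
]


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional parameters of the model before rescaling.

    Attributes
    ----------
    R : float
        Intrinsic growth-rate scale of the Allee growth term.
    K : float
        Prey carrying capacity (density).
    L : float
        Allee threshold density; strong Allee effect if ``L > 0``,
        weak if ``-K < L <= 0``.
    M : float
        Capture (attack) rate of the predator.
    A : float
        Handling-time coefficient (per unit prey density).
    B : float
        Predator-interference coefficient (per unit predator density).
    E : float
        Conversion efficiency of consumed prey into predators, in (0, 1).
    D : float
        Predator per-capita death rate.
    D1, D2 : float
        Prey and predator diffusion coefficients (area/time).
    L1 : float
        Characteristic length of the square spatial domain.
    """

    R: float
    K: float
    L: float
    M: float
    A: float
    B: float
    E: float
    D: float
    D1: float = 1.0
    D2: float = 1.0
    L1: float = 1.0

    def __post_init__(self) -> None:
        for name in ("R", "K", "M", "A", "B", "D", "D1", "D2", "L1"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0 < self.E < 1:
            raise DomainError(f"E must lie in (0, 1), got {self.E}")
        if not self.L > -self.K:
            raise DomainError(
                f"Allee threshold L must exceed -K (got L={self.L}, K={self.K})"
            )


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless reaction parameters.

    ``l`` is the dimensionless Allee threshold, ``beta`` the capture rate,
    ``a`` the handling coefficient, ``b`` the interference coefficient and
    ``d`` the predator death rate.  ``allee=False`` selects the pure
    logistic variant (``l`` is then ignored).  ``permissive=True`` allows
    ``l <= -1`` (outside the usual weak-Allee range) with a warning.
    """

    l: float = 0.0
    beta: float = 1.0
    a: float = 1.0
    b: float = 1.0
    d: float = 0.1
    allee: bool = True
    permissive: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("beta", "d"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive, got {getattr(self, name)}")
        # a = 0 and b = 0 are admitted as the classical reductions of the
        # response (Holling I/II, Harrison); negative values are not
        for name in ("a", "b"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.allee and self.l <= -1.0:
            if self.permissive:
                warnings.warn(
                    f"l={self.l} is outside the weak-Allee range (-1, 0]; "
                    "accepted in permissive mode",
                    stacklevel=2,
                )
            else:
                raise DomainError(
                    f"Allee threshold l must exceed -1 (got {self.l}); "
                    "use permissive=True to override"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("permissive")
        return d

    @classmethod
    def from_dict(cls, d: dict, **kwargs) -> "ModelParams":
        known = {k: d[k] for k in ("l", "beta", "a", "b", "d", "allee") if k in d}
        known.update(kwargs)
        return cls(**known)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class DiffusionParams:
    """Dimensionless diffusion coefficients ``d1`` (prey) and ``d2`` (predator)."""

    d1: float
    d2: float

    def __post_init__(self) -> None:
        if not (self.d1 > 0 and self.d2 > 0):
            raise DomainError(f"diffusion coefficients must be positive, got {self}")


def nondimensionalize(p: DimensionalParams) -> tuple[ModelParams, DiffusionParams]:
    """Map dimensional parameters to the dimensionless ones.

    Uses the variable scaling ``x = X/K``, ``y = Y/(K E)``, ``t = K R T``,
    ``xi = xi_1/L1``, giving

        l = L/K,  beta = M E / R,  a = A K,  b = B K E,  d = D/(K R),
        d1 = D1/(R K L1^2),  d2 = D2/(R K L1^2).

    Under this scaling the dimensional rates satisfy
    ``dX/dT = K^2 R * dx/dt`` and ``dY/dT = K^2 R E * dy/dt``.
    """
    mp = ModelParams(
        l=p.L / p.K,
        beta=p.M * p.E / p.R,
        a=p.A * p.K,
        b=p.B * p.K * p.E,
        d=p.D / (p.K * p.R),
    )
    scale = p.R * p.K * p.L1**2
    dp = DiffusionParams(d1=p.D1 / scale, d2=p.D2 / scale)
    return mp, dp


def predation_rate(x, y, p: ModelParams):
    """Crowley-Martin predation rate ``beta*x*y / ((1+a*x)(1+b*y))``.

    Vectorized over ``x`` and ``y``.  The factored denominator is used; on
    the nonnegative quadrant it is >= 1, so the rate is finite and
    nonnegative, vanishing whenever either density is zero.
    """
    return p.beta * x * y / ((1.0 + p.a * x) * (1.0 + p.b * y))


def growth_rate(x, p: ModelParams):
    """Prey per-area growth: Allee ``x(1-x)(x-l)`` or logistic ``x(1-x)``."""
    if p.allee:
        return x * (1.0 - x) * (x - p.l)
    return x * (1.0 - x)


def reaction_rhs(x, y, p: ModelParams):
    """Reaction rates ``(dx/dt, dy/dt)`` of the nonspatial model.

    Vectorized: ``x`` and ``y`` may be arrays of matching shape.
    """
    pred = predation_rate(x, y, p)
    return growth_rate(x, p) - pred, pred - p.d * y


def jacobian(x: float, y: float, p: ModelParams) -> np.ndarray:
    """Analytic Jacobian of :func:`reaction_rhs` at a general point.

    Returns the 2x2 array ``[[J11, J12], [J21, J22]]``.  The predation term
    ``g = beta x y / ((1+ax)(1+by))`` has partials

        dg/dx = beta y / ((1+ax)^2 (1+by)),
        dg/dy = beta x / ((1+ax)(1+by)^2),

    so ``J12 <= 0`` and ``J21 >= 0`` on the nonnegative quadrant.
    """
    ax1 = 1.0 + p.a * x
    by1 = 1.0 + p.b * y
    dg_dx = p.beta * y / (ax1**2 * by1)
    dg_dy = p.beta * x / (ax1 * by1**2)
    if p.allee:
        # d/dx [x(1-x)(x-l)] = -3x^2 + 2(1+l)x - l
        growth_x = -3.0 * x * x + 2.0 * (1.0 + p.l) * x - p.l
    else:
        growth_x = 1.0 - 2.0 * x
    return np.array(
        [
            [growth_x - dg_dx, -dg_dy],
            [dg_dx, dg_dy - p.d],
        ]
    )
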