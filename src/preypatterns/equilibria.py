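"""Equilibrium enumeration for the nonspatial model.

Boundary equilibria are ``E0 = (0, 0)`` (total extinction), ``E1 = (1, 0)``
(prey at carrying capacity) and, for a strong Allee effect with
``0 < l < 1``, ``E2 = (l, 0)`` (prey at the Allee threshold).

Coexistence (interior) equilibria lie at intersections of the nontrivial
nullclines.  Eliminating ``y`` via the predator nullcline

    y* = (beta x* - (1 + a x*) d) / (b d (1 + a x*))

reduces the prey nullcline to a quartic in ``x``,

    Q(x) = k4 x^4 + k3 x^3 + k2 x^2 + k1 x + k0 = 0,

with ``k4 = a b``, ``k3 = b (1 - a (1 + l))``, ``k2 = -b (1 + l) + l a b``,
``k1 = l b + beta - a d`` and ``k0 = -d``.  Positive roots with ``y* > 0``
are the coexistence states; their number (0-3 in practice) controls the
bistability structure.  Without the Allee term the same elimination yields
a cubic instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._errors import UnsupportedVariantError
from .model_core import ModelParams, reaction_rhs

__all__ = [
    "Quartic",
    "Equilibrium",
    "quartic_coefficients",
    "predator_nullcline_y",
    "coexistence_equilibria",
    "boundary_equilibria",
    "no_allee_equilibrium",
    "all_equilibria",
]

#: accept a polynomial root as real when |Im| < this times max(1, |Re|)
_IMAG_TOL = 1e-8
#: merge two real roots (tangency) when they are closer than this; a double
#: root split by an O(eps) coefficient perturbation separates by O(sqrt(eps)),
#: so parameters printed to ~12 digits can leave a residual split of ~1e-6
_MERGE_TOL = 1e-6
#: strict positivity threshold for y*
_Y_POS_TOL = 1e-12


@dataclass(frozen=True)
class Quartic:
    """Coefficients of the interior-equilibrium quartic ``Q(x)``."""

    k4: float
    k3: float
    k2: float
    k1: float
    k0: float

    def coeffs(self) -> np.ndarray:
        """Coefficients in descending order, for numpy polynomial routines."""
        return np.array([self.k4, self.k3, self.k2, self.k1, self.k0])

    def __call__(self, x):
        return np.polyval(self.coeffs(), x)

    def derivative(self, x):
        return np.polyval(np.polyder(self.coeffs()), x)


@dataclass(frozen=True)
class Equilibrium:
    """A steady state of the reaction system.

    ``kind`` is one of ``"trivial"`` (E0), ``"axial_capacity"`` (E1),
    ``"axial_threshold"`` (E2) or ``"coexistence"`` (E3-type).
    ``multiplicity`` is 2 for a fold point where two interior roots have
    collided.  ``eigenvalues`` and ``stability`` are filled by
    :func:`preypatterns.dynamics.classify`.
    """

    x: float
    y: float
    kind: str
    multiplicity: int = 1
    eigenvalues: tuple[complex, complex] | None = None
    stability: str | None = None

    @property
    def state(self) -> np.ndarray:
        return np.array([self.x, self.y])

    def with_stability(self, eigenvalues, stability) -> "Equilibrium":
        return replace(self, eigenvalues=tuple(eigenvalues), stability=stability)


def quartic_coefficients(p: ModelParams) -> Quartic:
    """Quartic whose positive roots are candidate interior prey levels.

    Only defined for the Allee variant; the logistic variant reduces to a
    cubic handled by :func:`no_allee_equilibrium`.
    """
    if not p.allee:
        raise UnsupportedVariantError(
            "the interior-equilibrium quartic is defined for the Allee variant; "
            "use no_allee_equilibrium for the logistic model"
        )
    return Quartic(
        k4=p.a * p.b,
        k3=p.b * (1.0 - p.a * (1.0 + p.l)),
        k2=-p.b * (1.0 + p.l) + p.l * p.a * p.b,
        k1=p.l * p.b + p.beta - p.a * p.d,
        k0=-p.d,
    )


def predator_nullcline_y(x, p: ModelParams):
    """Predator level on the nontrivial predator nullcline at prey level x."""
    ax1 = 1.0 + p.a * x
    return (p.beta * x - ax1 * p.d) / (p.b * p.d * ax1)


def _positive_real_roots(coeffs: np.ndarray, polish: np.ndarray | None = None):
    """Real positive roots of a polynomial, Newton-polished, merged by proximity.

    Returns a list of ``(x, multiplicity)`` sorted ascending.
    """
    roots = np.roots(coeffs)
    deriv = np.polyder(coeffs)
    real = []
    for r in roots:
        if abs(r.imag) >= _IMAG_TOL * max(1.0, abs(r.real)):
            continue
        x = float(r.real)
        # polish with a few Newton steps on the polynomial itself
        for _ in range(3):
            fp = np.polyval(deriv, x)
            if fp == 0.0:
                break
            x -= np.polyval(coeffs, x) / fp
        if x > 0.0:
            real.append(x)
    real.sort()
    merged: list[list[float]] = []
    for x in real:
        if merged and abs(x - merged[-1][0]) < _MERGE_TOL:
            merged[-1][1] += 1
        else:
            merged.append([x, 1])
    return [(x, int(m)) for x, m in merged]


def coexistence_equilibria(p: ModelParams) -> list[Equilibrium]:
    """All interior equilibria ``(x*, y*)`` with both components positive.

    Roots of the quartic are found via the companion matrix, Newton-polished,
    deduplicated (a nullcline tangency is reported once with multiplicity 2)
    and filtered by strict positivity of ``y*``.  Sorted ascending in x.
    An empty list is a valid answer (e.g. whenever ``beta <= a d``).
    """
    q = quartic_coefficients(p)
    out = []
    for x, mult in _positive_real_roots(q.coeffs()):
        y = float(predator_nullcline_y(x, p))
        if y > _Y_POS_TOL:
            out.append(Equilibrium(x=x, y=y, kind="coexistence", multiplicity=mult))
    return out


def boundary_equilibria(p: ModelParams) -> list[Equilibrium]:
    """E0, E1 and (strong Allee with 0 < l < 1 only) E2."""
    out = [
        Equilibrium(x=0.0, y=0.0, kind="trivial"),
        Equilibrium(x=1.0, y=0.0, kind="axial_capacity"),
    ]
    if p.allee and 0.0 < p.l < 1.0:
        out.append(Equilibrium(x=float(p.l), y=0.0, kind="axial_threshold"))
    return out


def no_allee_equilibrium(p: ModelParams) -> list[Equilibrium]:
    """Interior equilibria of the logistic (no-Allee) variant.

    Substituting the predator nullcline into the prey nullcline
    ``x (1 - x) = beta x y / ((1+a x)(1+b y))`` gives the cubic

        b (1 + a x) x (1 - x) - beta x + d (1 + a x) = 0.

    Positive roots with ``y* > 0`` are returned, sorted ascending in x.
    """
    if p.allee:
        raise UnsupportedVariantError(
            "no_allee_equilibrium applies to the logistic variant only"
        )
    # b(1+ax)x(1-x) - beta x + d(1+ax), descending powers
    coeffs = np.array(
        [
            -p.a * p.b,
            p.b * (p.a - 1.0),
            p.b + p.a * p.d - p.beta,
            p.d,
        ]
    )
    out = []
    for x, mult in _positive_real_roots(coeffs):
        y = float(predator_nullcline_y(x, p))
        if y > _Y_POS_TOL:
            out.append(Equilibrium(x=x, y=y, kind="coexistence", multiplicity=mult))
    return out


def all_equilibria(p: ModelParams) -> list[Equilibrium]:
    """Boundary plus interior equilibria for either model variant."""
    interior = coexistence_equilibria(p) if p.allee else no_allee_equilibrium(p)
    return boundary_equilibria(p) + interior


def residuals(eq: Equilibrium, p: ModelParams) -> tuple[float, float]:
    """Reaction-rate residuals at an equilibrium (should both be ~0)."""
    fx, fy = reaction_rhs(eq.x, eq.y, p)
    return float(fx), float(fy)
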