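"""Linear spatial stability: dispersion relation and Turing conditions.

Linearizing the reaction-diffusion system about a homogeneous coexistence
state and inserting a plane-wave perturbation ``exp(mu t + i k.r)`` gives
the dispersion relation

    (J11 - k^2 d1 - mu)(J22 - k^2 d2 - mu) - J12 J21 = 0,

i.e. ``mu^2 + alpha_k mu + beta_k = 0`` with

    alpha_k = k^2 (d1 + d2) - (J11 + J22),
    beta_k  = d1 d2 k^4 - (d1 J22 + d2 J11) k^2 + det(J).

Diffusion-driven (Turing) instability of a state that is stable without
diffusion requires

    (i)   tr(J) < 0                (ODE-stable)
    (ii)  det(J) > 0               (ODE-stable)
    (iii) d1 J22 + d2 J11 > 0      (activator must diffuse slower)
    (iv)  (d1 J22 + d2 J11)^2 / (4 d1 d2) > det(J),

(iv) implying (iii) given (ii); (ii) and (iv) together put the minimum of
``beta_k`` below zero over a band of unstable wavenumbers around
``k_c^2 = (d1 J22 + d2 J11)/(2 d1 d2)``.  The wavenumber ``k`` is treated
as continuous (large-domain limit).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .equilibria import Equilibrium, coexistence_equilibria, no_allee_equilibrium
from .model_core import DiffusionParams, ModelParams, jacobian

__all__ = [
    "DispersionResult",
    "TuringReport",
    "dispersion",
    "neumann_mode_k2",
    "turing_conditions",
    "turing_scan",
]


def neumann_mode_k2(length: float, max_mode: int) -> np.ndarray:
    """Squared wavenumbers of the discrete Neumann modes on a square side.

    On a domain of side ``length`` with zero-flux boundaries the admissible
    perturbation modes are cos(n pi xi / L) cos(m pi eta / L), so
    k^2 = (pi/L)^2 (n^2 + m^2).  Returns the sorted unique k^2 values for
    0 <= n, m <= max_mode (excluding the homogeneous mode n = m = 0).
    By default the package treats k as continuous (large-domain limit);
    this helper supports small-domain studies where only quantized modes
    can destabilize.
    """
    n = np.arange(max_mode + 1)
    sq = (n[:, None] ** 2 + n[None, :] ** 2).ravel()
    sq = np.unique(sq[sq > 0])
    return (np.pi / length) ** 2 * sq


@dataclass(frozen=True)
class DispersionResult:
    """Growth rates of a spatial mode with squared wavenumber ``k2``."""

    k2: float
    alpha_k: float
    beta_k: float
    mu_plus: complex
    mu_minus: complex

    @property
    def max_re(self) -> float:
        return max(self.mu_plus.real, self.mu_minus.real)


@dataclass(frozen=True)
class TuringReport:
    """Outcome of the four Turing conditions at one equilibrium."""

    cond_i: bool
    cond_ii: bool
    cond_iii: bool
    cond_iv: bool
    k2_crit: float | None
    band: tuple[float, float] | None
    turing_unstable: bool


def _jac_entries(p: ModelParams, eq: Equilibrium):
    J = jacobian(eq.x, eq.y, p)
    return J[0, 0], J[0, 1], J[1, 0], J[1, 1]


def dispersion(
    k2: float, p: ModelParams, dp: DiffusionParams, eq: Equilibrium
) -> DispersionResult:
    """Both roots of the mode-``k2`` characteristic quadratic."""
    J11, J12, J21, J22 = _jac_entries(p, eq)
    alpha = k2 * (dp.d1 + dp.d2) - (J11 + J22)
    beta = dp.d1 * dp.d2 * k2 * k2 - (dp.d1 * J22 + dp.d2 * J11) * k2 + (
        J11 * J22 - J12 * J21
    )
    disc = complex(alpha * alpha - 4.0 * beta) ** 0.5
    mu_p = (-alpha + disc) / 2.0
    mu_m = (-alpha - disc) / 2.0
    return DispersionResult(
        k2=float(k2), alpha_k=float(alpha), beta_k=float(beta),
        mu_plus=complex(mu_p), mu_minus=complex(mu_m),
    )


def turing_conditions(
    p: ModelParams, dp: DiffusionParams, eq: Equilibrium
) -> TuringReport:
    """Evaluate the four Turing-instability conditions at a coexistence state."""
    J11, J12, J21, J22 = _jac_entries(p, eq)
    tr = J11 + J22
    det = J11 * J22 - J12 * J21
    s = dp.d1 * J22 + dp.d2 * J11
    cond_i = tr < 0
    cond_ii = det > 0
    cond_iii = s > 0
    # (iv) in the signed form s > 2 sqrt(d1 d2 det): with det > 0 this forces
    # s > 0, so (iv) and (ii) together encapsulate (iii)
    cond_iv = det >= 0 and s > 2.0 * np.sqrt(dp.d1 * dp.d2 * det)
    k2_crit = s / (2.0 * dp.d1 * dp.d2) if s > 0 else None
    band = None
    disc = s * s - 4.0 * dp.d1 * dp.d2 * det
    if s > 0 and disc > 0:
        sq = np.sqrt(disc)
        k2m = (s - sq) / (2.0 * dp.d1 * dp.d2)
        k2p = (s + sq) / (2.0 * dp.d1 * dp.d2)
        if k2p > 0:
            band = (max(k2m, 0.0), k2p)
    return TuringReport(
        cond_i=bool(cond_i),
        cond_ii=bool(cond_ii),
        cond_iii=bool(cond_iii),
        cond_iv=bool(cond_iv),
        k2_crit=k2_crit,
        band=band,
        turing_unstable=bool(cond_i and cond_ii and cond_iv),
    )


def _unique_interior(p: ModelParams) -> Equilibrium | None:
    eqs = coexistence_equilibria(p) if p.allee else no_allee_equilibrium(p)
    if len(eqs) == 1 and eqs[0].multiplicity == 1:
        return eqs[0]
    return None


def turing_scan(
    p_base: ModelParams,
    dp: DiffusionParams,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
):
    """Scan two reaction parameters for Turing instability.

    ``axis1``/``axis2`` are ``(name, values)`` pairs over reaction-parameter
    names.  Returns ``(mask, reports)`` where ``mask[i, j]`` is +1 when the
    point with ``axis1=values1[i]``, ``axis2=values2[j]`` is
    Turing-unstable, 0 when stable, and -1 (indeterminate) when the
    coexistence state is absent or non-unique (the linear analysis assumes
    a unique homogeneous state).  ``reports[i][j]`` holds the
    :class:`TuringReport` or ``None`` for indeterminate cells.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    mask = np.zeros((len(vals1), len(vals2)), dtype=int)
    reports: list[list[TuringReport | None]] = []
    for i, v1 in enumerate(vals1):
        row: list[TuringReport | None] = []
        for j, v2 in enumerate(vals2):
            p = replace(p_base, **{name1: float(v1), name2: float(v2)})
            eq = _unique_interior(p)
            if eq is None:
                mask[i, j] = -1
                row.append(None)
                continue
            rep = turing_conditions(p, dp, eq)
            mask[i, j] = 1 if rep.turing_unstable else 0
            row.append(rep)
        reports.append(row)
    return mask, reports
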