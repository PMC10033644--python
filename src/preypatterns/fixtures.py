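"""Registry of reference parameter sets and synthetic test fields.

Every study condition used in the reference figures is registered here as
an immutable :class:`FixtureEntry` under a ``figN``/``figNx`` key: nullcline
multiplicity cases (strong and weak Allee), phase-portrait/bistability and
limit-cycle cases, and the pattern-formation runs with and without the
Allee term.  ``expected`` carries the annotation transcribed from the
source figure caption (equilibrium count, stability words, pattern word) —
never a computed value — so regression failures show their provenance.

Also provides the seeded random initial condition used by the
reaction-diffusion runs and deterministic synthetic fields of known
morphology (spots / holes / stripes) for exercising the pattern
classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._errors import UnknownFixtureError
from .model_core import DiffusionParams, ModelParams

__all__ = [
    "FixtureEntry",
    "get_fixture",
    "list_fixtures",
    "registry_json",
    "perturbed_initial_condition",
    "morphology_fixture",
]


@dataclass(frozen=True)
class FixtureEntry:
    """One registered parameter set with its caption annotation."""

    key: str
    params: ModelParams
    diffusion: DiffusionParams | None = None
    expected: dict | None = None
    partial: bool = False  # caption does not pin every parameter

    def to_dict(self) -> dict:
        d = {"key": self.key, "params": self.params.to_dict(), "partial": self.partial}
        d["diffusion"] = asdict(self.diffusion) if self.diffusion else None
        d["expected"] = self.expected
        return d


def _mp(l, beta, a, b, d, allee=True, permissive=False):
    return ModelParams(l=l, beta=beta, a=a, b=b, d=d, allee=allee, permissive=permissive)


_D = DiffusionParams  # brevity below


def _build_registry() -> dict[str, FixtureEntry]:
    r: dict[str, FixtureEntry] = {}
    # fig4's caption value l=-2 needs permissive mode; the annotation records
    # that, so the construction warning is suppressed during registry build
    import warnings as _w

    _stack = _w.catch_warnings()
    _stack.__enter__()
    _w.simplefilter("ignore", UserWarning)

    def add(key, params, diffusion=None, expected=None, partial=False):
        r[key] = FixtureEntry(key, params, diffusion, expected, partial)

    # nullcline multiplicity, strong Allee
    add("fig1a", _mp(0.1, 10.0, 10.5, 5.2, 0.3),
        expected={"note": "caption gives beta only", "count": 3}, partial=True)
    add("fig1b", _mp(0.01, 7.8, 10.5, 5.2, 0.3), expected={"count": 3})
    add("fig1c", _mp(0.2, 9.0, 7.5, 4.1, 0.7), expected={"count": 2})
    add("fig1d", _mp(0.2, 5.0, 10.5, 5.2, 0.3), expected={"count": 2})
    add("fig1e", _mp(0.2, 10.1267155062337, 7.5, 4.1, 0.7),
        expected={"count": 1, "tangency": True})
    add("fig1f", _mp(0.01, 1.0, 0.5, 0.9, 0.3), expected={"count": 1})
    add("fig1g", _mp(0.1, 5.0, 10.5, 5.2, 0.3), expected={"count": 1})
    add("fig1h", _mp(0.2, 10.7, 7.5, 4.1, 0.7), expected={"count": 0})

    # nullcline multiplicity, weak Allee
    add("fig2a", _mp(-0.2, 10.7, 10.9, 3.2, 0.3), expected={"count": 3})
    add("fig2b", _mp(-0.2, 10.7, 10.9, 5.2, 0.3), expected={"count": 3})
    add("fig2c", _mp(-0.2, 11.494054912906, 10.9, 3.2, 0.3),
        expected={"count": 2, "tangency": True})
    add("fig2d", _mp(-0.2, 1.0, 0.5, 0.9, 0.3), expected={"count": 1})
    add("fig2e", _mp(-0.2, 6.4, 10.5, 5.2, 0.3), expected={"count": 1})

    # phase portraits: bistability with separatrix
    add("fig3", _mp(0.1, 9.8, 7.8, 4.1, 0.7),
        expected={"count": 3, "attractors": ["E0", "E3"],
                  "note": "stable manifolds of the interior saddles separate E0 and E3"})
    add("fig4", _mp(-2.0, 10.5, 11.0, 3.0, 0.3, permissive=True),
        expected={"count": 3, "attractors": ["E0", "E3"],
                  "note": "weak-Allee caption value l=-2 (permissive mode)"})

    # limit cycles
    add("fig5", _mp(0.04, 1.1, 0.5, 1.0, 0.3),
        expected={"count": 1, "limit_cycle": True,
                  "note": "unstable interior point surrounded by a stable limit cycle"})
    add("fig6", _mp(-0.01, 1.2, 0.5, 1.0, 0.3),
        expected={"count": 1, "limit_cycle": True})

    # pattern formation, Allee variant
    add("fig7", _mp(0.01, 1.0, 0.5, 0.9, 0.3), _D(0.1, 20.0),
        expected={"pattern": "holes and short stripes"})
    for key, d1 in (("fig8a", 0.05), ("fig8b", 0.1), ("fig8c", 0.2), ("fig8d", 0.5)):
        add(key, _mp(0.01, 1.05, 0.5, 0.9, 0.3), _D(d1, 20.0),
            expected={"pattern": "holes"})
    add("fig9a", _mp(-0.01, 1.05, 0.5, 0.9, 0.3), _D(0.1, 20.0),
        expected={"pattern": "holes"})
    add("fig9b", _mp(-0.04, 1.05, 0.5, 0.9, 0.3), _D(0.1, 20.0),
        expected={"pattern": "holes and short stripes"})
    add("fig10a", _mp(-0.01, 1.05, 0.5, 1.0, 0.3), _D(0.1, 20.0),
        expected={"pattern": "holes"})
    add("fig10b", _mp(0.04, 1.05, 0.5, 1.0, 0.3), _D(0.1, 20.0),
        expected={"pattern": "holes"})
    add("fig11a", _mp(-0.03, 1.1, 0.6, 0.98, 0.3), _D(0.1, 20.0),
        expected={"pattern": "holes and short stripes"})
    add("fig11b", _mp(0.0, 1.1, 0.6, 0.98, 0.3), _D(0.1, 20.0),
        expected={"pattern": "holes"})
    add("fig11c", _mp(0.025, 1.1, 0.6, 0.98, 0.3), _D(0.1, 20.0),
        expected={"pattern": "holes"})

    # pattern formation, no-Allee variant: beta sequence then d sequence
    fig12_patterns = {
        4.8: "holes", 4.9: "hole-stripe mixtures", 5.1: "stripes",
        5.2: "labyrinthine", 5.4: "spot-stripe mixtures", 6.0: "spots",
    }
    for idx, (beta, pat) in zip("abcdef", fig12_patterns.items()):
        add(f"fig12{idx}", _mp(0.0, beta, 2.1, 3.01, 0.2, allee=False),
            _D(0.1, 20.0), expected={"pattern": pat})
    fig13_patterns = {
        0.2: "spots", 0.24: "spot-stripe mixtures", 0.261: "stripes",
        0.3: "labyrinthine", 0.32: "hole-stripe mixtures", 0.34: "holes",
    }
    for idx, (d, pat) in zip("abcdef", fig13_patterns.items()):
        add(f"fig13{idx}", _mp(0.0, 6.0, 2.1, 3.01, d, allee=False),
            _D(0.1, 20.0), expected={"pattern": pat})
    _stack.__exit__(None, None, None)
    return r


_REGISTRY = _build_registry()


def get_fixture(key: str) -> FixtureEntry:
    """Look up a registered parameter set; raise on unknown keys."""
    try:
        return _REGISTRY[key]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture key {key!r}; known keys: {', '.join(sorted(_REGISTRY))}"
        ) from None


def list_fixtures() -> list[str]:
    return sorted(_REGISTRY)


def registry_json() -> str:
    """The whole registry as a JSON object keyed by fixture key."""
    return json.dumps({k: _REGISTRY[k].to_dict() for k in sorted(_REGISTRY)}, indent=2)


def perturbed_initial_condition(eq_xy, n: int, amp: float, seed: int):
    """Fields ``eq * (1 + amp * U)`` with ``U ~ Uniform[-1, 1]`` i.i.d., seeded.

    ``amp = 0`` gives exactly homogeneous fields at the equilibrium.
    """
    if amp < 0:
        raise ValueError(f"perturbation amplitude must be >= 0, got {amp}")
    x_star, y_star = float(eq_xy[0]), float(eq_xy[1])
    rng = np.random.default_rng(seed)
    x_f = x_star * (1.0 + amp * rng.uniform(-1.0, 1.0, size=(n, n)))
    y_f = y_star * (1.0 + amp * rng.uniform(-1.0, 1.0, size=(n, n)))
    return x_f, y_f


def morphology_fixture(kind: str, n: int = 64) -> np.ndarray:
    """Deterministic synthetic field with a named morphology.

    ``spots``: Gaussian bumps on a flat background (hot spots);
    ``holes``: the same bumps subtracted (cold spots);
    ``stripes``: parallel sinusoidal bands.
    """
    if n < 32:
        raise ValueError(f"morphology fixtures need n >= 32, got {n}")
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    if kind in ("spots", "holes"):
        bumps = np.zeros((n, n))
        spacing = n // 4
        sigma = n / 24.0
        for ci in range(spacing // 2, n, spacing):
            for cj in range(spacing // 2, n, spacing):
                bumps += np.exp(-((ii - ci) ** 2 + (jj - cj) ** 2) / (2 * sigma**2))
        return 1.0 + bumps if kind == "spots" else 1.0 - bumps
    if kind == "stripes":
        period = n / 4.0
        return 1.0 + 0.5 * np.sin(2.0 * np.pi * ii / period)
    raise ValueError(f"unknown morphology kind {kind!r}")
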