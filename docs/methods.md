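# Methods

## Model and assumptions

The package analyzes the planar reaction system

    dx/dt = x(1 − x)(x − l) − βxy/((1 + ax)(1 + by)),
    dy/dt = βxy/((1 + ax)(1 + by)) − dy,

and its two-species reaction–diffusion extension with Fickian self-diffusion
(coefficients d₁, d₂) on a square domain with homogeneous Neumann (zero-flux)
boundaries.  The variables are dimensionless densities obtained from the
dimensional model by x = X/K, y = Y/(KE), t = KRT, with parameters
l = L/K, β = ME/R, a = AK, b = BKE, d = D/(KR), d₁ = D₁/(RKL₁²),
d₂ = D₂/(RKL₁²).  Assumptions inherited from the model class:

* prey growth is logistic with a multiplicative Allee factor (x − l):
  strong Allee (extinction threshold) for l > 0, weak for −1 < l ≤ 0;
* predation follows the Crowley–Martin form, i.e. predator interference
  acts regardless of handling state, so the denominator factors as
  (1 + ax)(1 + by);
* predators are specialists (no alternative food): dy/dt < 0 when x = 0;
* the environment is homogeneous; diffusion is the only spatial process.

Setting `allee=False` replaces the growth factor with plain logistic
x(1 − x); every downstream operation (equilibria, stability, Turing
analysis, simulation) accepts both variants through the same interface.

Parameter admissibility: β, d > 0; a, b ≥ 0 (a = 0 and/or b = 0 are the
Harrison / Holling II / mass-action reductions and are retained because the
package's own reduction tests exercise them); l > −1 under the Allee
variant.  A `permissive` flag admits l ≤ −1 with a warning — one published
phase portrait uses l = −2, which is outside the weak-Allee range but still
defines a smooth vector field; we store that parameter set with the flag
rather than silently rejecting or silently accepting it.

A note on two printed formulas.  The equilibrium Jacobian used everywhere
here is obtained by direct differentiation of the right-hand side and is
verified against a central-difference oracle; at an interior equilibrium
J₁₁ = x(1 + l − 2x) **+** βaxy/((1+ax)²(1+by)) (the predation correction
enters with a plus sign once the prey-nullcline identity is substituted).
Likewise the eigenvalues at the threshold state (l, 0) are **+**l(1 − l)
and βl/(1 + al) − d; the positive first eigenvalue is what makes the Allee
threshold repelling along the prey axis and (l, 0) a saddle whenever the
predator cannot invade there — consistent with the phase portraits in the
bistable regime.

## Equilibrium enumeration

Boundary states: (0,0) and (1,0) always; (l,0) only for 0 < l < 1 (for
l ≤ 0 it leaves the positive quadrant, for l ≥ 1 it collides with or passes
the capacity state).  Interior states eliminate y through the predator
nullcline y* = (βx − (1+ax)d)/(bd(1+ax)) and solve the quartic

    Q(x) = abx⁴ + b(1 − a(1+l))x³ + (lab − b(1+l))x² + (lb + β − ad)x − d

(the no-Allee variant reduces to the cubic b(1+ax)x(1−x) − βx + d(1+ax)).
Roots come from the companion matrix (numpy.roots), are polished with three
Newton steps, accepted as real when |Im| < 1e−8·max(1, |Re|), filtered by
x > 0 and y* > 1e−12, and deduplicated.  Near-coincident roots are merged
into a single equilibrium of multiplicity 2 when |x_i − x_j| < 1e−6: a
double root perturbed by O(ε) in the coefficients splits by O(√ε), so
parameter values printed to ~12 significant digits can leave a residual
split of order 1e−6; the merge tolerance is chosen at that scale (all
genuinely distinct roots in the reference parameter sets are separated by
more than 1e−3).  No upper bound x < 1 is imposed; filtering is by
positivity only.

## Stability and bifurcations

Classification uses the trace/determinant of the analytic Jacobian:
saddle iff det < 0; focus vs node by the sign of tr² − 4·det; "marginal"
when |tr| < 1e−9 with det > 0 or |det| < 1e−12.

**Hopf in β.**  The tracked interior equilibrium is the one continuous in β
from the bracket's left endpoint (nearest-x matching over a 64-point scan;
a vanishing branch raises a branch-discontinuity error).  tr(J(β)) along
the branch is bracketed for a sign change and refined with Brent's method
to xtol 1e−12.  Reported: β_c, ω₀ = √det(J) (validity requires det > 0),
and the transversality dtr/dβ as a centred finite difference along the
branch — the finite difference is preferred over the printed closed form
because the equilibrium coordinates themselves move with β.

**Fold in β.**  β enters Q only through the coefficient of x, linearly.
The fold is bracketed by bisection on the total interior-equilibrium count
(multiplicity-weighted) to width 1e−10, then polished by Newton on the
2×2 system Q(x; β) = 0, ∂Q/∂x(x; β) = 0, whose Jacobian is available in
closed form (∂Q/∂β = x, ∂Q'/∂β = 1).  Both reference folds reproduce the
printed 13-digit values to ~1e−13 relative.

**Trajectories.**  scipy's RK45 (Dormand–Prince) with rtol 1e−8,
atol 1e−10; components dipping into [−1e−12, 0) are clipped to zero
(the model is only meaningful on the closed quadrant); any state magnitude
above 1e6 raises a blow-up error.

**Limit cycles.**  From the equilibrium plus a 1% radial offset, a
transient of 2000 time units is discarded, then upward crossings of the
Poincaré section x = x* are collected over another 2000 units at tight
tolerance (rtol 1e−9).  A cycle is reported when successive crossing
heights converge (relative change < 1e−4) to a value bounded away from y*
(> 1e−3 relative); a spiral into the equilibrium returns found = false.
The period is the last inter-crossing interval and amplitude extents are
measured over 1.5 periods.

**Separatrices and basins.**  The stable manifold of a saddle is grown by
integrating the reversed flow from saddle ± 1e−6·v_stable, truncated at the
box [0, 1.5] × [0, y_max].  Basin labels come from integrating each initial
state forward and matching the endpoint to a supplied attractor list
(point attractors within 1e−3; a detected cycle by its inflated bounding
box), with "unresolved" otherwise.

## Turing analysis

Linearization about the unique interior state with a plane-wave ansatz
gives μ² + α_k μ + β_k = 0, α_k = k²(d₁+d₂) − tr J,
β_k = d₁d₂k⁴ − (d₁J₂₂ + d₂J₁₁)k² + det J.  The four instability conditions
are evaluated exactly, with (iv) in the signed form
d₁J₂₂ + d₂J₁₁ > 2√(d₁d₂ det J) so that (ii) ∧ (iv) ⇒ (iii) holds
structurally.  The critical squared wavenumber is
k²_c = (d₁J₂₂ + d₂J₁₁)/(2d₁d₂) and the unstable band is the real-root
interval of β_k(k²), computed in closed form.  k is treated as continuous
(large-domain limit); the domain length for mode quantization is
deliberately not fixed.  Parameter scans mark cells whose interior
equilibrium is absent or non-unique as "indeterminate" (−1) rather than
stable, because the linear analysis presumes a unique homogeneous state.

## Reaction–diffusion simulation

Explicit Euler in time, five-point Laplacian in space with mirrored ghost
cells (second-order zero-flux).  Reference protocol defaults: 200×200
grid, spacing h = 1, step dt = 0.01, horizon t = 5000; the diffusive
stability bound dt ≤ h²/(4·max(d₁,d₂)) is enforced at configuration time.
Initial data are the homogeneous coexistence state multiplied by
1 + amp·U with U ~ Uniform[−1, 1] i.i.d. from a seeded generator;
amp defaults to 0.01 ("small random perturbation"; the exact amplitude and
RNG of the reference runs are unspecified, so these are declared choices
recorded in run manifests).  Negative undershoots are clipped to zero and
counted as a quality metric rather than erroring, since explicit Euler can
undershoot near sharp fronts.  Runs with the same seed are bitwise
reproducible.

Test- and acceptance-scale runs use a 64×64 grid.  Pattern wavelengths
here are ~16 grid cells, so a 64² domain holds ~4×4 pattern units — enough
to measure variance, skewness and morphology, not enough for the large-
domain pattern statistics a 200² run would give.  Horizons are chosen per
regime from the linear growth rate: the holes/short-stripes reference set
sits close to the instability threshold (max Re μ ≈ 0.002) and saturates
only around t ≈ 2000–2500, so its stationarity check runs to t = 3000;
the faster no-Allee sets (max Re μ ≈ 0.008–0.017) use t = 1000.

## Pattern morphology

The prey deviation field (field minus spatial mean) is thresholded at
zero; 4-connected components of each sign are counted and their grid
circularity 4πA/P² computed (P counts exposed cell edges, so a rasterized
disk scores ≈ π²/16 ≈ 0.62 and a long stripe ≈ πw/L).  A sign whose
components are compact (median circularity > 0.45, ≥ 5 components, areas
≥ 4 cells) names a spot phase — "hot spots" for above-mean prey,
"cold spots" (holes) for below-mean; elongated components of both signs
give "stripes/labyrinthine"; compact components of both signs, "mixture";
relative variance below 1e−10, "homogeneous".  The thresholds are
calibrated on the constructed morphology fixtures (Gaussian bumps,
inverted bumps, sinusoidal bands).  Field skewness is the cheap polarity
proxy: negative in hole-dominated patterns, positive in spot-dominated
ones.

## What the synthetic inputs do and do not represent

There is no observational data in this problem: the study conditions are
the ~25 published figure parameter sets, all registered in
`preypatterns.fixtures` with their caption annotations (equilibrium
counts, stability words, pattern words) transcribed verbatim as strings —
never computed values — so regressions display their provenance.  The
seeded uniform perturbation emulates the "small random perturbation" of
the reference protocol; it does not emulate demographic noise,
environmental heterogeneity, or any real spatial ecology, so passing
pattern tests demonstrates the model's behavior, not fidelity to field
data.  One caption set (the weak-Allee phase portrait with l = −2) is
registered under the permissive flag; another (a nullcline panel whose
caption omits four of five parameters) is registered as partial and
excluded from regressions.

## Known limitations

* No first-Lyapunov-coefficient computation: Hopf criticality
  (super/subcritical) is inferred from simulation, not normal-form theory.
* No two-parameter continuation, delay, noise, travelling waves or
  non-local interactions.
* The explicit Euler scheme is first-order in time; it matches the
  reference protocol but is not the efficient choice for stiff regimes
  (d₂/d₁ here is 200, still comfortably within the CFL bound at dt=0.01).
* The morphology classifier is a heuristic over connected components;
  near phase boundaries (spot–stripe mixtures) its label is "mixture" by
  construction rather than a sharp category.
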