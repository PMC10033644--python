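"""Stability classification, Hopf/fold location, cycles, separatrices."""

import numpy as np
import pytest

from preypatterns._errors import (
    BranchDiscontinuityError,
    DomainError,
    NoFoldError,
    NotASaddleError,
)
from preypatterns.dynamics import (
    basin_classify,
    classify,
    detect_limit_cycle,
    fold_beta,
    hopf_critical_beta,
    integrate,
    separatrix,
)
from preypatterns.equilibria import boundary_equilibria, coexistence_equilibria
from preypatterns.fixtures import get_fixture
from preypatterns.model_core import ModelParams, jacobian

from conftest import random_model_params
from dataclasses import replace


class TestClassify:
    def test_extinction_state_stable_under_strong_allee(self):
        p = ModelParams(l=0.1, beta=1.0, a=0.5, b=1.0, d=0.3)
        e0 = classify(boundary_equilibria(p)[0], p)
        assert e0.stability == "stable node"

    def test_extinction_state_saddle_under_weak_allee(self):
        p = ModelParams(l=-0.01, beta=1.2, a=0.5, b=1.0, d=0.3)
        e0 = classify(boundary_equilibria(p)[0], p)
        assert e0.stability == "saddle"

    def test_capacity_state_saddle_when_predator_invades(self):
        # beta > d(1+a) means predators grow at (1, 0)
        p = ModelParams(l=0.04, beta=1.1, a=0.5, b=1.0, d=0.3)
        e1 = classify(boundary_equilibria(p)[1], p)
        assert e1.stability == "saddle"

    def test_capacity_state_stable_when_predator_dies_out(self):
        p = ModelParams(l=0.04, beta=0.4, a=0.5, b=1.0, d=0.3)  # beta < d(1+a)
        e1 = classify(boundary_equilibria(p)[1], p)
        assert e1.stability == "stable node"

    def test_boundary_eigenvalues_closed_forms(self, rng):
        """E0, E1, E2 eigenvalues equal (-l, -d), (l-1, beta/(1+a)-d),
        (l(1-l), beta*l/(1+a*l)-d) to 1e-12."""
        for p in random_model_params(rng, 100):
            eig0 = sorted(np.linalg.eigvals(jacobian(0, 0, p)).real)
            assert eig0 == pytest.approx(sorted([-p.l, -p.d]), abs=1e-12)
            eig1 = sorted(np.linalg.eigvals(jacobian(1, 0, p)).real)
            assert eig1 == pytest.approx(
                sorted([p.l - 1, p.beta / (1 + p.a) - p.d]), abs=1e-12
            )
            if 0 < p.l < 1:
                eig2 = sorted(np.linalg.eigvals(jacobian(p.l, 0, p)).real)
                expect = sorted([p.l * (1 - p.l), p.beta * p.l / (1 + p.a * p.l) - p.d])
                assert eig2 == pytest.approx(expect, abs=1e-12)

    def test_bistable_portrait_classification(self, fig3):
        labels = [classify(e, fig3.params).stability
                  for e in coexistence_equilibria(fig3.params)]
        assert labels == ["unstable focus", "saddle", "stable focus"]


class TestHopf:
    def test_critical_point_contract(self, fig5):
        res = hopf_critical_beta(fig5.params, (0.8, 1.5))
        assert res.found and res.valid
        p_c = replace(fig5.params, beta=res.beta_c)
        eq = coexistence_equilibria(p_c)[0]
        J = jacobian(eq.x, eq.y, p_c)
        tr, det = J[0, 0] + J[1, 1], float(np.linalg.det(J))
        assert abs(tr) < 1e-9
        assert det > 0
        eig = np.linalg.eigvals(J)
        assert np.allclose(sorted(eig.imag), [-res.omega0, res.omega0], atol=1e-7)
        assert res.omega0 == pytest.approx(np.sqrt(det), rel=1e-9)

    def test_classification_flips_across_critical_beta(self, fig5):
        res = hopf_critical_beta(fig5.params, (0.8, 1.5))
        labels = {}
        for db in (-1e-3, +1e-3):
            p = replace(fig5.params, beta=res.beta_c + db)
            labels[db] = classify(coexistence_equilibria(p)[0], p).stability
        assert {labels[-1e-3], labels[1e-3]} == {"stable focus", "unstable focus"}

    def test_transversality_sign_matches_secant_slope(self, fig5):
        res = hopf_critical_beta(fig5.params, (0.8, 1.5))

        def trace(beta):
            p = replace(fig5.params, beta=beta)
            eq = coexistence_equilibria(p)[0]
            J = jacobian(eq.x, eq.y, p)
            return J[0, 0] + J[1, 1]

        secant = (trace(res.beta_c + 0.01) - trace(res.beta_c - 0.01)) / 0.02
        assert np.sign(res.transversality) == np.sign(secant)
        assert res.transversality != 0

    def test_not_found_when_trace_keeps_sign(self, fig5):
        res = hopf_critical_beta(fig5.params, (0.8, 0.95))
        assert not res.found

    def test_error_without_coexistence_state(self):
        p = ModelParams(l=0.2, beta=0.5, a=10.0, b=1.0, d=0.5)
        with pytest.raises(BranchDiscontinuityError):
            hopf_critical_beta(p, (0.5, 0.6))


class TestFold:
    def test_strong_allee_reference_value(self):
        p = ModelParams(l=0.2, beta=9.0, a=7.5, b=4.1, d=0.7)
        res = fold_beta(p, (9.0, 10.7))
        assert res.beta_sn == pytest.approx(10.1267155062337, rel=1e-6)
        assert abs(res.count_below - res.count_above) == 2

    def test_weak_allee_reference_value(self):
        p = ModelParams(l=-0.2, beta=11.0, a=10.9, b=3.2, d=0.3)
        res = fold_beta(p, (10.7, 12.0))
        assert res.beta_sn == pytest.approx(11.494054912906, rel=1e-6)

    def test_tangency_residuals(self):
        from preypatterns.equilibria import quartic_coefficients

        p = ModelParams(l=0.2, beta=9.0, a=7.5, b=4.1, d=0.7)
        res = fold_beta(p, (9.0, 10.7))
        q = quartic_coefficients(replace(p, beta=res.beta_sn))
        assert abs(q(res.x_tangency)) < 1e-9
        assert abs(q.derivative(res.x_tangency)) < 1e-9

    def test_count_changes_by_two_across_fold(self):
        p = ModelParams(l=0.2, beta=9.0, a=7.5, b=4.1, d=0.7)
        res = fold_beta(p, (9.0, 10.7))
        n_below = len(coexistence_equilibria(replace(p, beta=res.beta_sn - 1e-6)))
        n_above = len(coexistence_equilibria(replace(p, beta=res.beta_sn + 1e-6)))
        assert n_below - n_above == 2

    def test_error_when_no_fold_in_bracket(self):
        p = ModelParams(l=0.2, beta=9.0, a=7.5, b=4.1, d=0.7)
        with pytest.raises(NoFoldError):
            fold_beta(p, (9.0, 9.5))


class TestIntegrate:
    def test_fixed_point_stays_fixed(self, fig3):
        eq = coexistence_equilibria(fig3.params)[-1]  # the attractor
        tra = integrate(fig3.params, eq.state, 100.0)
        assert np.linalg.norm(tra.end - eq.state) < 1e-6

    def test_tolerance_halving_stability(self, fig5):
        s0 = (0.5, 0.2)
        end1 = integrate(fig5.params, s0, 50.0, rtol=1e-8, atol=1e-10).end
        end2 = integrate(fig5.params, s0, 50.0, rtol=5e-9, atol=5e-11).end
        assert np.linalg.norm(end1 - end2) < 1e-5

    def test_nonnegativity_preserved(self, fig5, rng):
        for _ in range(5):
            s0 = rng.uniform(0.01, 1.0, 2)
            tra = integrate(fig5.params, s0, 200.0)
            assert (tra.states >= 0).all()

    def test_rejects_negative_initial_state(self, fig5):
        with pytest.raises(DomainError):
            integrate(fig5.params, (-0.5, 0.1), 10.0)


class TestLimitCycle:
    def test_found_for_strong_allee_oscillator(self, fig5):
        eq = classify(coexistence_equilibria(fig5.params)[0], fig5.params)
        assert eq.stability == "unstable focus"
        rep = detect_limit_cycle(fig5.params, eq)
        assert rep.found
        assert rep.period > 0
        # the cycle encloses the equilibrium
        assert rep.x_extent[0] < eq.x < rep.x_extent[1]
        assert rep.y_extent[0] < eq.y < rep.y_extent[1]

    def test_found_for_weak_allee_oscillator(self):
        f = get_fixture("fig6")
        eq = classify(coexistence_equilibria(f.params)[0], f.params)
        assert detect_limit_cycle(f.params, eq).found

    def test_not_found_at_stable_coexistence(self, fig3):
        eq = classify(coexistence_equilibria(fig3.params)[-1], fig3.params)
        assert eq.stability == "stable focus"
        assert not detect_limit_cycle(fig3.params, eq).found


class TestSeparatrix:
    def test_branches_start_at_saddle_tangent_to_stable_eigenvector(self, fig3):
        eqs = [classify(e, fig3.params) for e in coexistence_equilibria(fig3.params)]
        sad = next(e for e in eqs if e.stability == "saddle")
        sep = separatrix(fig3.params, sad)
        J = jacobian(sad.x, sad.y, fig3.params)
        lam, V = np.linalg.eig(J)
        v = np.real(V[:, np.argmin(lam.real)])
        v /= np.linalg.norm(v)
        for br in sep.branches:
            assert np.linalg.norm(br[0] - sad.state) < 1e-5
            t = br[1] - br[0]
            t = t / np.linalg.norm(t)
            assert min(np.linalg.norm(t - v), np.linalg.norm(t + v)) < 1e-3

    def test_rejects_non_saddle(self, fig3):
        eqs = [classify(e, fig3.params) for e in coexistence_equilibria(fig3.params)]
        stable = next(e for e in eqs if e.stability == "stable focus")
        with pytest.raises(NotASaddleError):
            separatrix(fig3.params, stable)

    def test_threshold_manifold_splits_extinction_from_cycle(self, fig5):
        # points left of the stable manifold of (l, 0) collapse to extinction
        p = fig5.params
        left = integrate(p, (0.03, 0.05), 2000.0).end
        right = integrate(p, (0.30, 0.05), 2000.0).end
        assert np.linalg.norm(left) < 1e-4
        assert np.linalg.norm(right) > 0.05


class TestBasins:
    def test_attractor_cells_resolve_to_their_attractor(self, fig3):
        eqs = [classify(e, fig3.params) for e in coexistence_equilibria(fig3.params)]
        e0 = classify(boundary_equilibria(fig3.params)[0], fig3.params)
        e3 = next(e for e in eqs if e.stability == "stable focus")
        labels = basin_classify(fig3.params, [e0.state, e3.state], [e0, e3], t_end=200.0)
        assert labels[0].startswith("E:0")
        assert labels[1] == f"E:{e3.x:.6g},{e3.y:.6g}"

    def test_bistability_both_basins_populated(self, fig3):
        eqs = [classify(e, fig3.params) for e in coexistence_equilibria(fig3.params)]
        e0 = classify(boundary_equilibria(fig3.params)[0], fig3.params)
        e3 = next(e for e in eqs if e.stability == "stable focus")
        grid = [(x, y) for x in (0.2, 0.5, 0.9) for y in (0.02, 0.1)]
        labels = basin_classify(fig3.params, grid, [e0, e3], t_end=1500.0)
        assert any(lb.startswith("E:0,") or lb == "E:0,0" for lb in labels)
        assert any(lb == f"E:{e3.x:.6g},{e3.y:.6g}" for lb in labels)
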