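"""Constrained-maximization solver: expressions, systems, roots, tables."""

import itertools
from fractions import Fraction

import mpmath
import pytest
import sympy as sp

from epistable import (
    DomainError,
    NoSolutionError,
    SolverConfig,
    SolverSolution,
    UnderdeterminedSystemError,
    ValidationError,
    additive_model,
    build_max_heritability_system,
    build_max_prevalence_system,
    filter_solutions,
    find_max_heritability,
    find_max_prevalence,
    genotype_probabilities,
    heritability_expression,
    incompatible_model,
    prevalence_expression,
    solve_system,
    table_heritability,
    threshold_model,
)
from epistable.model_io import EpistasisModel
from .conftest import (
    WORKED_PREVALENCE,
    WORKED_TABLE,
    WORKED_X,
    WORKED_Y,
)

x, y = sp.symbols("x y")


def constant_model(c):
    return EpistasisModel(
        name="const", order=1, variables=(x, y),
        genotype_labels=("AA", "Aa", "aa"),
        expressions=(c, c, c),
    )


def loop_prevalence(model, dist, xv, yv):
    """Term-by-term summation oracle, plain floats."""
    total = 0.0
    for expr, pr in zip(model.expressions, dist.probabilities):
        total += float(expr.subs({x: xv, y: yv})) * float(pr)
    return total


def loop_heritability(model, dist, xv, yv):
    """Direct genetic-variance oracle scaled by the odds of being
    unaffected, plain floats."""
    pd = loop_prevalence(model, dist, xv, yv)
    vg = 0.0
    for expr, pr in zip(model.expressions, dist.probabilities):
        vg += (float(expr.subs({x: xv, y: yv})) - pd) ** 2 * float(pr)
    return vg * (1 - pd) / pd


class TestExpressions:
    def test_prevalence_at_worked_example_point(self, additive2, dist025):
        expr = prevalence_expression(additive2, dist025)
        # x recovered from the boundary condition x*(1+y)^4 = 1; the
        # published x is rounded to 4 decimals, which alone would shift
        # the prevalence by ~4e-4
        val = float(expr.subs({x: 1 / (1 + WORKED_Y) ** 4, y: WORKED_Y}))
        assert val == pytest.approx(WORKED_PREVALENCE, abs=5e-5)

    def test_constant_model_prevalence_is_the_constant(self):
        m = constant_model(sp.Rational(1, 2))
        dist = genotype_probabilities((0.3,))
        assert prevalence_expression(m, dist) == sp.Rational(1, 2)

    def test_prevalence_matches_term_by_term_loop(self):
        m = threshold_model(3)
        dist = genotype_probabilities((0.1, 0.1, 0.1))
        expr = prevalence_expression(m, dist)
        assert float(expr.subs({x: 0.5, y: 1})) == pytest.approx(
            loop_prevalence(m, dist, 0.5, 1), rel=1e-12
        )

    def test_heritability_at_solved_point(self, additive2, dist025):
        expr = heritability_expression(additive2, dist025)
        # at the 4-decimal-rounded published point the target is met to ~1e-5
        val = float(expr.subs({x: 1 / (1 + WORKED_Y) ** 4, y: WORKED_Y}))
        assert val == pytest.approx(0.2, abs=1e-4)

    def test_constant_model_heritability_is_zero(self):
        m = constant_model(sp.Rational(1, 3))
        dist = genotype_probabilities((0.3,))
        assert sp.simplify(heritability_expression(m, dist)) == 0

    def test_heritability_matches_direct_variance_loop(self):
        m = additive_model(2)
        dist = genotype_probabilities((0.3, 0.2))
        expr = heritability_expression(m, dist)
        assert float(expr.subs({x: 0.01, y: 2.5})) == pytest.approx(
            loop_heritability(m, dist, 0.01, 2.5), rel=1e-9
        )

    def test_order_mismatch_raises(self, additive2):
        with pytest.raises(DomainError):
            prevalence_expression(additive2, genotype_probabilities((0.25,)))


class TestSystems:
    def test_max_prevalence_second_equation(self, additive2, dist025):
        _, eq2 = build_max_prevalence_system(additive2, dist025, 0.2)
        assert sp.simplify(eq2.lhs - x * (1 + y) ** 4) == 0
        assert eq2.rhs == 1

    def test_threshold_second_equation_is_first_degree(self):
        m = threshold_model(2)
        dist = genotype_probabilities((0.25, 0.25))
        _, eq2 = build_max_prevalence_system(m, dist, 0.2)
        assert sp.simplify(eq2.lhs - x * (1 + y)) == 0

    def test_target_out_of_bounds(self, additive2, dist025):
        with pytest.raises(DomainError):
            build_max_prevalence_system(additive2, dist025, 1.5)
        with pytest.raises(DomainError):
            build_max_heritability_system(additive2, dist025, 0.0)

    def test_max_heritability_first_equation_is_prevalence(self, additive2, dist025):
        eq1, eq2 = build_max_heritability_system(additive2, dist025, 0.1)
        assert eq1.rhs == sp.Rational(1, 10)
        assert sp.simplify(eq1.lhs - prevalence_expression(additive2, dist025)) == 0


class TestSolveSystem:
    def test_worked_example_root(self, additive2, dist025):
        system = build_max_prevalence_system(additive2, dist025, 0.2)
        sols = solve_system(system)
        best = filter_solutions(sols, additive2, dist025, maximize="prevalence")
        xv, yv = best.variable_values
        assert round(float(xv), 4) == WORKED_X
        assert round(float(yv), 4) == WORKED_Y

    def test_underdetermined_system(self):
        with pytest.raises(UnderdeterminedSystemError):
            solve_system((sp.Eq(x - 1, 0), sp.Eq(x * 1, 1)))

    def test_residuals_are_tiny_at_roots(self, additive2, dist025):
        system = build_max_prevalence_system(additive2, dist025, 0.2)
        for sol in solve_system(system):
            assert sol.residuals[1] < 1e-20  # max-penetrance eq holds by construction


class TestFilter:
    def test_negative_candidate_discarded(self, additive2, dist025):
        good = SolverSolution(
            variable_values=(mpmath.mpf("0.00192942"), mpmath.mpf("3.7713732")),
            residuals=(1e-30, 1e-30),
        )
        bad = SolverSolution(
            variable_values=(mpmath.mpf("0.3"), mpmath.mpf("-2.1")),
            residuals=(0.0, 0.0),
        )
        cfg = SolverConfig(residual_tol=1e-4)  # published point is 4-decimal
        best = filter_solutions([good, bad], additive2, dist025, cfg)
        assert best is good
        assert bad.rejection_reason and "negative" in bad.rejection_reason

    def test_boundary_penetrance_accepted(self, additive2, dist025):
        sol = SolverSolution(
            variable_values=(mpmath.mpf("0.00192942"), mpmath.mpf("3.7713732")),
            residuals=(1e-30, 1e-30),
        )
        best = filter_solutions([sol], additive2, dist025, SolverConfig(residual_tol=1e-4))
        assert best.valid

    def test_all_rejected_raises_with_reasons(self, additive2, dist025):
        sol = SolverSolution(
            variable_values=(mpmath.mpf(2), mpmath.mpf(3)),
            residuals=(0.5, 0.5),
        )
        with pytest.raises(NoSolutionError) as exc:
            filter_solutions([sol], additive2, dist025)
        assert exc.value.reasons


class TestFindMax:
    def test_worked_example_table(self, additive2):
        t = find_max_prevalence(additive2, (0.25, 0.25), 0.2)
        assert tuple(round(float(p), 4) for p in t.penetrances) == WORKED_TABLE
        assert round(float(t.achieved_prevalence), 4) == WORKED_PREVALENCE
        assert float(t.achieved_heritability) == pytest.approx(0.2, abs=1e-12)

    def test_incompatible_model_rejected(self):
        with pytest.raises(ValidationError):
            find_max_prevalence(incompatible_model(), (0.25, 0.25), 0.2)

    def test_near_unit_prevalence_leaves_no_variance_headroom(self, additive2):
        t = find_max_heritability(additive2, (0.25, 0.25), 0.999)
        assert float(t.achieved_heritability) < 0.01

    def test_max_heritability_root_matches_bisection_oracle(self, additive2):
        """Independent float-only oracle: eliminate x by bisection on the
        max-penetrance equation, then bisect the prevalence constraint
        in y; the solver's root must agree to 6 significant digits."""
        probs = [float(p) for p in genotype_probabilities((0.25, 0.25)).probabilities]
        ks = [a + b for a, b in itertools.product(range(3), repeat=2)]

        def x_of_y(yv):
            lo, hi = 0.0, 1.0
            for _ in range(200):
                mid = (lo + hi) / 2
                if mid * (1 + yv) ** 4 > 1:
                    hi = mid
                else:
                    lo = mid
            return (lo + hi) / 2

        def g(yv):
            xv = x_of_y(yv)
            return sum(xv * (1 + yv) ** k * p for k, p in zip(ks, probs)) - 0.1

        lo, hi = 1e-6, 100.0
        assert g(lo) > 0 > g(hi)
        for _ in range(200):
            mid = (lo + hi) / 2
            if g(mid) > 0:
                lo = mid
            else:
                hi = mid
        oracle_y = (lo + hi) / 2

        t = find_max_heritability(additive2, (0.25, 0.25), 0.1)
        assert float(t.variable_values[1]) == pytest.approx(oracle_y, rel=1e-6)

    def test_max_prevalence_monotone_in_heritability_target(self, additive2):
        prevs = [
            float(find_max_prevalence(additive2, (0.25, 0.25), h).achieved_prevalence)
            for h in (0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(prevs, prevs[1:]))

    def test_doubling_precision_does_not_worsen_residual(self, additive2):
        res = {}
        for digits in (32, 64):
            t = find_max_prevalence(additive2, (0.25, 0.25), 0.2,
                                    SolverConfig(digits=digits))
            with mpmath.workdps(200):
                res[digits] = abs(table_heritability(t, dps=200) - mpmath.mpf(1) / 5)
        assert res[64] <= res[32]

    @pytest.mark.parametrize("maf,h2", [(0.25, 0.2), (0.4, 0.1), (0.1, 0.3)])
    def test_constraint_round_trip_and_boundary_attainment(self, additive2, maf, h2):
        cfg = SolverConfig()
        t = find_max_prevalence(additive2, (maf, maf), h2, cfg)
        with mpmath.workdps(80):
            h_back = table_heritability(t, dps=80)
            assert abs(h_back - mpmath.mpf(str(h2))) <= 10 * cfg.residual_tol
        assert abs(float(max(t.penetrances)) - 1) <= 10 * cfg.residual_tol
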