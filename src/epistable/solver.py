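"""Constrained maximization of prevalence or heritability.

Given a bivariate epistasis model f_i(x, y), per-locus minor allele
frequencies and one fixed population parameter, the method finds the
variable values that maximize the other parameter subject to every
penetrance lying in [0, 1].

Definitions used throughout (P(g_i) are the exact genotype
frequencies, f_i the penetrances):

* prevalence       P(D) = sum_i f_i P(g_i)
* heritability     h^2  = sum_i (f_i - P(D))^2 P(g_i) * (1 - P(D)) / P(D)

i.e. the genetic variance of the binary trait scaled by the odds of
being unaffected. See docs/methods.md for a discussion of this
normalization and its relation to the phenotypic-variance form
V_G / (P(1-P)); for rare phenotypes the two coincide to O(P).

For an admissible model (monotone non-decreasing, sortable expressions
on the positive quadrant) the maximized parameter attains its maximum
when the largest penetrance expression equals 1. The solver therefore
solves the two-equation system {constraint = target, max expression = 1}
by eliminating one variable through the max-penetrance equation,
clearing the remaining univariate equation to a polynomial numerator,
and taking its complete root set at arbitrary precision. Roots with
negative components, large residuals, or penetrances outside [0, 1]
are discarded; among the survivors the one maximizing the free
parameter is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Literal, Sequence

import mpmath
import sympy as sp

from .errors import (
    DomainError,
    NoSolutionError,
    UnderdeterminedSystemError,
    ValidationError,
)
from .genetics import GenotypeDistribution, genotype_probabilities
from .model_io import EpistasisModel, validate_monotone, validate_sortable
from .ptable import PenetranceTable

__all__ = [
    "SolverConfig",
    "SolverSolution",
    "prevalence_expression",
    "heritability_expression",
    "build_max_prevalence_system",
    "build_max_heritability_system",
    "solve_system",
    "filter_solutions",
    "find_max_prevalence",
    "find_max_heritability",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings for the constrained solve.

    Attributes
    ----------
    digits:
        Working precision in significant decimal digits (>= 16).
    residual_tol:
        Maximum acceptable residual of each solved equation at a root,
        relative to the constrained value.
    free_var_bracket:
        Search interval for the reduced univariate unknown; used both
        to window the polynomial root set and for the multistart
        fallback when the reduced equation is not polynomial.
    multistart:
        Number of log-spaced seeds for the non-polynomial fallback.
    require_validation:
        Whether model admissibility (monotone + sortable) must pass
        before solving.
    """

    digits: int = 32
    residual_tol: float = 1e-12
    free_var_bracket: tuple[float, float] = (1e-12, 1e6)
    multistart: int = 64
    require_validation: bool = True

    def __post_init__(self):
        if self.digits < 16:
            raise DomainError("working precision must be at least 16 digits")
        if self.residual_tol <= 0:
            raise DomainError("residual tolerance must be positive")
        lo, hi = self.free_var_bracket
        if not (0 < lo < hi):
            raise DomainError("bracket must satisfy 0 < lower < upper")


@dataclass
class SolverSolution:
    """A candidate root of the constrained system.

    ``residuals`` are relative: |constraint - target| / target and
    |max expression - 1|. ``valid`` is set by :func:`filter_solutions`.
    """

    variable_values: tuple[mpmath.mpf, mpmath.mpf]
    residuals: tuple[float, float]
    valid: bool = False
    rejection_reason: str | None = None
    objective: float | None = None


def _check_orders(model: EpistasisModel, dist: GenotypeDistribution) -> None:
    if model.order != dist.order:
        raise DomainError(
            f"model order {model.order} != distribution order {dist.order}"
        )


def _weights(model: EpistasisModel, dist: GenotypeDistribution) -> dict[sp.Expr, Fraction]:
    """Collapse duplicate penetrance expressions, summing their genotype
    frequencies. Keeps high-order models tractable: an order-n additive
    model has 3^n rows but only 2n+1 distinct expressions."""
    w: dict[sp.Expr, Fraction] = {}
    for expr, pr in zip(model.expressions, dist.probabilities):
        w[expr] = w.get(expr, Fraction(0)) + pr
    return w


def _rational(value) -> sp.Rational:
    if isinstance(value, (sp.Rational, sp.Integer)):
        return value
    if isinstance(value, Fraction):
        return sp.Rational(value.numerator, value.denominator)
    if isinstance(value, float):
        return sp.Rational(str(value))
    return sp.Rational(value)


def prevalence_expression(model: EpistasisModel, dist: GenotypeDistribution) -> sp.Expr:
    """P(D) = sum_i f_i(x, y) P(g_i), with exact rational weights."""
    _check_orders(model, dist)
    w = _weights(model, dist)
    return sp.expand(sum(e * _rational(pr) for e, pr in w.items()))


def heritability_expression(model: EpistasisModel, dist: GenotypeDistribution) -> sp.Expr:
    """h^2 = sum_i (f_i - P(D))^2 P(g_i) * (1 - P(D)) / P(D)."""
    _check_orders(model, dist)
    w = _weights(model, dist)
    pd = prevalence_expression(model, dist)
    vg = sum((e - pd) ** 2 * _rational(pr) for e, pr in w.items())
    return vg * (1 - pd) / pd


def _max_expression(model: EpistasisModel, require_validation: bool, seed: int = 0) -> sp.Expr:
    report = validate_sortable(model, seed=seed)
    if report.passed:
        return report.max_expression(model)
    if require_validation:
        pairs = ", ".join(f"({a}, {b})" for a, b in report.conflicts)
        raise ValidationError(
            f"model {model.name!r} is not sortable on the positive quadrant; "
            f"conflicting expression pairs: {pairs}"
        )
    # override: choose the expression largest at a fixed interior point
    point = {v: sp.Rational(3, 2) for v in model.variables}
    return max(model.unique_expressions, key=lambda e: e.subs(point))


def _check_target(value, name: str) -> sp.Rational:
    t = _rational(value)
    if not (0 < t < 1):
        raise DomainError(f"{name} target must lie in (0, 1), got {value}")
    return t


def build_max_prevalence_system(
    model: EpistasisModel,
    dist: GenotypeDistribution,
    h2_target,
    *,
    require_validation: bool = True,
) -> tuple[sp.Eq, sp.Eq]:
    """System whose solution maximizes prevalence at fixed heritability:
    {heritability = h2_target, largest penetrance expression = 1}."""
    target = _check_target(h2_target, "heritability")
    _check_orders(model, dist)
    return (
        sp.Eq(heritability_expression(model, dist), target),
        sp.Eq(_max_expression(model, require_validation), 1),
    )


def build_max_heritability_system(
    model: EpistasisModel,
    dist: GenotypeDistribution,
    prev_target,
    *,
    require_validation: bool = True,
) -> tuple[sp.Eq, sp.Eq]:
    """System whose solution maximizes heritability at fixed prevalence:
    {prevalence = prev_target, largest penetrance expression = 1}."""
    target = _check_target(prev_target, "prevalence")
    _check_orders(model, dist)
    return (
        sp.Eq(prevalence_expression(model, dist), target),
        sp.Eq(_max_expression(model, require_validation), 1),
    )


# --------------------------------------------------------------------------
# Root finding
# --------------------------------------------------------------------------

def _mpf_from_rational(c, dps: int) -> mpmath.mpf:
    with mpmath.workdps(dps):
        if isinstance(c, sp.Rational):
            return mpmath.mpf(int(c.p)) / int(c.q)
        return mpmath.mpf(float(c))


def _poly_real_roots(coeffs, dps: int) -> list[mpmath.mpf]:
    """All real roots of a polynomial given leading-first coefficients."""
    with mpmath.workdps(dps + 10):
        cs = [_mpf_from_rational(c, dps + 10) for c in coeffs]
        while cs and cs[0] == 0:
            cs = cs[1:]
        if len(cs) <= 1:
            return []
        try:
            roots = mpmath.polyroots(cs[::-1], maxsteps=500, extraprec=4 * dps, asc=True)
        except TypeError:  # mpmath < 1.4 has no asc keyword
            roots = mpmath.polyroots(cs, maxsteps=500, extraprec=4 * dps)
        tol = mpmath.mpf(10) ** (-dps // 2)
        out = []
        for r in roots:
            if abs(mpmath.im(r)) <= tol * (1 + abs(mpmath.re(r))):
                out.append(mpmath.re(r))
        return out


def _refine(fn, r0, dps: int):
    with mpmath.workdps(dps):
        try:
            return mpmath.findroot(fn, r0)
        except (ValueError, ZeroDivisionError, OverflowError):
            return r0


def _dedupe(roots: list, rel: float = 1e-10) -> list:
    out: list = []
    for r in sorted(roots):
        if not out or abs(r - out[-1]) > rel * (1 + abs(r)):
            out.append(r)
    return out


def _univariate_roots(expr: sp.Expr, var: sp.Symbol, config: SolverConfig) -> list[mpmath.mpf]:
    """Real roots of a univariate expression.

    The expression is cleared to a rational function; if its numerator
    is polynomial the complete root set is computed with arbitrary-
    precision polynomial root finding, otherwise sign-change bracketing
    over a log-spaced multistart grid is used.
    """
    dps = config.digits
    together = sp.together(expr)
    num, den = sp.fraction(together)
    num = sp.expand(num)
    fn = sp.lambdify(var, together, "mpmath")
    den_fn = sp.lambdify(var, den, "mpmath")

    candidates: list[mpmath.mpf] = []
    poly = None
    if num.free_symbols <= {var} and num.is_polynomial(var):
        try:
            poly = sp.Poly(num, var)
        except sp.PolynomialError:
            poly = None
    if poly is not None and all(c.is_Rational or c.is_Float for c in poly.all_coeffs()):
        candidates = _poly_real_roots(poly.all_coeffs(), dps)
    else:
        lo, hi = config.free_var_bracket
        with mpmath.workdps(dps):
            import math

            seeds = [
                mpmath.mpf(10) ** (math.log10(lo) + i * (math.log10(hi) - math.log10(lo))
                                   / (config.multistart - 1))
                for i in range(config.multistart)
            ]
            vals = []
            for s in seeds:
                try:
                    vals.append(fn(s))
                except (ValueError, ZeroDivisionError, OverflowError):
                    vals.append(mpmath.nan)
            for (a, fa), (b, fb) in zip(zip(seeds, vals), zip(seeds[1:], vals[1:])):
                if mpmath.isnan(fa) or mpmath.isnan(fb):
                    continue
                if fa == 0:
                    candidates.append(a)
                elif fa * fb < 0:
                    try:
                        candidates.append(
                            mpmath.findroot(fn, (a, b), solver="anderson")
                        )
                    except (ValueError, ZeroDivisionError, OverflowError):
                        pass

    roots = []
    with mpmath.workdps(dps):
        for r in _dedupe(candidates):
            r = _refine(fn, r, dps)
            try:
                if abs(den_fn(r)) < mpmath.mpf(10) ** (-dps):
                    continue  # spurious root of the cleared numerator
                if abs(fn(r)) > mpmath.mpf("1e-6"):
                    continue  # refinement diverged
            except (ValueError, ZeroDivisionError, OverflowError):
                continue
            roots.append(r)
    return _dedupe(roots)


def solve_system(
    equations: tuple[sp.Eq, sp.Eq],
    config: SolverConfig | None = None,
) -> list[SolverSolution]:
    """Solve the two-equation constrained system.

    The max-penetrance equation is solved symbolically for one variable
    (for models of the common x*g(y) shape it is linear in x), the
    result is substituted into the constraint, and the complete real
    root set of the resulting univariate equation is computed at
    working precision. Roots are returned unfiltered (including
    negative ones) with their residuals.

    Raises
    ------
    UnderdeterminedSystemError
        If the system has fewer than two effective unknowns.
    NoSolutionError
        If no real root exists.
    """
    config = config or SolverConfig()
    constraint, max_eq = equations
    unknowns = sorted(
        (constraint.lhs - constraint.rhs).free_symbols
        | (max_eq.lhs - max_eq.rhs).free_symbols,
        key=lambda s: s.name,
    )
    if len(unknowns) != 2:
        raise UnderdeterminedSystemError(
            f"expected a system in exactly 2 unknowns, found {len(unknowns)}: "
            f"{', '.join(s.name for s in unknowns) or 'none'}"
        )
    xsym, ysym = unknowns

    # prefer eliminating the variable the max equation is linear in
    def _deg(e, v):
        try:
            return sp.degree(sp.expand(e), v)
        except sp.PolynomialError:
            return None

    elim, free = xsym, ysym
    max_res = max_eq.lhs - max_eq.rhs
    if _deg(max_res, xsym) != 1 and _deg(max_res, ysym) == 1:
        elim, free = ysym, xsym

    try:
        elim_solutions = sp.solve(max_eq, elim)
    except Exception:
        elim_solutions = []
    if not elim_solutions:
        other = ysym if elim is xsym else xsym
        try:
            elim_solutions = sp.solve(max_eq, other)
            elim, free = other, elim
        except Exception:
            elim_solutions = []
    if not elim_solutions:
        raise NoSolutionError(
            "could not isolate either variable in the max-penetrance equation"
        )

    target = constraint.rhs
    scale = abs(float(target)) or 1.0
    c_fn = sp.lambdify((xsym, ysym), constraint.lhs - constraint.rhs, "mpmath")
    m_fn = sp.lambdify((xsym, ysym), max_eq.lhs - max_eq.rhs, "mpmath")

    solutions: list[SolverSolution] = []
    for elim_expr in elim_solutions:
        uni = (constraint.lhs - constraint.rhs).subs(elim, elim_expr)
        if free not in uni.free_symbols:
            raise UnderdeterminedSystemError(
                "substituting the max-penetrance equation leaves no free unknown"
            )
        elim_fn = sp.lambdify(free, elim_expr, "mpmath")
        for r in _univariate_roots(uni, free, config):
            with mpmath.workdps(config.digits):
                try:
                    other_val = elim_fn(r)
                except (ValueError, ZeroDivisionError, OverflowError):
                    continue
                if mpmath.im(other_val) != 0 or mpmath.im(r) != 0:
                    continue
                pair = {elim: mpmath.re(other_val), free: mpmath.re(r)}
                xv, yv = pair[xsym], pair[ysym]
                try:
                    res_c = abs(c_fn(xv, yv)) / scale
                    res_m = abs(m_fn(xv, yv))
                except (ValueError, ZeroDivisionError, OverflowError):
                    continue
            solutions.append(
                SolverSolution(
                    variable_values=(xv, yv),
                    residuals=(float(res_c), float(res_m)),
                )
            )
    if not solutions:
        raise NoSolutionError(
            "no real root of the constrained system exists; the model cannot "
            "reach this target anywhere in the search region"
        )
    return solutions


def filter_solutions(
    solutions: list[SolverSolution],
    model: EpistasisModel,
    dist: GenotypeDistribution,
    config: SolverConfig | None = None,
    *,
    maximize: Literal["prevalence", "heritability"] = "prevalence",
) -> SolverSolution:
    """Discard inadmissible roots and return the maximizing survivor.

    A root is rejected if any variable is negative, any residual
    exceeds the tolerance, or any penetrance falls outside [0, 1]
    (boundary inclusive, within 10x tolerance). Among survivors the
    solution maximizing the free parameter wins; ties break toward the
    smaller second variable.
    """
    if not solutions:
        raise NoSolutionError("no candidate solutions to filter")
    config = config or SolverConfig()
    w = _weights(model, dist)
    exprs = list(w)
    fns = [sp.lambdify(model.variables, e, "mpmath") for e in exprs]
    tol = config.residual_tol
    bound_tol = 10 * tol

    survivors = []
    with mpmath.workdps(config.digits):
        weights_mp = [_mpf_from_rational(_rational(w[e]), config.digits) for e in exprs]
        for sol in solutions:
            xv, yv = sol.variable_values
            if xv < 0 or yv < 0:
                sol.rejection_reason = (
                    f"negative variable value (x={float(xv):.6g}, y={float(yv):.6g})"
                )
                continue
            if sol.residuals[0] > tol or sol.residuals[1] > tol:
                sol.rejection_reason = (
                    f"residuals {sol.residuals} above tolerance {tol:g}"
                )
                continue
            try:
                pens = [f(xv, yv) for f in fns]
            except (ValueError, ZeroDivisionError, OverflowError):
                sol.rejection_reason = "penetrance evaluation failed"
                continue
            if any(p < -bound_tol or p > 1 + bound_tol for p in pens):
                bad = [float(p) for p in pens if p < -bound_tol or p > 1 + bound_tol]
                sol.rejection_reason = f"penetrance outside [0, 1]: {bad}"
                continue
            pd = sum(p * wk for p, wk in zip(pens, weights_mp))
            if maximize == "prevalence":
                sol.objective = float(pd)
            else:
                if pd <= 0 or pd >= 1:
                    sol.rejection_reason = f"degenerate prevalence {float(pd):.6g}"
                    continue
                vg = sum((p - pd) ** 2 * wk for p, wk in zip(pens, weights_mp))
                sol.objective = float(vg * (1 - pd) / pd)
            sol.valid = True
            survivors.append(sol)

    if not survivors:
        reasons = [s.rejection_reason or "unknown" for s in solutions]
        raise NoSolutionError(
            "all candidate roots were rejected; the constraint is reachable "
            "only outside the admissible region",
            reasons=reasons,
        )
    return min(survivors, key=lambda s: (-s.objective, float(s.variable_values[1])))


# --------------------------------------------------------------------------
# High-level entry points
# --------------------------------------------------------------------------

def _finalize_table(
    model: EpistasisModel,
    dist: GenotypeDistribution,
    best: SolverSolution,
    config: SolverConfig,
) -> PenetranceTable:
    with mpmath.workdps(config.digits):
        xv, yv = best.variable_values
        fns = {
            e: sp.lambdify(model.variables, e, "mpmath")
            for e in model.unique_expressions
        }
        values = {e: fn(xv, yv) for e, fn in fns.items()}
        pens = []
        for e in model.expressions:
            v = values[e]
            v = mpmath.mpf(0) if v < 0 else (mpmath.mpf(1) if v > 1 else v)
            pens.append(v)
        weights = [
            _mpf_from_rational(_rational(pr), config.digits)
            for pr in dist.probabilities
        ]
        pd = sum(p * wk for p, wk in zip(pens, weights))
        vg = sum((p - pd) ** 2 * wk for p, wk in zip(pens, weights))
        h2 = vg * (1 - pd) / pd
        return PenetranceTable(
            order=model.order,
            mafs=dist.mafs,
            genotype_labels=model.genotype_labels,
            penetrances=tuple(pens),
            variable_names=tuple(v.name for v in model.variables),
            variable_values=(xv, yv),
            achieved_prevalence=pd,
            achieved_heritability=h2,
            source_model_name=model.name,
        )


def _validate_or_raise(model: EpistasisModel, config: SolverConfig) -> None:
    if not config.require_validation:
        return
    mono = validate_monotone(model)
    if not mono.passed:
        bad = ", ".join(str(e) for e in mono.failures)
        raise ValidationError(
            f"model {model.name!r} has non-monotone expressions on the "
            f"positive quadrant: {bad}"
        )
    # sortability is (re)checked inside _max_expression


def find_max_prevalence(
    model: EpistasisModel,
    mafs: Sequence,
    h2_target,
    config: SolverConfig | None = None,
) -> PenetranceTable:
    """Penetrance table with maximum prevalence at fixed heritability."""
    config = config or SolverConfig()
    _validate_or_raise(model, config)
    dist = genotype_probabilities(mafs)
    system = build_max_prevalence_system(
        model, dist, h2_target, require_validation=config.require_validation
    )
    solutions = solve_system(system, config)
    best = filter_solutions(solutions, model, dist, config, maximize="prevalence")
    log.info(
        "max-prevalence solution: %s=%.10g %s=%.10g prevalence=%.10g",
        model.variables[0], float(best.variable_values[0]),
        model.variables[1], float(best.variable_values[1]),
        best.objective,
    )
    return _finalize_table(model, dist, best, config)


def find_max_heritability(
    model: EpistasisModel,
    mafs: Sequence,
    prev_target,
    config: SolverConfig | None = None,
) -> PenetranceTable:
    """Penetrance table with maximum heritability at fixed prevalence."""
    config = config or SolverConfig()
    _validate_or_raise(model, config)
    dist = genotype_probabilities(mafs)
    system = build_max_heritability_system(
        model, dist, prev_target, require_validation=config.require_validation
    )
    solutions = solve_system(system, config)
    best = filter_solutions(solutions, model, dist, config, maximize="heritability")
    log.info(
        "max-heritability solution: %s=%.10g %s=%.10g heritability=%.10g",
        model.variables[0], float(best.variable_values[0]),
        model.variables[1], float(best.variable_values[1]),
        best.objective,
    )
    return _finalize_table(model, dist, best, config)
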