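"""Generators for the classic bivariate epistasis model families.

All families share two variables: a baseline effect ``x`` and a
genotypic effect ``y``. With g = (g_1 ... g_n) the per-locus minor
allele counts of a genotype:

* additive        f_g = x * (1 + y) ** (g_1 + ... + g_n)
* multiplicative  f_g = x * (1 + y) ** (g_1 * ... * g_n)
* threshold       f_g = x * (1 + y) if every g_k >= 1, else x

At order 2 the additive family reproduces the classic two-locus model
in which the odds increase multiplicatively with genotype both within
and between loci. The threshold family keeps every expression at first
degree in each variable; the multiplicative family's polynomial degree
grows with the product of the genotype codes.

``incompatible_model`` returns the canonical counter-example that
fails both admissibility checks: its expression x/y increases in y on
(0, 1) but decreases on (1, inf), so it is neither monotone nor
sortable on the positive quadrant.
"""

from __future__ import annotations

import math

import sympy as sp

from .errors import DomainError
from .genetics import genotype_labels, minor_allele_counts
from .model_io import EpistasisModel

__all__ = [
    "additive_model",
    "multiplicative_model",
    "threshold_model",
    "incompatible_model",
]

_x, _y = sp.symbols("x y")


def _build(name: str, order: int, exponent_of) -> EpistasisModel:
    if order < 1:
        raise DomainError(f"interaction order must be >= 1, got {order}")
    powers: dict[int, sp.Expr] = {}
    exprs = []
    for counts in minor_allele_counts(order):
        k = exponent_of(counts)
        if k not in powers:
            powers[k] = _x * (1 + _y) ** k
        exprs.append(powers[k])
    return EpistasisModel(
        name=name,
        order=order,
        variables=(_x, _y),
        genotype_labels=genotype_labels(order),
        expressions=tuple(exprs),
    )


def additive_model(order: int) -> EpistasisModel:
    """Additive family: exponent is the total minor-allele count."""
    return _build(f"additive_{order}", order, sum)


def multiplicative_model(order: int) -> EpistasisModel:
    """Multiplicative family: exponent is the product of the counts."""
    return _build(f"multiplicative_{order}", order, math.prod)


def threshold_model(order: int) -> EpistasisModel:
    """Threshold family: penetrance jumps once every locus carries at
    least one minor allele."""
    return _build(f"threshold_{order}", order, lambda c: 1 if min(c) >= 1 else 0)


def incompatible_model() -> EpistasisModel:
    """Order-2 model with expressions {x, x*y, x/y} that fails both the
    monotonicity and the sortability checks."""
    exprs = []
    for a, b in minor_allele_counts(2):
        if a == 0:
            exprs.append(_x)
        elif b == 0:
            exprs.append(_x * _y)
        else:
            exprs.append(_x / _y)
    return EpistasisModel(
        name="incompatible",
        order=2,
        variables=(_x, _y),
        genotype_labels=genotype_labels(2),
        expressions=tuple(exprs),
    )
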