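"""Parsing, validation and serialization of bivariate epistasis models.

A model file is plain CSV with no header: one row per multilocus
genotype, two columns — the genotype label and a penetrance expression
in exactly two shared variables, e.g.::

    AABB,x
    AABb,x*(1+y)
    AAbb,x*(1+y)^2
    ...

Any alphabetic identifier in the expression column is interpreted as a
variable name; a valid model uses exactly two distinct variables across
all its rows. Arithmetic supports ``+ - * /`` and both ``^`` and ``**``
for exponentiation; implicit multiplication (``x(1+y)``) is rejected as
ambiguous. Lines that are empty or start with ``#`` are skipped.

The admissibility checks required by the constrained-maximization
method live here as well:

* :func:`validate_monotone` — every expression must be monotonically
  non-decreasing in both variables on the open positive quadrant;
* :func:`validate_sortable` — the expressions must admit one total
  order valid for all non-negative variable values.

Both try a symbolic proof first (sign analysis of derivatives /
pairwise differences under positivity assumptions) and fall back to
evaluation on a deterministic grid, flagging the result as sampled.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import sympy as sp
from sympy.parsing.sympy_parser import (
    convert_xor,
    parse_expr,
    standard_transformations,
)

from .errors import ExpressionError, ModelDefinitionError, ModelFormatError

__all__ = [
    "EpistasisModel",
    "parse_model",
    "write_model",
    "validate_monotone",
    "validate_sortable",
    "MonotonicityReport",
    "SortabilityReport",
]

_IDENTIFIER = re.compile(r"[A-Za-z_][A-Za-z_0-9]*")
_TRANSFORMS = standard_transformations + (convert_xor,)

# Deterministic sampling fallback: a 20x20 log-spaced lattice over
# (1e-6, 1e3)^2 plus 100 seeded pseudo-random points in the same box.
_GRID_SIDE = 20
_GRID_LO, _GRID_HI = 1e-6, 1e3
_N_RANDOM = 100
_SAMPLE_TOL = 1e-9


@dataclass(frozen=True)
class EpistasisModel:
    """An ordered bivariate epistasis model.

    Attributes
    ----------
    name:
        Short identifier (defaults to the input file stem).
    order:
        Number of loci; the model has 3**order rows.
    variables:
        The two model variables (baseline and genotypic effect), as
        sympy symbols sorted lexicographically by name.
    genotype_labels:
        3**order unique genotype labels in row order.
    expressions:
        3**order sympy expressions over ``variables``, index-aligned
        with ``genotype_labels``.
    """

    name: str
    order: int
    variables: tuple[sp.Symbol, sp.Symbol]
    genotype_labels: tuple[str, ...]
    expressions: tuple[sp.Expr, ...]

    def __post_init__(self):
        n = 3 ** self.order
        if len(self.genotype_labels) != n or len(self.expressions) != n:
            raise ModelDefinitionError(
                f"model of order {self.order} needs {n} rows, got "
                f"{len(self.genotype_labels)} labels / {len(self.expressions)} expressions"
            )

    @property
    def unique_expressions(self) -> tuple[sp.Expr, ...]:
        """Distinct expressions in first-appearance order."""
        seen: dict[sp.Expr, None] = {}
        for e in self.expressions:
            seen.setdefault(e)
        return tuple(seen)


def _parse_expression(text: str, lineno: int) -> sp.Expr:
    names = set(_IDENTIFIER.findall(text))
    local = {n: sp.Symbol(n) for n in names}
    try:
        expr = parse_expr(text, local_dict=local, transformations=_TRANSFORMS)
    except Exception as exc:  # sympy raises a mixed bag of exception types
        raise ExpressionError(f"line {lineno}: cannot parse expression {text!r}: {exc}") from exc
    if expr.atoms(sp.Function):
        raise ExpressionError(
            f"line {lineno}: {text!r} looks like implicit multiplication or a "
            f"function call; write explicit products such as x*(1+y)"
        )
    if not expr.free_symbols and not expr.is_number:
        raise ExpressionError(f"line {lineno}: expression {text!r} is not numeric")
    return expr


def _is_power_of_three(n: int) -> bool:
    while n % 3 == 0 and n > 1:
        n //= 3
    return n == 1


_LABEL_CODE = re.compile(r"([A-Za-z])\1|([A-Za-z])([A-Za-z])")


def _check_label(label: str, order: int, lineno: int) -> None:
    if len(label) != 2 * order:
        raise ModelFormatError(
            f"line {lineno}: genotype label {label!r} should have {2 * order} "
            f"characters for an order-{order} model"
        )
    for k in range(order):
        code = label[2 * k: 2 * k + 2]
        a, b = code
        if a.upper() != b.upper():
            raise ModelFormatError(
                f"line {lineno}: locus code {code!r} in {label!r} mixes letters"
            )
        if not (a.isupper() and b.isupper() or a.isupper() and b.islower()
                or a.islower() and b.islower()):
            raise ModelFormatError(
                f"line {lineno}: locus code {code!r} in {label!r} is not one of "
                f"XX, Xx, xx"
            )


def parse_model(path) -> EpistasisModel:
    """Read a bivariate epistasis model from a CSV file.

    Raises
    ------
    ModelFormatError
        Malformed rows, bad labels, or a row count that is not a power
        of three.
    ExpressionError
        A penetrance expression that cannot be parsed.
    ModelDefinitionError
        The expressions do not use exactly two distinct variables.
    """
    path = Path(path)
    rows: list[tuple[str, sp.Expr]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2:
                raise ModelFormatError(
                    f"line {lineno}: expected 2 comma-separated fields, got {len(parts)}"
                )
            label, expr_text = parts
            rows.append((label, _parse_expression(expr_text, lineno), lineno))

    if not rows or not _is_power_of_three(len(rows)):
        raise ModelFormatError(
            f"model must have 3^order rows, got {len(rows)}"
        )
    order = round(np.log(len(rows)) / np.log(3))

    labels = []
    for label, _, lineno in rows:
        _check_label(label, order, lineno)
        labels.append(label)
    if len(set(labels)) != len(labels):
        raise ModelFormatError("duplicate genotype labels in model file")

    symbols = sorted(
        set().union(*(e.free_symbols for _, e, _ in rows)), key=lambda s: s.name
    )
    if len(symbols) != 2:
        raise ModelDefinitionError(
            f"a bivariate model must use exactly 2 variables, found "
            f"{len(symbols)}: {', '.join(s.name for s in symbols) or 'none'}"
        )

    return EpistasisModel(
        name=path.stem,
        order=order,
        variables=(symbols[0], symbols[1]),
        genotype_labels=tuple(labels),
        expressions=tuple(e for _, e, _ in rows),
    )


def write_model(model: EpistasisModel, path) -> None:
    """Write a model back to CSV, parseable by :func:`parse_model`."""
    lines = [
        f"{label},{sp.sstr(expr)}"
        for label, expr in zip(model.genotype_labels, model.expressions)
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Admissibility validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MonotonicityReport:
    """Per-expression monotonicity results.

    ``entries`` holds (expression, passed, method) triples where method
    is ``"symbolic"`` for a proved result and ``"sampled"`` when the
    grid fallback decided.
    """

    passed: bool
    entries: tuple[tuple[sp.Expr, bool, str], ...]

    @property
    def sampled_only(self) -> bool:
        return any(m == "sampled" for _, _, m in self.entries)

    @property
    def failures(self) -> tuple[sp.Expr, ...]:
        return tuple(e for e, ok, _ in self.entries if not ok)


@dataclass(frozen=True)
class SortabilityReport:
    """Result of the total-order check.

    ``order`` is the index permutation sorting the model's expressions
    ascending (valid on the whole non-negative quadrant) when the check
    passes, else None. ``conflicts`` lists expression pairs whose
    difference changes sign on the positive quadrant.
    """

    passed: bool
    order: tuple[int, ...] | None
    method: str
    conflicts: tuple[tuple[sp.Expr, sp.Expr], ...] = field(default_factory=tuple)

    def max_expression(self, model: EpistasisModel) -> sp.Expr:
        if not self.passed or self.order is None:
            raise ValueError("model is not sortable; no maximum expression")
        return model.expressions[self.order[-1]]


def _positive_clone(expr: sp.Expr, variables) -> sp.Expr:
    sub = {v: sp.Symbol(v.name, positive=True) for v in variables}
    return expr.xreplace(sub)


@functools.lru_cache(maxsize=8)
def _sample_points(seed: int) -> tuple[np.ndarray, np.ndarray]:
    side = np.logspace(np.log10(_GRID_LO), np.log10(_GRID_HI), _GRID_SIDE)
    gx, gy = np.meshgrid(side, side)
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(_GRID_LO), np.log10(_GRID_HI)
    rx = 10 ** rng.uniform(lo, hi, _N_RANDOM)
    ry = 10 ** rng.uniform(lo, hi, _N_RANDOM)
    return (
        np.concatenate([gx.ravel(), rx]),
        np.concatenate([gy.ravel(), ry]),
    )


def _sample(expr: sp.Expr, variables, seed: int) -> np.ndarray:
    xs, ys = _sample_points(seed)
    fn = sp.lambdify(list(variables), expr, "numpy")
    with np.errstate(all="ignore"):
        vals = fn(xs, ys)
    return np.broadcast_to(np.asarray(vals, dtype=float), xs.shape)


def _sign_on_quadrant(expr: sp.Expr, variables, seed: int) -> tuple[str, str]:
    """Classify the sign of ``expr`` for all positive variable values.

    Returns (sign, method) with sign one of ``"zero"``, ``"nonneg"``,
    ``"nonpos"``, ``"mixed"`` and method ``"symbolic"`` or ``"sampled"``.
    """
    e = sp.factor(sp.cancel(_positive_clone(sp.expand(expr), variables)))
    if e == 0:
        return "zero", "symbolic"
    if e.is_nonnegative:
        return "nonneg", "symbolic"
    if e.is_nonpositive:
        return "nonpos", "symbolic"
    vals = _sample(expr, variables, seed)
    vals = vals[np.isfinite(vals)]
    has_pos = bool((vals > _SAMPLE_TOL).any())
    has_neg = bool((vals < -_SAMPLE_TOL).any())
    if has_pos and has_neg:
        return "mixed", "sampled"
    if has_neg:
        return "nonpos", "sampled"
    if has_pos:
        return "nonneg", "sampled"
    return "zero", "sampled"


def validate_monotone(model: EpistasisModel, *, seed: int = 0) -> MonotonicityReport:
    """Check that every expression is non-decreasing in both variables
    on the open positive quadrant.

    Failures are reported, not raised; the solver decides what to do
    with a failing report.
    """
    entries = []
    for expr in model.unique_expressions:
        ok = True
        method = "symbolic"
        for v in model.variables:
            sign, how = _sign_on_quadrant(sp.diff(expr, v), model.variables, seed)
            if how == "sampled":
                method = "sampled"
            if sign not in ("zero", "nonneg"):
                ok = False
        entries.append((expr, ok, method))
    passed = all(ok for _, ok, _ in entries)
    return MonotonicityReport(passed=passed, entries=tuple(entries))


def validate_sortable(model: EpistasisModel, *, seed: int = 0) -> SortabilityReport:
    """Check that the expressions admit a total order on the
    non-negative quadrant and return the sorting permutation.

    Identical expressions tie; two distinct expressions whose
    difference changes sign make the model unsortable.
    """
    unique = list(model.unique_expressions)
    method = "symbolic"
    conflicts = []
    # rank[i] counts how many unique expressions are <= expression i
    greater: dict[int, set[int]] = {i: set() for i in range(len(unique))}
    for i in range(len(unique)):
        for j in range(i + 1, len(unique)):
            sign, how = _sign_on_quadrant(unique[j] - unique[i], model.variables, seed)
            if how == "sampled":
                method = "sampled"
            if sign == "mixed":
                conflicts.append((unique[i], unique[j]))
            elif sign in ("nonneg", "zero"):
                greater[j].add(i)
            else:  # nonpos
                greater[i].add(j)
    if conflicts:
        return SortabilityReport(
            passed=False, order=None, method=method, conflicts=tuple(conflicts)
        )
    rank = {id(e): len(greater[i]) for i, e in enumerate(unique)}
    unique_rank = {e: rank[id(e)] for e in unique}
    order = tuple(
        sorted(range(len(model.expressions)),
               key=lambda idx: (unique_rank[model.expressions[idx]], idx))
    )
    return SortabilityReport(passed=True, order=order, method=method)
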