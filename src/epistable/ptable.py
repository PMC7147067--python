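"""Penetrance tables: parameter recomputation and serialization.

A :class:`PenetranceTable` holds the numeric penetrance of every
multilocus genotype together with the solved model-variable values and
the achieved prevalence/heritability. Two text formats are supported:

* the GAMETES 2.x attribute-model layout (``write_gametes`` /
  ``read_gametes``): attribute names and per-attribute minor allele
  frequencies, ``#``-prefixed metadata lines (skipped by GAMETES-style
  parsers), then the penetrances as nested 3x3 blocks in canonical
  genotype order;
* a two-column CSV mirroring the model-input format (``write_csv`` /
  ``read_csv``), with the same metadata as ``#`` comments.

Numbers are rendered with round-half-even at a configurable number of
significant digits (default 10, lossless for double round-trips at
test tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import mpmath

from .errors import DomainError, ModelFormatError
from .genetics import genotype_labels, genotype_probabilities

__all__ = [
    "PenetranceTable",
    "table_prevalence",
    "table_heritability",
    "write_gametes",
    "read_gametes",
    "write_csv",
    "read_csv",
]

_DEFAULT_SIG = 10


@dataclass(frozen=True)
class PenetranceTable:
    """A numeric penetrance table plus its population parameters."""

    order: int
    mafs: tuple[Fraction, ...]
    genotype_labels: tuple[str, ...]
    penetrances: tuple
    variable_values: tuple
    achieved_prevalence: object
    achieved_heritability: object
    source_model_name: str = ""
    variable_names: tuple[str, str] = ("x", "y")

    def __post_init__(self):
        n = 3 ** self.order
        if len(self.penetrances) != n or len(self.genotype_labels) != n:
            raise DomainError(
                f"order-{self.order} table needs {n} rows, got "
                f"{len(self.penetrances)}"
            )


def table_prevalence(table: PenetranceTable, *, dps: int = 50):
    """Recompute P(D) = sum_i f_i P(g_i) from the stored penetrances
    and the exact genotype frequencies."""
    dist = genotype_probabilities(table.mafs)
    with mpmath.workdps(dps):
        return sum(
            mpmath.mpf(p) * mpmath.mpf(pr.numerator) / pr.denominator
            for p, pr in zip(table.penetrances, dist.probabilities)
        )


def table_heritability(table: PenetranceTable, *, dps: int = 50):
    """Recompute h^2 = V_G * (1 - P(D)) / P(D) from the stored
    penetrances (see the solver module for the normalization used).

    Raises
    ------
    DomainError
        If the prevalence is 0 or 1 (no phenotypic variation).
    """
    dist = genotype_probabilities(table.mafs)
    with mpmath.workdps(dps):
        weights = [
            mpmath.mpf(pr.numerator) / pr.denominator for pr in dist.probabilities
        ]
        pens = [mpmath.mpf(p) for p in table.penetrances]
        pd = sum(p * w for p, w in zip(pens, weights))
        if pd <= 0 or pd >= 1:
            raise DomainError(
                f"heritability undefined at prevalence {float(pd):.6g}"
            )
        vg = sum((p - pd) ** 2 * w for p, w in zip(pens, weights))
        return vg * (1 - pd) / pd


def _fmt(value, sig: int) -> str:
    return format(float(value), f".{sig}g")


def write_gametes(table: PenetranceTable, path, *, sig: int = _DEFAULT_SIG) -> None:
    """Write the table as a GAMETES 2.x attribute-model text file."""
    lines = []
    names = "\t".join(f"P{k}" for k in range(table.order))
    lines.append(f"Attribute names:\t{names}")
    mafs = "\t".join(_fmt(m, sig) for m in table.mafs)
    lines.append(f"Minor allele frequencies:\t{mafs}")
    xn, yn = table.variable_names
    lines.append(f"# Model: {table.source_model_name}")
    lines.append(f"# {xn}: {_fmt(table.variable_values[0], sig)}")
    lines.append(f"# {yn}: {_fmt(table.variable_values[1], sig)}")
    lines.append(f"# Prevalence: {_fmt(table.achieved_prevalence, sig)}")
    lines.append(f"# Heritability: {_fmt(table.achieved_heritability, sig)}")
    lines.append("")
    lines.append("Table:")
    lines.append("")
    n = 3 ** table.order
    for start in range(0, n, 3):
        if start > 0 and table.order >= 3 and start % 9 == 0:
            lines.append("")  # blank line between 3x3 blocks
        row = ", ".join(_fmt(v, sig) for v in table.penetrances[start:start + 3])
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gametes(path) -> PenetranceTable:
    """Read a table previously written by :func:`write_gametes`."""
    text = Path(path).read_text(encoding="utf-8")
    order = None
    mafs: list[Fraction] = []
    meta: dict[str, str] = {}
    cells: list[float] = []
    in_table = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("Attribute names:"):
            order = len(line.split("\t")[1:])
        elif line.startswith("Minor allele frequencies:"):
            mafs = [Fraction(tok) for tok in line.split("\t")[1:]]
        elif line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
        elif line.startswith("Table:"):
            in_table = True
        elif in_table:
            try:
                cells.extend(float(tok) for tok in line.split(","))
            except ValueError as exc:
                raise ModelFormatError(f"line {lineno}: bad table row {line!r}") from exc
        else:
            raise ModelFormatError(f"line {lineno}: unexpected content {line!r}")
    if order is None or not mafs or len(mafs) != order:
        raise ModelFormatError("missing or inconsistent header lines")
    if len(cells) != 3 ** order:
        raise ModelFormatError(
            f"expected {3 ** order} penetrance cells, found {len(cells)}"
        )
    var_names = [k for k in meta if k not in ("Model", "Prevalence", "Heritability")]
    if len(var_names) != 2:
        var_names = ["x", "y"]
        var_values = (float("nan"), float("nan"))
    else:
        var_values = (float(meta[var_names[0]]), float(meta[var_names[1]]))
    return PenetranceTable(
        order=order,
        mafs=tuple(mafs),
        genotype_labels=genotype_labels(order),
        penetrances=tuple(cells),
        variable_names=(var_names[0], var_names[1]),
        variable_values=var_values,
        achieved_prevalence=float(meta.get("Prevalence", "nan")),
        achieved_heritability=float(meta.get("Heritability", "nan")),
        source_model_name=meta.get("Model", ""),
    )


def write_csv(table: PenetranceTable, path, *, sig: int = _DEFAULT_SIG) -> None:
    """Write a two-column (genotype label, penetrance) CSV with the
    table metadata as ``#`` comments."""
    xn, yn = table.variable_names
    lines = [
        f"# Model: {table.source_model_name}",
        f"# MAFs: {' '.join(_fmt(m, sig) for m in table.mafs)}",
        f"# {xn}: {_fmt(table.variable_values[0], sig)}",
        f"# {yn}: {_fmt(table.variable_values[1], sig)}",
        f"# Prevalence: {_fmt(table.achieved_prevalence, sig)}",
        f"# Heritability: {_fmt(table.achieved_heritability, sig)}",
    ]
    for label, pen in zip(table.genotype_labels, table.penetrances):
        lines.append(f"{label},{_fmt(pen, sig)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_csv(path) -> PenetranceTable:
    """Read a table previously written by :func:`write_csv`."""
    meta: dict[str, str] = {}
    labels: list[str] = []
    cells: list[float] = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 2:
            raise ModelFormatError(f"line {lineno}: expected 2 fields, got {len(parts)}")
        labels.append(parts[0])
        try:
            cells.append(float(parts[1]))
        except ValueError as exc:
            raise ModelFormatError(f"line {lineno}: bad penetrance {parts[1]!r}") from exc
    n = len(cells)
    order = 0
    m = n
    while m > 1 and m % 3 == 0:
        m //= 3
        order += 1
    if m != 1 or order == 0:
        raise ModelFormatError(f"row count {n} is not a power of 3")
    mafs = tuple(Fraction(tok) for tok in meta.get("MAFs", "").split()) or tuple(
        Fraction(0, 1) for _ in range(order)
    )
    var_names = [k for k in meta if k not in ("Model", "MAFs", "Prevalence", "Heritability")]
    if len(var_names) != 2:
        var_names = ["x", "y"]
        var_values = (float("nan"), float("nan"))
    else:
        var_values = (float(meta[var_names[0]]), float(meta[var_names[1]]))
    return PenetranceTable(
        order=order,
        mafs=mafs,
        genotype_labels=tuple(labels),
        penetrances=tuple(cells),
        variable_names=(var_names[0], var_names[1]),
        variable_values=var_values,
        achieved_prevalence=float(meta.get("Prevalence", "nan")),
        achieved_heritability=float(meta.get("Heritability", "nan")),
        source_model_name=meta.get("Model", ""),
    )
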