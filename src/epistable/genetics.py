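"""Multilocus genotype enumeration and population frequencies.

Genotypes are enumerated in a canonical mixed-radix base-3 order: index
digit ``k`` (most significant digit = locus 0) is the number of minor
alleles at locus ``k`` — 0 for the homozygous major genotype (``AA``),
1 for the heterozygote (``Aa``) and 2 for the homozygous minor (``aa``).
Under Hardy-Weinberg equilibrium at each locus and linkage equilibrium
among loci, the population frequency of a multilocus genotype is the
product over loci of {q^2, 2pq, p^2}, with p the minor allele frequency
(MAF) and q = 1 - p.

Frequencies are computed with exact rational arithmetic so that the
distribution sums to one exactly and no rounding enters downstream
calculations before the numeric solve.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .errors import DomainError

__all__ = [
    "GenotypeDistribution",
    "genotype_probabilities",
    "genotype_labels",
    "minor_allele_counts",
]

_MAX_ORDER = len(string.ascii_uppercase)


def _as_fraction(value) -> Fraction:
    """Convert a user-supplied MAF to an exact Fraction.

    Floats go through their shortest decimal repr, so 0.1 becomes 1/10
    rather than the nearest binary double.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(str(value))
    return Fraction(value)


def minor_allele_counts(order: int) -> Iterable[tuple[int, ...]]:
    """Yield minor-allele-count vectors in canonical (base-3) order."""
    if order < 1:
        raise DomainError(f"interaction order must be >= 1, got {order}")
    return itertools.product(range(3), repeat=order)


def genotype_labels(order: int) -> tuple[str, ...]:
    """Canonical genotype labels, e.g. ('AABB', 'AABb', ..., 'aabb') for order 2."""
    if order < 1:
        raise DomainError(f"interaction order must be >= 1, got {order}")
    if order > _MAX_ORDER:
        raise DomainError(f"interaction order {order} exceeds supported maximum {_MAX_ORDER}")
    codes = []
    for k in range(order):
        upper = string.ascii_uppercase[k]
        lower = upper.lower()
        codes.append((upper + upper, upper + lower, lower + lower))
    return tuple(
        "".join(codes[k][g] for k, g in enumerate(counts))
        for counts in minor_allele_counts(order)
    )


@dataclass(frozen=True)
class GenotypeDistribution:
    """Exact genotype frequencies for a MAF vector.

    Attributes
    ----------
    mafs:
        Per-locus minor allele frequencies as exact fractions.
    order:
        Number of loci.
    probabilities:
        3**order rational frequencies, index-aligned with the canonical
        genotype enumeration. They sum to one exactly.
    """

    mafs: tuple[Fraction, ...]
    order: int
    probabilities: tuple[Fraction, ...]

    def __post_init__(self):
        assert len(self.probabilities) == 3 ** self.order


def genotype_probabilities(mafs: Sequence) -> GenotypeDistribution:
    """Genotype frequencies under Hardy-Weinberg + linkage equilibrium.

    Parameters
    ----------
    mafs:
        One minor allele frequency per locus, each in (0, 0.5]. Values
        may be floats, strings, or Fractions; they are converted to
        exact rationals.

    Raises
    ------
    DomainError
        If the vector is empty or any frequency lies outside (0, 0.5].
    """
    fracs = tuple(_as_fraction(m) for m in mafs)
    if len(fracs) == 0:
        raise DomainError("at least one locus is required")
    for m in fracs:
        if not (0 < m <= Fraction(1, 2)):
            raise DomainError(
                f"minor allele frequency must lie in (0, 0.5], got {m}"
            )
    per_locus = [
        ((1 - p) ** 2, 2 * p * (1 - p), p ** 2)  # indexed by minor-allele count
        for p in fracs
    ]
    order = len(fracs)
    probs = []
    for counts in minor_allele_counts(order):
        pr = Fraction(1)
        for k, g in enumerate(counts):
            pr *= per_locus[k][g]
        probs.append(pr)
    return GenotypeDistribution(mafs=fracs, order=order, probabilities=tuple(probs))
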