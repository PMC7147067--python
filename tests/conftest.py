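import itertools
from fractions import Fraction

import pytest

from epistable import additive_model, genotype_probabilities

# Reference values for the classic second-order additive worked example
# (MAF 0.25 at both loci, heritability fixed at 0.2, prevalence maximized):
# the solved variable values to 4 decimals, the achieved prevalence, and
# the full penetrance table row-by-row in canonical genotype order.
WORKED_X = 0.0019
WORKED_Y = 3.7714
WORKED_PREVALENCE = 0.0275
WORKED_TABLE = (0.0019, 0.0092, 0.0439, 0.0092, 0.0439, 0.2096,
                0.0439, 0.2096, 1.0)


@pytest.fixture(scope="session")
def additive2():
    return additive_model(2)


@pytest.fixture(scope="session")
def dist025():
    return genotype_probabilities((0.25, 0.25))


def brute_force_probabilities(mafs):
    """Independent oracle: enumerate every ordered pair of gametes per
    locus and accumulate genotype frequencies from allele products."""
    per_locus = []
    for m in mafs:
        p = Fraction(str(m)) if not isinstance(m, Fraction) else m
        q = 1 - p
        counts = {}
        for a1, pr1 in ((0, q), (1, p)):
            for a2, pr2 in ((0, q), (1, p)):
                counts[a1 + a2] = counts.get(a1 + a2, Fraction(0)) + pr1 * pr2
        per_locus.append(counts)
    probs = []
    for combo in itertools.product(range(3), repeat=len(mafs)):
        pr = Fraction(1)
        for k, g in enumerate(combo):
            pr *= per_locus[k][g]
        probs.append(pr)
    return probs
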