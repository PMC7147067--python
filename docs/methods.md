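# Methods

## Model class and assumptions

A bivariate epistasis model assigns every multilocus genotype g_i a
penetrance expression f_i(x, y) in two shared variables: a baseline
effect x (the penetrance floor common to all genotypes) and a
genotypic effect y (the per-allele increase in risk). The package is
strictly bivariate: models with one variable, more than two variables,
or per-locus distinct effect variables are rejected at parse time.

Two admissibility conditions underpin the maximization argument:

1. **Monotonicity** — every f_i is non-decreasing in both variables on
   the open positive quadrant;
2. **Sortability** — the expressions admit a single total order valid
   for all x, y ≥ 0.

Under these conditions all penetrances grow together as the variables
grow, so the constrained objective is maximal exactly when the largest
expression attains the largest value a probability can take, 1. This
converts a constrained optimization into root finding for a square
system. Both conditions are checked before solving (a flag disables
the check for exploratory use). The checks attempt a symbolic proof —
sign analysis of each partial derivative, and of each pairwise
difference of expressions, under positivity assumptions after
factoring — and fall back to evaluation on a deterministic 20×20
log-spaced grid over (10⁻⁶, 10³)² plus 100 seeded pseudo-random points
when the symbolic route is inconclusive. Sampling-based verdicts are
flagged (`method="sampled"`) because a sign change can in principle
hide between samples; for polynomial families the symbolic route
decides.

## Genotype frequencies

With per-locus minor allele frequency p ∈ (0, 0.5] and q = 1 − p, the
single-locus genotype frequencies under Hardy–Weinberg equilibrium are
q², 2pq, p² (indexed by minor-allele count), and multilocus frequencies
are their products across loci (linkage equilibrium). Frequencies are
kept as exact rationals (`fractions.Fraction`; floats are converted
through their decimal repr, so 0.1 means 1/10) and only converted to
arbitrary-precision floats inside the numeric solve. MAF = 0.5 is
allowed (the minor/major boundary); MAF = 0 is rejected as a
monomorphic locus. Genotypes are enumerated in mixed-radix base-3
order, digit k = minor-allele count at locus k.

## Population parameters

* Prevalence: P(D) = Σ_i f_i P(g_i).
* Heritability: h² = V_G · (1 − P)/P, with V_G = Σ_i (f_i − P)² P(g_i)
  the genetic variance of the binary trait.

The heritability normalization deserves a note. The more common
textbook form for a binary trait divides V_G by the phenotypic variance
P(1 − P). This package instead scales V_G by (1 − P)/P — the odds of
being unaffected — which is the definition established reference
results for this method family were computed under, and is the
definition used consistently here in both the solver constraint and
the table-side recomputation. The two differ by a factor (1 − P)², so
for the rare phenotypes these tables target (P ≲ 0.05) they agree to
within ~10 %, and any table produced under one definition can be
re-scored under the other from the emitted penetrances. Callers who
need the phenotypic-variance convention can divide the reported h² by
(1 − P)².

## Solving the constrained system

The system is {constraint(x, y) = target, f_max(x, y) = 1} with the
target taken as an exact rational.

1. **Elimination.** f_max = 1 is solved symbolically for whichever
   variable it is linear in (x for every x·g(y)-shaped family); the
   general case falls back to sympy's solver on either variable.
2. **Univariate root set.** Substituting gives one equation in y. It
   is cleared to a rational function; when the numerator is a
   polynomial with rational coefficients (all built-in families and
   any polynomial/fraction model), its *complete* root set is computed
   with arbitrary-precision polynomial root finding
   (`mpmath.polyroots` with extended working precision), and each real
   root is polished by Newton iteration at the configured precision.
   Roots of the cleared numerator that annihilate the denominator are
   dropped. If the numerator is not polynomial, sign-change bracketing
   over 64 log-spaced seeds in the configurable bracket
   (default (10⁻¹², 10⁶)) is used instead; the wide upper end matters
   because admissible genotypic effects routinely exceed small-grid
   intuitions.
3. **Filtering.** Candidate roots are discarded if any variable is
   negative (the admissibility argument only holds on the positive
   quadrant), any relative residual exceeds the tolerance, or any
   substituted penetrance leaves [0, 1] (boundary inclusive within
   10× tolerance). Among survivors the root maximizing the free
   parameter is returned; exact ties break toward the smaller y for
   determinism.
4. **Diagnostics.** "No real root anywhere" and "roots exist but all
   violate the penetrance bounds" produce distinct messages, with
   per-candidate rejection reasons attached.

Defaults: 32 significant digits of working precision (configurable;
raising it is advisable for targets very close to 0 or 1), relative
residual tolerance 10⁻¹². Doubling the precision never increases the
constraint residual of the returned table.

**Duplicate-expression collapsing.** Before any symbolic work,
identical expressions are merged and their genotype frequencies
summed. An order-n additive model has 3ⁿ rows but only 2n+1 distinct
expressions, so the univariate polynomial stays at degree 6n and the
additive family solves through order 10 (degree-60 root isolation) in
well under a minute; the full 3ⁿ-row table is reconstructed afterwards.

## Penetrance tables and formats

The returned table stores the numeric penetrances (clamped to [0, 1]
only against sub-tolerance numerical overshoot), the solved variable
values, and the achieved prevalence/heritability recomputed from the
penetrances and the exact genotype frequencies — so the reported
parameters are properties of the emitted table, not of the symbolic
solution.

Two writers are provided, both round-trippable by bundled readers:

* **GAMETES attribute-model text**: `Attribute names:` and
  `Minor allele frequencies:` header lines, `#`-prefixed metadata
  (solved variables, achieved parameters) that GAMETES-style parsers
  skip, then the penetrances as 3-per-line rows grouped into 3×3
  blocks in canonical genotype order. The exact header bytes expected
  by a given GAMETES release cannot be pinned here; all formatting is
  isolated in one writer so a dialect adjustment is a one-function
  change.
* **Two-column CSV** mirroring the model-input format.

Numbers are rendered with round-half-even at 10 significant digits by
default — more than the 4 decimals of the classic published tables, so
write→read round-trips are lossless at test tolerance.

## Built-in model families

With g the per-locus minor-allele-count vector:

| family         | penetrance                         | character |
|----------------|------------------------------------|-----------|
| additive       | x(1+y)^(Σ g_k)                     | degree grows linearly with order |
| multiplicative | x(1+y)^(Π g_k)                     | highest degrees; hardest to solve |
| threshold      | x if any g_k = 0, else x(1+y)      | all expressions first-degree |

The additive family at order 2 is the classic two-locus model in which
odds increase multiplicatively within and between loci; the
multiplicative and threshold generalizations follow the standard
characterizations (degree growing with the product of genotype codes;
a single first-degree jump once every locus carries a minor allele).
These generalization conventions are documented here as conventions —
other definitions exist in the literature, and user-supplied CSV
models bypass them entirely. `incompatible_model()` provides the
canonical negative control {x, xy, x/y}, which fails both
admissibility checks because x/y rises then falls in y across y = 1.

## What the generated models do and do not exercise

The built-in families are the test suite's synthetic backbone: they
span first-degree through high-degree polynomial systems with known
qualitative behavior, and the frequencies they are paired with
(MAF 0.1–0.5, targets 0.05–0.8) cover the range used in simulation
practice. They do not exercise non-polynomial penetrance expressions
(the multistart fallback is covered separately), linkage
disequilibrium, genotyping error, or phenocopies — a passing suite
says nothing about those; table consumers model them downstream.

## Numerical choices and degenerate inputs

* Targets outside (0, 1) are domain errors; targets extremely close to
  the boundaries may need more digits (the default tolerance is
  relative to the target).
* A constant (variable-free) expression passes monotonicity trivially;
  a model whose expressions are all equal has no usable boundary
  equation and surfaces as a no-solution/underdetermined error.
* An all-tied maximum (several genotypes sharing the top expression)
  is unproblematic: the shared expression is pinned to 1.
* Root multiplicity: all real roots are collected before filtering;
  selection is by the maximization objective, never by solver order.
* The feasible range of the free parameter is (0, maximum]; requesting
  a fixed parameter outside the model's reachable set yields the
  distinct infeasibility diagnostics described above.

## Problem sizes used in the checks

The bundled verification runs solve the order-2 families (9 rows), the
additive family at orders 3–4 across the MAF × h² battery, and one
order-10 additive capability case (59 049 rows, 21 distinct
expressions); the maximality oracle evaluates 200×200 log-spaced grids
in float arithmetic. These sizes keep a full verification run in the
low minutes on a single core while covering every code path the larger
configurations use.
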