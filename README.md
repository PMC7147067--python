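# epistable

Penetrance tables for high-order epistasis models under prevalence and
heritability constraints.

## The problem

Benchmarking epistasis-detection methods requires simulated case–control
data in which the gene–gene interaction is known by construction. The
interaction is usually specified as a *penetrance table*: for every
multilocus genotype g, the probability P(D|g) of expressing the
phenotype. Classic bivariate epistasis models (additive, multiplicative,
threshold, ...) define each penetrance as an expression f_i(x, y) in a
baseline effect x and a genotypic effect y — but turning a model into a
concrete table that also exhibits a realistic population prevalence
P(D) and heritability h² is a constrained search, and prescribing both
parameters at once usually produces an incompatible system.

`epistable` takes the alternative route: fix **one** parameter and
**maximize** the other over the model's admissible region. For any
model whose expressions are monotone non-decreasing and sortable on the
positive quadrant, the maximized parameter attains its maximum exactly
when the largest penetrance expression reaches its upper bound of 1.
The search therefore reduces to the two-equation system

```
h²(x, y) = h²_target        (or  P(D)(x, y) = P_target)
max_i f_i(x, y) = 1
```

with

```
P(D)  = Σ_i f_i(x, y) · P(g_i)                       (prevalence)
h²    = Σ_i (f_i − P(D))² P(g_i) · (1 − P(D)) / P(D)  (heritability)
```

where P(g_i) are the exact genotype frequencies under Hardy–Weinberg
and linkage equilibrium. The solver eliminates x through the boundary
condition, clears the remaining univariate equation to a polynomial,
takes its complete real root set at arbitrary precision, discards roots
with negative variables or penetrances outside [0, 1], and returns the
table maximizing the free parameter. Because equal expressions are
collapsed before the symbolic work, interaction orders well beyond
anything enumerable by stochastic table search remain tractable (an
order-10 additive model has 59 049 genotypes but only 21 distinct
expressions).

The resulting tables are written in the GAMETES attribute-model text
format, so a downstream simulator can generate case–control samples
embedding the designed interaction.

## Worked example

The classic second-order additive model with MAF 0.25 at both loci,
heritability fixed at 0.2, prevalence maximized:

```
$ epistable zoo additive --order 2 --out model.csv
additive_2: 9 rows -> model.csv
$ epistable find max-prevalence --model model.csv --maf 0.25 --h2 0.2 \
      --out table.txt --format gametes
max-prevalence: x=0.00192942 y=3.77137 prevalence=0.0274902 heritability=0.2 -> table.txt
```

The solved variables round to x = 0.0019, y = 3.7714: the baseline
penetrance is ~0.002 and each minor allele multiplies the odds term by
(1+y) ≈ 4.77, so the double-homozygous-minor genotype reaches
penetrance 1 while the population prevalence tops out at 0.0275 — a
rare phenotype with a strong two-locus component. The table written to
`table.txt`:

```
Attribute names:	P0	P1
Minor allele frequencies:	0.25	0.25
# Model: model
# x: 0.001929418574
# y: 3.771373193
# Prevalence: 0.02749017785
# Heritability: 0.2

Table:

0.001929418574, 0.009205976063, 0.0439251474
0.009205976063, 0.0439251474, 0.2095832708
0.0439251474, 0.2095832708, 1
```

The same run through the Python API:

```python
from epistable import additive_model, find_max_prevalence

table = find_max_prevalence(additive_model(2), (0.25, 0.25), h2_target=0.2)
print([round(float(p), 4) for p in table.penetrances])
# [0.0019, 0.0092, 0.0439, 0.0092, 0.0439, 0.2096, 0.0439, 0.2096, 1.0]
```

`find_max_heritability` is the mirror image (prevalence fixed,
heritability maximized). Models can also be supplied as a two-column
CSV (`genotype_label,expression`) with any two variable names.

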