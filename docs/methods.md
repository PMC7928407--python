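# Methods

`dairyopt` simulates a small, closed dairy cattle breeding program in which
part of the milk-recording budget can be reallocated to genotyping, and
compares conventional progeny-test selection against genomic selection of
males under equal total resources. This note documents the model, its
assumptions, the defaults, and the numerical choices.

## Genome and genetic architecture

Founder haplotypes are drawn from a coalescent simulation (msprime) of a
cattle-like genome: by default 10 chromosomes of 10^8 bp, each carrying
1,000 causal and 2,000 marker loci placed uniformly at random (disjoint
sets), retained only at sites segregating among the founders. The
demography is two-epoch — recent effective population size 100 (cattle-like
post-domestication bottleneck), ancestral size 1,000 beyond 100 generations
— chosen to give realistic linkage disequilibrium that decays with physical
distance; neither the map length (default 1 Morgan/chromosome) nor the
demography is a quantity the study's conclusions depend on, only the class
of LD behaviour.

Causal effects are sampled once per replicate from a normal distribution
and rescaled so the variance of founder true breeding values (TBV) is
exactly 1; TBVs are centred at twice the founder allele frequency, so the
founder mean is ~0 and the additive genetic standard deviation is the unit
of all reported gains. Meiosis places Poisson(map length) crossovers
uniformly in bp with no interference and a random start haplotype.
Marker-only genotypes never enter TBV computation, and causal loci never
enter the marker panel used for genomic relationships.

## Phenotype model

Each active cow produces `n` test-day records per lactation:

    y_ijkl = a_i + p_i + h_j + hy_jk + htd_jkl + e_ijkl

with variances (in units of sigma2_a = 1): permanent environment 1, herd
1/3, herd-year 1/3, herd-test-day 1/3, residual 1. The implied heritability
is 0.25 and the repeatability — the correlation of two records sharing only
the animal-level effects a and p — is 0.50. Records of herd mates on the
same test day share the htd effect. Cows keep one herd for life (default
100 herds, scaled with the census); herd-year effects are redrawn each
year, herd-test-day effects each recording day. Cows calve once per year
and all records of a lactation fall in one herd-year.

`realized_ratios` estimates the two ratios from simulated data as moment
ratios var(a)/var(y) and var(a+p)/var(y), using the simulation's known
animal-level effects; the within-herd-year record correlation is higher
(2/3 at the defaults, because h and hy are also shared) and is deliberately
not what "repeatability" means here.

## Breeding program

The program mimics a population of ~22,500 animals with 10,852 active cows
in at most four parities. Per year, scaled to the census:

- 4,320 newborn females, of which 3,849 are kept as replacements (pedigree
  EBV truncation, ties by id); first calving at age 2; per-parity survival
  is solved once from the census target (cull lowest EBV).
- 139 bull dams from cows in parities 2–4; elite matings with the current
  proven sires produce 45 male calves.
- Conventional path: the top 8 elite calves by parent average enter progeny
  testing; test sires cover 20% of commercial matings at age 1; five years
  after birth the 4 best by EBV become proven sires (service life one
  year). Sire-of-cow generation interval emerges at ~5–6 years.
- Genomic path: a budgeted number of male calves is genotyped (all elite
  calves first, then the general calf pool by parent average); the 5
  highest genomic EBVs become proven sires immediately, collapsing the sire
  generation interval to ~1–2 years. Females are never genotyped for
  selection; a budgeted number of randomly chosen first-parity cows is
  genotyped to update the training population, and all selections use the
  single yearly evaluation.

Twenty years of conventional "historical" breeding (burn-in) precede the
scenario phase; within a replicate every scenario restarts from the
identical burn-in snapshot (paired design).

## Genetic evaluation

A repeatability animal model with the year mean as the only fixed effect
and additive-genetic, permanent-environment and herd-year random effects.
Herd and herd-test-day are not fitted — the data structure of a small
population does not support them — so their variances fold into herd-year
(2/3) and the residual (4/3) respectively; variance components are treated
as known, not re-estimated. Records of a cow within a herd-year are
collapsed to their cell mean with weight n, which is algebraically exact
for this model and shrinks the equations by an order of magnitude.

The additive structure is the sparse A-inverse (Meuwissen–Luo inbreeding,
Henderson's rules) on the pedigree of all active, phenotyped or genotyped
animals plus three ancestral generations. With genotyped animals the
single-step H-inverse adds (G^-1 − A22^-1) on the genotyped block, where G
is a VanRaden method-1 matrix from the 2,000-marker-per-chromosome panel,
centred at founder allele frequencies, rescaled to A22's mean diagonal and
off-diagonal, and blended 0.95 G + 0.05 A22 (common single-step software
defaults). A22 is extracted by Colleau's indirect pedigree-flow method
(one O(n) matvec per genotyped animal). The training population is capped
at 25,000 genotypes (a software-limit emulation); beyond the cap the
oldest-genotyped animals' genotypes are dropped first — phenotypes never
are.

Henderson's equations are solved by Jacobi-preconditioned conjugate
gradients to relative residual 1e-8 (max 10,000 iterations, failure
raises). Because the tuning of G adds a rank-one shift that can leave a
near-singular blended matrix marginally indefinite, the smallest diagonal
jitter (starting at 1e-8 of the mean diagonal) that restores a Cholesky
factorization is added; this perturbs relationships by well under any
quantity of interest.

## Resource allocation

The canonical price input is the cost of a full 11-record lactation,
P_total = EUR 19.55; the per-record price is derived for display (avoiding
the 1.78 x 11 = 19.58 rounding trap). A 6% multiplicative quantity discount
applies per additional record: c(n) = (P_total/11) * 0.94^(n-11). The
per-lactation saving from recording n < 11 is rounded to cents *before*
multiplying by the cow count — the only order that reproduces the published
worked example (EUR 0.64/lactation, EUR 6,945/year, 710 genotypes/year at
$P:$G = 2:1). Genotype price is P_total scaled by the $P:$G ratio
(2:1 → half, 1:2 → double).

The yearly genotype count is floor(savings / $G), split 7:1
females:males with the female share rounded to the nearest 10 and capped at
the number of first-parity cows; funds stranded by the cap are saved, never
shifted to males. The published per-scenario table is internally
inconsistent with any single rounding rule at the percent level; this
pipeline reproduces the worked example exactly and the table's row sums to
within ~2% (one cell sits at 2.7%).

Training-population policies: *initial_TP* genotypes all active cows plus
the 80 most recent proven sires once, before the first genomic male
selection; *build_TP* spends the whole yearly budget on first-parity cows
until the training population holds 2,000 cows (so 355 cows/year reach it
in year 6), then switches to the standard split and genomic male selection.

## Outcome metrics

Genetic gain is the mean TBV by birth-year cohort, standardized to mean 0
and genetic SD 1 in the first scenario year. Accuracy is the Pearson
correlation of EBV and TBV within four groups: candidate males (the
genotyped calf crop; in the conventional program, the elite calves at
parent-average information), proven males, candidate females (newborn,
non-genotyped, non-phenotyped) and proven females (active cows).

The intensity of two-stage male selection integrates the standard bivariate
normal density over both truncation regions:

    i = (1/p2) ∫_{Tx}^{∞} ∫_{Ty}^{∞} f(x, y, ρ) · x dy dx

with x the parent average (stage 1, proportion p1 of newborn males), y the
genomic breeding value (stage 2, proportion p2), both cut-offs marginal
standard-normal quantiles, and ρ the ratio of parent-average to genomic
accuracy. The integrand uses x, the first-stage variable, as printed in the
source material for this design; because one may argue the second-stage
criterion y belongs in the integrand instead, `two_stage_intensity` exposes
a `stage_variable` switch rather than silently "correcting" it. Adaptive
quadrature runs over [T, 8] in each axis (tail error < 1e-10); ρ = 1 uses
the closed-form single-stage expression. A Monte-Carlo evaluator of the
same expectation serves as an independent oracle in the tests.

## Desk-scale study conditions

Full-size runs (20+20 years, 10,852 cows, 25,000-genotype cap, 10
replicates) are cluster-scale. The test suite and examples instead run the
complete program at scale 0.05: 543 active cows, 216 newborn per sex and
year, genotype cap 1,250, training threshold 100, 10 burn-in + 10 scenario
years, 10 replicates. Male-path quotas keep their structural values (8 test
bulls, 4/5 proven sires, ≥16 elite calves) because scaling them to ~1 sire
would replace selection with drift. Genotyping budgets are computed at full
scale from the cost model and then multiplied by the scale factor, so the
7:1 split survives scaling.

The desk-scale genome uses 2 chromosomes that keep the full-scale
per-chromosome architecture (1,000 causal and 2,000 marker loci, 10^8 bp,
1 Morgan). Scaling the chromosome count rather than the within-chromosome
structure is deliberate: genomic prediction accuracy is governed by
the ratio of training-population size to the number of effective genome
segments, and shrinking the population 20-fold while keeping a full-size
genome would push every scenario into the information-starved regime the
full-scale study does not occupy. Scaling the genome with the population
keeps the accuracy regime — and therefore the qualitative scenario ordering
(conventional < low-genotyping < high-genotyping, diminishing returns
beyond ~5 records) — comparable to the full-size program. Desk-scale runs
reproduce sign and ordering properties, not the full-scale magnitudes.

## What the generator does and does not emulate

Simulated data carry the variance structure, selection history, overlapping
generations and pedigree/genotype information flows of a real small dairy
program. They do not include lactation-curve shape or 305-day yield
prediction, non-additive gene action, genotype-by-environment interaction,
parentage errors, missing records, heterogeneous herd sizes, or genetic
correlations below 1 between parities — so passing tests demonstrate the
method's behaviour under the stated model, not performance on field data.
Accuracies are accordingly higher than field values.

## Known limitations

- Proven-male accuracy is computed over a handful of animals per year at
  desk scale and is reported as NaN when fewer than 3 are available or the
  group is degenerate.
- The published budget table can only be matched to ~2% (hand-rounding in
  the source); the worked example is matched exactly.
- The cost model is static: no genotyping-price decline, discounting or
  currency effects.
- Selection is single-trait and truncation-based; no inbreeding management
  or mate allocation beyond even sire use.
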