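# Methods

## Scope and model

`snpqg` analyses one biallelic locus at a time against continuous traits
in a single population. Each locus has a designated allele 1 — whichever
allele the locus metadata lists first — and every oriented quantity
(genotype class 11, the additive half-difference a, the allele effects
α₁/α₂, the substitution effect s(1→2)) is defined relative to that
allele. No automatic major/minor reordering is applied: published
component tables fix the orientation allele per locus, and silently
re-orienting would flip signs.

The phenotype model underlying both the simulator and the effect
decomposition is the standard single-locus genotypic-value model
(Falconer convention): genotypic values +a, d, −a for classes 11/12/22
about the homozygote midpoint, an optional fixed sex shift, and i.i.d.
Gaussian residuals. The decomposition estimates these quantities from
class means:

- a is estimated by (X̄₁₁ − X̄₂₂)/2 and D by X̄₁₂ − (X̄₁₁ + X̄₂₂)/2;
  both are invariant to adding a constant to the trait, and swapping
  allele labels flips the sign of a while leaving D unchanged.
- The "printed" additive contrast A = X̄₂₂ − X̄₁₁ is reported alongside
  the half-difference because published tables use the two conventions
  interchangeably (A = −2a exactly).
- Allele mean values m₁ = pX̄₁₁ + qX̄₁₂ and m₂ = pX̄₁₂ + qX̄₂₂ mix
  homozygote and heterozygote means with allele frequencies; the average
  effects αᵢ = mᵢ − X̄ depend on the choice of the population mean X̄.

X̄ defaults to the arithmetic mean over all phenotyped animals
(count-weighted); an HWE-weighted mean (p²X̄₁₁ + 2pqX̄₁₂ + q²X̄₂₂) is
available behind `xbar_mode="hwe"`. The two differ when observed class
counts deviate from Hardy–Weinberg proportions. The identity
s(1→2) = (α₂ − α₁)/2 = (m₂ − m₁)/2 holds under either choice and is
enforced to machine precision.

## Diversity statistics

Allele frequencies come from direct allele counting over called
genotypes. H_e is plain 2pq by default because that choice reconciles
with reference tables computed from exact count-based frequencies; Nei's
unbiased variant (2N/(2N−1))·2pq is reported alongside but never used for
comparisons. PIC uses the biallelic specialisation of Botstein's measure,
1 − (p² + q²) − 2p²q², bounded above by H_e with equality only at
fixation, and maximal at 0.375 for p = 0.5.

The HWE test is the Pearson χ² against expected counts (Np², 2Npq, Nq²)
on 1 df without continuity correction — the textbook large-sample test.
An exact test is deliberately out of scope; at the near-fixation loci
this cohort contains, expected homozygote-2 counts are ≪ 1 and the χ²
p-value is only indicative (the statistic itself is still exactly the
Pearson sum, verified against a brute-force O/E loop on every count
triple up to N = 30). Monomorphic loci are flagged not-testable rather
than given a number.

Report rendering rounds frequencies/H_o/H_e to 2 decimals and PIC to 3,
half-up, matching the precision of published marker tables; full
precision is kept internally and in the TSV outputs. Published tables of
this kind sometimes chain already-rounded frequencies into H_e/PIC; we
never do, so third-decimal discrepancies against such tables are expected
at near-fixation loci.

## Association testing

"LSMeans" are computed as plain class means: in a one-way layout they are
identical, and that reading reconciles the component-table identities. An
optional sex-adjusted mode fits y ~ genotype + sex by OLS and averages
fitted cell means over sex levels, for unbalanced cohorts where sex
confounds genotype. Pairwise comparisons use pooled-variance Student t
tests by default (consistent with the single homoscedastic ANOVA
framework); Welch is a flag. For a two-class locus the pooled t test and
the ANOVA coincide (F = t²), which the tests assert.

No multiple-testing correction is applied by default — the replicated
study design tests each locus × trait at face value — but
Benjamini–Hochberg adjustment across a scan is available
(`adjust="bh"`).

The compact letter display uses insert-and-absorb: start from one group
holding all classes, split any group containing both members of a
significant pair, drop absorbed subsets, and letter surviving groups by
their first class in the fixed class order (11, 12, 22). Ties are never
broken by comparing means. Two displays are produced per table: lowercase
at α = 0.05 and uppercase at α = 0.10, the dual-threshold convention of
the field's tables. Pairs untestable for size (a singleton class) count
as non-significant and are logged.

Eligibility: association requires at least `min_classes` (default 2)
genotype classes with n ≥ `min_class_n` (default 3); monomorphic loci are
always refused. These defaults admit a locus carried by six heterozygotes
while excluding one with only two, matching how such cohorts are
analysed in practice. Samples missing the genotype or the trait are
dropped per locus × trait (pairwise deletion) and counted in the run
manifest; the reference datasets this design mimics have no missing data,
so the policy is ours.

## Significance of A and D

Published component tables star A and D without naming a test. We use a
two-tailed permutation test: trait values are shuffled across animals
with class sizes fixed, the component is recomputed, and the tail
proportion is taken with add-one smoothing ((1 + hits)/(1 + n_perm)), so
p is never exactly zero and the estimator is valid for any n_perm. The
default is 10,000 shuffles from a seeded generator; tests verify
agreement with exhaustive enumeration of all orderings at n = 8 and
approximate uniformity of the null p-value distribution.

## Synthetic cohorts

The generator draws genotypes from class probabilities
(p² + Fpq, 2pq(1−F), q² + Fpq) — Hardy–Weinberg at F = 0, with the
inbreeding coefficient available to create heterozygote-deficient
cohorts. Traits follow the genotypic-value model above. All randomness
derives from a single seed through named substreams (sexes, one per
locus, one per trait model), so identical config + seed gives a
bit-identical cohort regardless of evaluation order.

The reference configuration encodes the study conditions: 72 animals,
male fraction 0.5, the six loci at allele-1 frequencies 0.96 (CTSB), 0.91
(CTSL), 1.00 (CTSS), 0.98 (CTSK), 0.27 (GHRH), 0.67 (LEPR), and one
trait model per informative locus × trait whose (μ, a, d) are backed out
of the published class means (μ the homozygote midpoint) and whose σ is
the class-averaged SD recovered as SEM·√n. The sex effect is 0 in the
reference models: the source design treated sex as a random factor but
reported no magnitude, and any invented shift would perturb the
noiseless class means the configuration is required to reproduce.

When several loci model the same trait name, the generator emits one
column per (locus, trait) pair, suffixed with the driving gene
(`imf_ghrh`, `imf_lepr`, …). A joint multi-locus trait would be more
realistic but makes the noiseless class means of any one locus depend on
the sampling of the others in a finite cohort; one driving locus per
column keeps the generator's class-mean contract exact, at the price of
not emulating cross-locus confounding. Other simplifications: no linkage
disequilibrium, no litter/pen random effects, Gaussian i.i.d. residuals.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to correlated loci, shared-environment
structure or non-Gaussian traits.

## Numerical and degenerate-input choices

- ANOVA with zero within-class variance: F = 0, p = 1 if all class means
  agree, otherwise p = 0; both flagged degenerate rather than producing
  NaN from a 0/0.
- Zero-variance pairwise t: p = 1 (equal means) or p = 0 (unequal).
- Singleton classes: SEM reported as 0 with a flag; their pairs are
  untestable.
- Effect decomposition refuses loci with fewer than three observed
  classes rather than extrapolating a missing homozygote mean.
- Frequencies must satisfy p + q = 1 within 1e−9 in the allele-effect
  equations.
- Half-up decimal rounding for printed cells (Python's bankers' rounding
  would disagree with published tables on exact .5 boundaries).

## Problem sizes used in the test suite

Statistical calibration tests run at sizes chosen to keep Monte-Carlo
error well inside their tolerance bands: type-I error of the ANOVA uses
2000 null replicates of the 72-animal design (tolerance 3 binomial SDs of
0.05); bias checks for a and d use 200 cohorts of n = 5000 (3 SEs);
brute-force oracle comparisons enumerate all genotype count triples to
N = 30 and all two-group {0,1,2}⁶ layouts; permutation p-values are
checked against exhaustive enumeration at n = 8 (8! orderings). The whole
suite runs in well under a minute.

## Known limitations

Strictly biallelic, single-population, no phasing, no imputation, no
variance-component estimation (V_A/V_D, heritability) — the analysis
stops at the component scale, as the study design it reimplements does.
The χ² HWE test is unreliable at near-fixation loci (use the flagged
expected counts to judge); the sex-adjusted mode cannot rescue a design
where sex and genotype are perfectly confounded.
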