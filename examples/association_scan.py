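"""Genotype-trait association on a simulated cohort.

Simulates the reference cohort, then tests the GHRH locus against its
intramuscular-fat column: one-way ANOVA across genotype classes, class
means +/- SEM and compact letter displays at P<0.05 (lowercase) and
P<0.1 (uppercase).
"""

from snpqg import associate_locus, reference_config, simulate_cohort

matrix, traits = simulate_cohort(reference_config(), seed=42)
result = associate_locus(matrix, traits, "GHRH", "imf_ghrh")

print(f"locus {result.locus_id} x trait {result.trait}")
for s in result.class_summaries:
    print(
        f"  {s.label}: n={s.n:2d}  mean={s.mean:.2f} +/- {s.sem:.2f}"
        f"   letters {result.letters_005[s.label]}/{result.letters_010[s.label]}"
    )
F = result.anova
print(f"  ANOVA: F={F.F:.2f} on df={F.df}, P={F.p:.4f}")
for (a, b), p in result.pairwise_p.items():
    print(f"  t-test {a} vs {b}: P={p:.4f}" if p is not None else f"  {a} vs {b}: untestable")
print()
print(
    "Classes sharing a lowercase letter do not differ at P<0.05.  The\n"
    "simulated additive+dominance signal (BB homozygotes ~0.67 g/100 g\n"
    "fatter than AA) is usually, but not always, detected at n=72 -- the\n"
    "same marginal power regime as the real cohort."
)
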