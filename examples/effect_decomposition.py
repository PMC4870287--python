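"""Additive/dominance decomposition from published genotype-class means.

Evaluates the component equations directly on the published class means
for the two informative loci, printing both additive conventions, the
dominance deviation, allele average effects and the substitution effect.
"""

from snpqg import additive_component, allele_effects, dominance_component, substitution_effect

CASES = [
    # locus, trait, (X11, X12, X22), allele-1 frequency, unit
    ("GHRH", "intramuscular fat", (1.23, 1.41, 1.90), 39 / 144, "g/100 g"),
    ("LEPR", "ash content", (1.12, 1.12, 0.99), 96 / 144, "g/100 g"),
]

for locus, trait, (x11, x12, x22), p, unit in CASES:
    q = 1 - p
    xbar = p * p * x11 + 2 * p * q * x12 + q * q * x22  # HWE-weighted mean
    m1, m2, a1, a2 = allele_effects(p, q, x11, x12, x22, xbar)
    print(f"{locus} x {trait} ({unit}):")
    print(f"  class means 11/12/22 = {x11} / {x12} / {x22}")
    print(f"  A (X22-X11)       = {additive_component(x11, x22, 'printed'):+.4f}")
    print(f"  a (half-diff)     = {additive_component(x11, x22, 'half_difference'):+.4f}")
    print(f"  D (dominance)     = {dominance_component(x11, x12, x22):+.4f}")
    print(f"  m1/m2             = {m1:.4f} / {m2:.4f}")
    print(f"  alpha1/alpha2     = {a1:+.4f} / {a2:+.4f}")
    print(f"  s(1->2)           = {substitution_effect(a1, a2):+.4f}")
    print()

print(
    "GHRH: the heterozygote sits 0.155 g/100 g below the homozygote\n"
    "midpoint (partial dominance of the lean A allele); each A->B allele\n"
    "substitution raises intramuscular fat.  LEPR: D=+0.065 with near-zero\n"
    "CC-CT contrast is complete dominance of the C allele for ash content."
)
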