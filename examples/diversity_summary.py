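"""Marker diversity report for the published six-locus pig cohort.

Rebuilds the 72-animal genotype table from the published genotype-class
counts and prints allele frequencies, observed/expected heterozygosity,
PIC and the Hardy-Weinberg chi-square per locus.
"""

import numpy as np

from snpqg import GenotypeMatrix, Locus, diversity_table
from snpqg.pipeline import render_diversity_table

LOCI_AND_COUNTS = [
    (Locus("CTSB", "CTSB", "g.72A>C", "A", "C"), (66, 6, 0)),
    (Locus("CTSL", "CTSL", "g.143C>T", "C", "T"), (59, 13, 0)),
    (Locus("CTSS", "CTSS", "g.171G>A", "G", "A"), (72, 0, 0)),
    (Locus("CTSK", "CTSK", "g.15G>A", "G", "A"), (70, 2, 0)),
    (Locus("GHRH", "GHRH", "AluI", "A", "B"), (5, 29, 38)),
    (Locus("LEPR", "LEPR", "c.1987C>T", "C", "T"), (32, 32, 8)),
]


def matrix_from_counts() -> GenotypeMatrix:
    codes = np.column_stack(
        [
            [0] * n11 + [1] * n12 + [2] * n22
            for _, (n11, n12, n22) in LOCI_AND_COUNTS
        ]
    ).astype(np.int8)
    return GenotypeMatrix(
        [f"pig{i + 1:02d}" for i in range(72)],
        [loc for loc, _ in LOCI_AND_COUNTS],
        codes,
    )


summaries = diversity_table(matrix_from_counts())
print(render_diversity_table(summaries))
print()
print(
    "Ho ~ He at every segregating locus (no heterozygote excess/deficit),\n"
    "so the markers sit near Hardy-Weinberg proportions.  GHRH and LEPR are\n"
    "the informative markers: PIC 0.317 and 0.346 against the biallelic\n"
    "ceiling of 0.375, while the cathepsin loci are nearly fixed."
)
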