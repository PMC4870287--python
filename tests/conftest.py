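import numpy as np
import pytest

from snpqg.cohort import GenotypeClassCounts, GenotypeMatrix, Locus

# Published genotype-class counts of the six-locus pig cohort (n=72).
STUDY_COUNTS = {
    "CTSB": GenotypeClassCounts(66, 6, 0),
    "CTSL": GenotypeClassCounts(59, 13, 0),
    "CTSS": GenotypeClassCounts(72, 0, 0),
    "CTSK": GenotypeClassCounts(70, 2, 0),
    "GHRH": GenotypeClassCounts(5, 29, 38),
    "LEPR": GenotypeClassCounts(32, 32, 8),
}

STUDY_LOCI = [
    Locus("CTSB", "CTSB", "g.72A>C", "A", "C"),
    Locus("CTSL", "CTSL", "g.143C>T", "C", "T"),
    Locus("CTSS", "CTSS", "g.171G>A", "G", "A"),
    Locus("CTSK", "CTSK", "g.15G>A", "G", "A"),
    Locus("GHRH", "GHRH", "AluI", "A", "B"),
    Locus("LEPR", "LEPR", "c.1987C>T", "C", "T"),
]


def matrix_from_counts(counts_by_locus, loci) -> GenotypeMatrix:
    """Deterministic cohort whose per-locus class counts match a count table."""
    n = next(iter(counts_by_locus.values())).n_total
    codes = np.zeros((n, len(loci)), dtype=np.int8)
    for j, loc in enumerate(loci):
        c = counts_by_locus[loc.locus_id]
        col = [0] * c.n11 + [1] * c.n12 + [2] * c.n22 + [-1] * c.n_missing
        codes[:, j] = col
    return GenotypeMatrix([f"pig{i + 1:02d}" for i in range(n)], list(loci), codes)


@pytest.fixture
def study_matrix() -> GenotypeMatrix:
    return matrix_from_counts(STUDY_COUNTS, STUDY_LOCI)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160413)
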