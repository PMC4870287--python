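"""Per-locus diversity and informativeness statistics.

Replicates the summary a population-genetics package (GenAlEx-style) would
produce for a biallelic marker panel: allele and genotype frequencies,
observed and expected heterozygosity, polymorphic information content and
a Hardy-Weinberg chi-square test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortError, GenotypeClassCounts, GenotypeMatrix, genotype_class_counts


def allele_frequencies(counts: GenotypeClassCounts) -> tuple[float, float]:
    """Allele-1 and allele-2 frequencies from genotype counts.

    p = (2*n11 + n12) / 2N by direct allele counting over called genotypes.
    """
    N = counts.n_called
    if N == 0:
        raise CohortError("no called genotypes")
    p = (2 * counts.n11 + counts.n12) / (2 * N)
    return p, 1.0 - p


def heterozygosities(counts: GenotypeClassCounts) -> tuple[float, float, float]:
    """(Ho, He, He_unbiased).

    Ho = n12/N; He = 2pq; the unbiased variant applies Nei's small-sample
    correction 2N/(2N-1) and is reported alongside, not used by default.
    """
    N = counts.n_called
    if N == 0:
        raise CohortError("no called genotypes")
    p, q = allele_frequencies(counts)
    ho = counts.n12 / N
    he = 2.0 * p * q
    he_unbiased = (2 * N / (2 * N - 1)) * he if N > 0 else 0.0
    return ho, he, he_unbiased


def pic(p: float) -> float:
    """Polymorphic information content of a biallelic marker.

    Botstein's PIC specialised to two alleles:
    PIC = 1 - (p^2 + q^2) - 2 p^2 q^2.  Maximum 0.375 at p = 0.5.
    """
    if not 0.0 <= p <= 1.0:
        raise CohortError(f"allele frequency out of [0,1]: {p}")
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def hwe_chisq(
    counts: GenotypeClassCounts,
) -> tuple[float, float, tuple[float, float, float]]:
    """Pearson chi-square test of Hardy-Weinberg proportions.

    Compares observed genotype counts with (N p^2, 2Npq, N q^2) on 1 df,
    without continuity correction.  Returns (chi2, p_value, expected).
    Monomorphic loci are not testable.
    """
    N = counts.n_called
    if N == 0:
        raise CohortError("no called genotypes")
    p, q = allele_frequencies(counts)
    if p == 0.0 or p == 1.0:
        raise CohortError("monomorphic locus: HWE not testable")
    expected = (N * p * p, N * 2 * p * q, N * q * q)
    observed = counts.as_tuple()
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p_value, expected


@dataclass(frozen=True)
class DiversitySummary:
    """One locus row of the diversity report (Table-2 analogue)."""

    locus_id: str
    counts: GenotypeClassCounts
    p: float
    q: float
    genotype_freqs: tuple[float, float, float]
    Ho: float
    He: float
    He_unbiased: float
    PIC: float
    hwe_chi2: float  # NaN when not testable
    hwe_p: float  # NaN when not testable
    monomorphic: bool


def summarise_locus(locus_id: str, counts: GenotypeClassCounts) -> DiversitySummary:
    N = counts.n_called
    p, q = allele_frequencies(counts)
    ho, he, he_u = heterozygosities(counts)
    monomorphic = p in (0.0, 1.0)
    if monomorphic:
        chi2 = pval = float("nan")
    else:
        chi2, pval, _ = hwe_chisq(counts)
    return DiversitySummary(
        locus_id=locus_id,
        counts=counts,
        p=p,
        q=q,
        genotype_freqs=(counts.n11 / N, counts.n12 / N, counts.n22 / N),
        Ho=ho,
        He=he,
        He_unbiased=he_u,
        PIC=pic(p),
        hwe_chi2=chi2,
        hwe_p=pval,
        monomorphic=monomorphic,
    )


def diversity_table(matrix: GenotypeMatrix) -> list[DiversitySummary]:
    """Diversity summary for every locus of a cohort, in input order."""
    return [
        summarise_locus(loc.locus_id, genotype_class_counts(matrix, loc.locus_id))
        for loc in matrix.loci
    ]


def diversity_frame(summaries: list[DiversitySummary]) -> pd.DataFrame:
    """Full-precision tabular form of the diversity report."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "locus_id": s.locus_id,
                "n11": s.counts.n11,
                "n12": s.counts.n12,
                "n22": s.counts.n22,
                "n_missing": s.counts.n_missing,
                "p": s.p,
                "q": s.q,
                "Ho": s.Ho,
                "He": s.He,
                "He_unbiased": s.He_unbiased,
                "PIC": s.PIC,
                "hwe_chi2": s.hwe_chi2,
                "hwe_p": s.hwe_p,
                "monomorphic": s.monomorphic,
            }
        )
    return pd.DataFrame(rows)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as report tables use."""
    if isinstance(x, float) and math.isnan(x):
        return x
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def printed_diversity(summary: DiversitySummary) -> dict[str, float]:
    """Report-precision cells: 2 dp frequencies/Ho/He, 3 dp PIC."""
    return {
        "p": round_half_up(summary.p, 2),
        "q": round_half_up(summary.q, 2),
        "Ho": round_half_up(summary.Ho, 2),
        "He": round_half_up(summary.He, 2),
        "PIC": round_half_up(summary.PIC, 3),
    }
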