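"""Additive/dominance decomposition and allele average effects.

Single-locus quantitative genetics on genotype-class means.  With class
means X11 (homozygous allele 1), X12 (heterozygous) and X22 (homozygous
allele 2):

* dominance deviation      D  = X12 - (X11 + X22) / 2
* additive contrast        A  = X22 - X11                  ("printed" form)
                           a  = (X11 - X22) / 2            (half-difference,
                                Falconer orientation: allele-1 homozygote
                                sits at +a from the midpoint)
* allele mean values       m1 = p*X11 + q*X12,  m2 = p*X12 + q*X22
* allele average effects   alpha_i = m_i - Xbar
* substitution effect      s(1->2) = (alpha2 - alpha1) / 2

Both additive conventions are first-class outputs because published
candidate-gene tables use them interchangeably.  Significance of A and D
is assessed by a seeded permutation test, since class-mean contrasts have
no exact finite-sample null without distributional assumptions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .cohort import CohortError, GenotypeClassCounts
from .association import AssociationResult


def dominance_component(X11: float, X12: float, X22: float) -> float:
    """Dominance deviation of the heterozygote from the homozygote midpoint."""
    for x in (X11, X12, X22):
        if x is None or not math.isfinite(x):
            raise CohortError("dominance component requires three genotype classes")
    return X12 - (X11 + X22) / 2.0


def additive_component(X11: float, X22: float, convention: str = "printed") -> float:
    """Additive contrast between homozygote means.

    ``printed``: X22 - X11.  ``half_difference``: (X11 - X22) / 2, the
    Falconer genotypic value of the allele-1 homozygote about the midpoint.
    """
    for x in (X11, X22):
        if x is None or not math.isfinite(x):
            raise CohortError("additive component requires both homozygote classes")
    if convention == "printed":
        return X22 - X11
    if convention == "half_difference":
        return (X11 - X22) / 2.0
    raise CohortError(f"unknown additive convention {convention!r}")


def allele_effects(
    p: float, q: float, X11: float, X12: float, X22: float, Xbar: float
) -> tuple[float, float, float, float]:
    """Allele mean values and average effects (m1, m2, alpha1, alpha2)."""
    if abs(p + q - 1.0) > 1e-9:
        raise CohortError(f"allele frequencies must sum to 1, got p+q={p + q}")
    m1 = p * X11 + q * X12
    m2 = p * X12 + q * X22
    return m1, m2, m1 - Xbar, m2 - Xbar


def substitution_effect(alpha1: float, alpha2: float) -> float:
    """Expected phenotypic change per 1 -> 2 allele substitution."""
    return (alpha2 - alpha1) / 2.0


@dataclass(frozen=True)
class EffectDecomposition:
    """Per locus x trait decomposition (association-table companion row)."""

    locus_id: str
    trait: str
    X11: float
    X12: float
    X22: float
    Xbar: float
    p: float
    q: float
    A_printed: float
    A_halfdiff: float
    D: float
    m1: float
    m2: float
    alpha1: float
    alpha2: float
    s12: float
    p_A: float | None = None  # permutation p-values, None when not computed
    p_D: float | None = None


def hwe_weighted_mean(p: float, X11: float, X12: float, X22: float) -> float:
    """Population mean under Hardy-Weinberg class weights p^2 : 2pq : q^2."""
    q = 1.0 - p
    return p * p * X11 + 2 * p * q * X12 + q * q * X22


def decompose_locus(
    association: AssociationResult,
    counts: GenotypeClassCounts,
    trait_values: np.ndarray,
    xbar_mode: str = "weighted",
    rng: np.random.Generator | None = None,
    n_perm: int = 0,
) -> EffectDecomposition:
    """Assemble the full decomposition from an association result.

    Requires all three genotype classes (two-class loci are refused, as a
    half-populated decomposition is meaningless).  ``trait_values`` must be
    ordered by genotype class (the 11 block, then 12, then 22), matching
    ``counts``.  ``xbar_mode='weighted'``
    takes Xbar as the arithmetic mean over all phenotyped animals;
    ``'hwe'`` weights class means by Hardy-Weinberg proportions instead.
    With ``n_perm`` > 0, permutation p-values for A and D are attached.
    """
    from .diversity import allele_frequencies

    if len(association.class_summaries) < 3:
        raise CohortError(
            f"locus {association.locus_id!r}: effect decomposition "
            "requires three genotype classes"
        )
    s11, s12_, s22 = association.class_summaries
    X11, X12, X22 = s11.mean, s12_.mean, s22.mean
    p, q = allele_frequencies(counts)
    values = np.asarray(trait_values, dtype=float)
    if xbar_mode == "weighted":
        xbar = float(np.mean(values))
    elif xbar_mode == "hwe":
        xbar = hwe_weighted_mean(p, X11, X12, X22)
    else:
        raise CohortError(f"unknown xbar mode {xbar_mode!r}")
    m1, m2, a1, a2 = allele_effects(p, q, X11, X12, X22, xbar)
    p_A = p_D = None
    if n_perm:
        if rng is None:
            raise CohortError("permutation significance needs a seeded generator")
        class_sizes = (s11.n, s12_.n, s22.n)
        p_A = effect_significance(values, class_sizes, "A", n_perm, rng)
        p_D = effect_significance(values, class_sizes, "D", n_perm, rng)
    return EffectDecomposition(
        locus_id=association.locus_id,
        trait=association.trait,
        X11=X11,
        X12=X12,
        X22=X22,
        Xbar=xbar,
        p=p,
        q=q,
        A_printed=additive_component(X11, X22, "printed"),
        A_halfdiff=additive_component(X11, X22, "half_difference"),
        D=dominance_component(X11, X12, X22),
        m1=m1,
        m2=m2,
        alpha1=a1,
        alpha2=a2,
        s12=substitution_effect(a1, a2),
        p_A=p_A,
        p_D=p_D,
    )


def _component_from_split(values: np.ndarray, sizes: tuple[int, int, int], component: str) -> float:
    n11, n12, _ = sizes
    X11 = values[:n11].mean()
    X12 = values[n11 : n11 + n12].mean()
    X22 = values[n11 + n12 :].mean()
    if component == "A":
        return additive_component(X11, X22, "half_difference")
    return dominance_component(X11, X12, X22)


def effect_significance(
    values: np.ndarray,
    class_sizes: tuple[int, int, int],
    component: str,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Two-tailed permutation p-value for the A or D component.

    Trait values are shuffled across animals while class sizes stay fixed;
    the tail proportion uses add-one smoothing so p is never exactly 0.
    """
    if component not in ("A", "D"):
        raise CohortError(f"unknown component {component!r}")
    if n_perm < 1000:
        raise CohortError("n_perm must be >= 1000")
    values = np.asarray(values, dtype=float)
    if sum(class_sizes) != values.size or min(class_sizes) < 1:
        raise CohortError("class sizes must be positive and sum to the number of values")
    if np.ptp(values) == 0.0:
        return 1.0
    observed = abs(_component_from_split(values, class_sizes, component))
    hits = 0
    work = values.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        if abs(_component_from_split(work, class_sizes, component)) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def exhaustive_effect_significance(
    values: np.ndarray, class_sizes: tuple[int, int, int], component: str
) -> float:
    """Exact permutation p-value by enumerating all orderings (tiny n only)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n > 9:
        raise CohortError("exhaustive enumeration limited to n <= 9")
    observed = abs(_component_from_split(values, class_sizes, component))
    hits = total = 0
    for perm in itertools.permutations(values):
        total += 1
        if abs(_component_from_split(np.array(perm), class_sizes, component)) >= observed - 1e-12:
            hits += 1
    return hits / total
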