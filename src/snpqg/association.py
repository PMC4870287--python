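"""Per-locus trait association.

One-way fixed-effects ANOVA across genotype classes, class summaries
(mean +/- SEM), pairwise two-tailed t tests and a dual-threshold compact
letter display (lowercase letters at the strict threshold, uppercase at
the suggestive one), mirroring how candidate-gene studies in livestock
report genotype-trait tables.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import (
    CohortError,
    GenotypeClassCounts,
    GenotypeMatrix,
    TraitTable,
    eligible_loci,
    genotype_class_counts,
)

logger = logging.getLogger(__name__)


class IneligibleLocusError(CohortError):
    """Association requested for a locus that fails the eligibility rule."""


@dataclass(frozen=True)
class ClassSummary:
    """Mean +/- SEM of one genotype class."""

    label: str
    n: int
    mean: float
    sem: float  # sample SD / sqrt(n); 0 with singleton flag when n == 1
    singleton: bool = False


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    degenerate: bool = False


@dataclass
class AssociationResult:
    locus_id: str
    trait: str
    class_summaries: list[ClassSummary]
    anova: AnovaResult
    pairwise_p: dict[tuple[str, str], float | None]
    letters_005: dict[str, str]
    letters_010: dict[str, str]
    n_dropped_missing: int = 0

    @property
    def p_anova(self) -> float:
        return self.anova.p


def class_summaries(groups: Mapping[str, np.ndarray]) -> list[ClassSummary]:
    """Mean and SEM (sample SD / sqrt(n)) per genotype class.

    An empty class is a hard error: eligibility filtering upstream should
    have removed it.  A singleton class gets SEM 0 with a flag.
    """
    out = []
    for label, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise CohortError(f"empty genotype class {label!r}")
        if v.size == 1:
            out.append(ClassSummary(label, 1, float(v[0]), 0.0, singleton=True))
        else:
            sem = float(np.std(v, ddof=1) / np.sqrt(v.size))
            out.append(ClassSummary(label, int(v.size), float(np.mean(v)), sem))
    return out


def one_way_anova(groups: Mapping[str, np.ndarray]) -> AnovaResult:
    """Fixed-effects one-way ANOVA: F = MS_between / MS_within.

    Degenerate layouts are resolved explicitly: zero within-class variance
    everywhere with equal means gives F = 0, p = 1; zero within-variance
    with unequal means gives p = 0 with a degeneracy flag.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    k = len(arrays)
    if k < 2:
        raise CohortError("one-way ANOVA needs at least two classes")
    n_total = sum(a.size for a in arrays)
    if n_total <= k:
        raise CohortError("one-way ANOVA needs total n > number of classes")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, (df_b, df_w), 1.0, degenerate=True)
        return AnovaResult(float("inf"), (df_b, df_w), 0.0, degenerate=True)
    F = (ss_between / df_b) / (ss_within / df_w)
    return AnovaResult(float(F), (df_b, df_w), float(stats.f.sf(F, df_b, df_w)))


def pairwise_tests(
    groups: Mapping[str, np.ndarray], variant: str = "pooled"
) -> dict[tuple[str, str], float | None]:
    """Two-tailed t test p-value for every unordered pair of classes.

    ``variant`` selects pooled-variance Student t (default) or Welch.
    A class with n < 2 makes its pairs untestable (None).  Zero pooled
    variance with a nonzero mean difference is reported as p = 0.
    """
    if variant not in ("pooled", "welch"):
        raise CohortError(f"unknown t-test variant {variant!r}")
    labels = list(groups)
    out: dict[tuple[str, str], float | None] = {}
    for a, b in itertools.combinations(labels, 2):
        va = np.asarray(groups[a], dtype=float)
        vb = np.asarray(groups[b], dtype=float)
        if va.size < 2 or vb.size < 2:
            out[(a, b)] = None
            continue
        if np.var(va, ddof=1) == 0.0 and np.var(vb, ddof=1) == 0.0:
            out[(a, b)] = 1.0 if va.mean() == vb.mean() else 0.0
            continue
        res = stats.ttest_ind(va, vb, equal_var=(variant == "pooled"))
        out[(a, b)] = float(res.pvalue)
    return out


def letter_groups(
    pairwise_p: Mapping[tuple[str, str], float | None],
    class_order: Sequence[str],
    alpha: float,
    uppercase: bool = False,
) -> dict[str, str]:
    """Compact letter display at one significance threshold.

    Classes sharing any letter are pairwise non-significant at ``alpha``.
    Insert-and-absorb construction: start from one all-class group, split
    on each significant pair (taken in fixed class order, never by
    comparing means), drop absorbed subsets, letter the surviving groups
    by their first class.  Untestable pairs count as non-significant and
    are logged.
    """
    if not 0.0 < alpha < 1.0:
        raise CohortError(f"alpha out of (0,1): {alpha}")
    order = {c: i for i, c in enumerate(class_order)}
    groups: list[set[str]] = [set(class_order)]
    for (a, b), p in sorted(pairwise_p.items(), key=lambda kv: (order[kv[0][0]], order[kv[0][1]])):
        if p is None:
            logger.info("pair (%s, %s) untestable, treated as non-significant", a, b)
            continue
        if p >= alpha:
            continue
        new_groups: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend((g - {a}, g - {b}))
            else:
                new_groups.append(g)
        # absorb: drop any group contained in another
        groups = [
            g
            for i, g in enumerate(new_groups)
            if not any(i != j and g < h for j, h in enumerate(new_groups))
        ]
        # dedupe while preserving order
        seen: list[set[str]] = []
        for g in groups:
            if g not in seen:
                seen.append(g)
        groups = seen
    groups.sort(key=lambda g: min(order[c] for c in g))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ" if uppercase else "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {c: [] for c in class_order}
    for letter, g in zip(alphabet, groups):
        for c in g:
            letters[c].append(letter)
    return {c: "".join(sorted(ls)) for c, ls in letters.items()}


def _grouped_values(
    matrix: GenotypeMatrix,
    traits: TraitTable,
    locus_id: str,
    trait: str,
) -> tuple[dict[str, np.ndarray], GenotypeClassCounts, int]:
    """Trait values grouped by genotype class, after pairwise deletion.

    Samples missing either the genotype call or the trait value are
    dropped for this locus x trait pair only.
    """
    locus = matrix.locus(locus_id)
    labels = locus.genotype_labels()
    codes = matrix.locus_codes(locus_id)
    trait_map = traits.data[trait]
    groups: dict[str, list[float]] = {lab: [] for lab in labels}
    n_dropped = 0
    for sid, code in zip(matrix.sample_ids, codes):
        y = trait_map.get(sid, np.nan)
        if code < 0 or not np.isfinite(y):
            n_dropped += 1
            continue
        groups[labels[code]].append(float(y))
    counts = GenotypeClassCounts(
        n11=len(groups[labels[0]]),
        n12=len(groups[labels[1]]),
        n22=len(groups[labels[2]]),
        n_missing=n_dropped,
    )
    present = {lab: np.array(v) for lab, v in groups.items() if v}
    return present, counts, n_dropped


def sex_adjusted_means(
    groups: Mapping[str, np.ndarray], sexes: Mapping[str, Sequence[str]]
) -> dict[str, float]:
    """Least-squares genotype means from an additive genotype + sex fit.

    Fits y ~ genotype + sex by OLS and averages the fitted cell means over
    the sex levels observed, giving sex-balanced class means.  With a
    balanced layout these coincide with raw class means.
    """
    labels = list(groups)
    sex_levels = sorted({s for seq in sexes.values() for s in seq})
    rows, y = [], []
    for g_idx, lab in enumerate(labels):
        for val, sex in zip(groups[lab], sexes[lab]):
            row = [0.0] * len(labels) + [0.0] * len(sex_levels)
            row[g_idx] = 1.0
            row[len(labels) + sex_levels.index(sex)] = 1.0
            rows.append(row)
            y.append(val)
    X = np.asarray(rows)
    beta, *_ = np.linalg.lstsq(X, np.asarray(y), rcond=None)
    sex_avg = beta[len(labels):].mean()
    return {lab: float(beta[i] + sex_avg) for i, lab in enumerate(labels)}


def associate_locus(
    matrix: GenotypeMatrix,
    traits: TraitTable,
    locus_id: str,
    trait: str,
    *,
    ttest: str = "pooled",
    alpha: float = 0.05,
    alpha2: float = 0.10,
    min_class_n: int = 3,
    min_classes: int = 2,
) -> AssociationResult:
    """Full association analysis of one locus x trait pair.

    Checks eligibility on the post-deletion counts, refuses ineligible
    loci with the machine-readable reason, then assembles class summaries,
    the ANOVA, pairwise t tests and both letter displays.
    """
    groups, counts, n_dropped = _grouped_values(matrix, traits, locus_id, trait)
    ok, decisions = eligible_loci(
        {locus_id: counts}, min_class_n=min_class_n, min_classes=min_classes
    )
    if locus_id not in ok:
        raise IneligibleLocusError(
            f"locus {locus_id!r} ineligible for {trait!r}: {decisions[0].reason}"
        )
    order = [lab for lab in matrix.locus(locus_id).genotype_labels() if lab in groups]
    groups = {lab: groups[lab] for lab in order}
    anova = one_way_anova(groups)
    pw = pairwise_tests(groups, variant=ttest)
    return AssociationResult(
        locus_id=locus_id,
        trait=trait,
        class_summaries=class_summaries(groups),
        anova=anova,
        pairwise_p=pw,
        letters_005=letter_groups(pw, order, alpha),
        letters_010=letter_groups(pw, order, alpha2, uppercase=True),
        n_dropped_missing=n_dropped,
    )


def associate_scan(
    matrix: GenotypeMatrix,
    traits: TraitTable,
    locus_ids: Sequence[str] | None = None,
    trait_names: Sequence[str] | None = None,
    adjust: str = "none",
    **options,
) -> tuple[list[AssociationResult], list[str]]:
    """Associate every eligible locus with every trait.

    Returns results plus a list of skip messages for refused pairs.
    ``adjust='bh'`` replaces ANOVA p-values by Benjamini-Hochberg adjusted
    values across the scan.
    """
    locus_ids = list(locus_ids or [l.locus_id for l in matrix.loci])
    trait_names = list(trait_names or traits.trait_names)
    results, skipped = [], []
    for locus_id in locus_ids:
        for trait in trait_names:
            try:
                results.append(associate_locus(matrix, traits, locus_id, trait, **options))
            except IneligibleLocusError as exc:
                skipped.append(str(exc))
    if adjust == "bh" and results:
        adj = stats.false_discovery_control([r.anova.p for r in results], method="bh")
        for r, p in zip(results, adj):
            r.anova = AnovaResult(r.anova.F, r.anova.df, float(p), r.anova.degenerate)
    elif adjust not in ("none", "bh"):
        raise CohortError(f"unknown adjustment {adjust!r}")
    return results, skipped
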