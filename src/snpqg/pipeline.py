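"""End-to-end pipeline: diversity -> association -> effect decomposition.

Runs the three analysis stages in study order on either real input files
or a simulated cohort, writes TSV reports plus a JSON run manifest, and
renders the publication-style text tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import AssociationResult, IneligibleLocusError, associate_scan
from .cohort import (
    CohortError,
    GenotypeMatrix,
    ScreeningReport,
    TraitTable,
    eligible_loci,
    genotype_class_counts,
    read_genotype_table,
    read_trait_table,
    screen_samples,
)
from .diversity import DiversitySummary, diversity_frame, diversity_table, round_half_up
from .effects import EffectDecomposition, decompose_locus
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; serialisable to/from JSON."""

    genotype_path: str | None = None
    loci_path: str | None = None
    trait_path: str | None = None
    simulation_path: str | None = None  # alternative to the three files above
    screening_locus: str | None = None
    screening_class: str | None = None
    min_class_n: int = 3
    min_classes: int = 2
    alpha: float = 0.05
    alpha2: float = 0.10
    ttest: str = "pooled"
    adjust: str = "none"
    xbar_mode: str = "weighted"
    n_perm: int = 10_000
    seed: int = 0
    out_dir: str = "snpqg_out"

    def __post_init__(self) -> None:
        for a in (self.alpha, self.alpha2):
            if not 0.0 < a < 1.0:
                raise CohortError(f"alpha out of (0,1): {a}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class ReportBundle:
    diversity: list[DiversitySummary]
    associations: list[AssociationResult]
    effects: list[EffectDecomposition]
    screening: ScreeningReport | None
    manifest: dict


def _load_cohort(config: PipelineConfig) -> tuple[GenotypeMatrix, TraitTable, str]:
    if config.simulation_path:
        sim = SimulationConfig.from_json(config.simulation_path)
        matrix, traits = simulate_cohort(sim, seed=config.seed)
        return matrix, traits, f"simulated from {config.simulation_path} (seed {config.seed})"
    for p in (config.genotype_path, config.loci_path, config.trait_path):
        if p is None:
            raise CohortError("config needs genotype/loci/trait paths or a simulation config")
        if not Path(p).exists():
            raise FileNotFoundError(p)
    matrix = read_genotype_table(config.genotype_path, config.loci_path)
    traits = read_trait_table(config.trait_path)
    return matrix, traits, f"files {config.genotype_path}, {config.trait_path}"


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run diversity, association and effect decomposition; write reports.

    Deterministic for a fixed seed: all permutation randomness derives from
    ``config.seed`` via named substreams.  Outputs ``diversity.tsv``,
    ``association.tsv``, ``effects.tsv`` and ``manifest.json`` in
    ``config.out_dir``.
    """
    matrix, traits, source = _load_cohort(config)
    manifest: dict = {
        "tool": "snpqg",
        "version": __version__,
        "seed": config.seed,
        "input": source,
        "n_samples": matrix.n_samples,
        "loci": [l.locus_id for l in matrix.loci],
        "exclusions": {"samples": [], "loci": []},
    }

    screening = None
    if config.screening_locus:
        screening = screen_samples(matrix, config.screening_locus, config.screening_class)
        manifest["screening"] = {
            "locus": config.screening_locus,
            "required_class": config.screening_class,
            "n_retained": len(screening.retained),
        }
        for sid in screening.excluded:
            manifest["exclusions"]["samples"].append(
                {"sample_id": sid, "reason": f"screening genotype != {config.screening_class}"}
            )
        for sid in screening.missing:
            manifest["exclusions"]["samples"].append(
                {"sample_id": sid, "reason": "screening genotype missing"}
            )
        matrix = matrix.subset_samples(screening.retained)

    summaries = diversity_table(matrix)

    counts_by_locus = {
        l.locus_id: genotype_class_counts(matrix, l.locus_id) for l in matrix.loci
    }
    eligible, decisions = eligible_loci(
        counts_by_locus, min_class_n=config.min_class_n, min_classes=config.min_classes
    )
    for d in decisions:
        if not d.eligible:
            manifest["exclusions"]["loci"].append(
                {"locus_id": d.locus_id, "reason": d.reason}
            )

    analysis_traits = [t for t in traits.trait_names]
    associations, skipped = associate_scan(
        matrix,
        traits,
        locus_ids=eligible,
        trait_names=analysis_traits,
        adjust=config.adjust,
        ttest=config.ttest,
        alpha=config.alpha,
        alpha2=config.alpha2,
        min_class_n=config.min_class_n,
        min_classes=config.min_classes,
    )
    manifest["association_skipped"] = skipped

    effects: list[EffectDecomposition] = []
    perm_root = np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    perm_streams = perm_root.spawn(len(associations))
    for assoc, stream in zip(associations, perm_streams):
        if len(assoc.class_summaries) < 3:
            manifest["association_skipped"].append(
                f"locus {assoc.locus_id!r} x {assoc.trait!r}: effect decomposition "
                "requires three genotype classes"
            )
            continue
        values, counts = _class_ordered_values(matrix, traits, assoc)
        effects.append(
            decompose_locus(
                assoc,
                counts,
                values,
                xbar_mode=config.xbar_mode,
                rng=np.random.default_rng(stream),
                n_perm=config.n_perm,
            )
        )

    bundle = ReportBundle(summaries, associations, effects, screening, manifest)
    _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _class_ordered_values(matrix, traits, assoc):
    from .association import _grouped_values

    groups, counts, _ = _grouped_values(matrix, traits, assoc.locus_id, assoc.trait)
    labels = matrix.locus(assoc.locus_id).genotype_labels()
    values = np.concatenate([groups[lab] for lab in labels if lab in groups])
    return values, counts


def _write_bundle(bundle: ReportBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    diversity_frame(bundle.diversity).to_csv(out_dir / "diversity.tsv", sep="\t", index=False)
    association_frame(bundle.associations).to_csv(
        out_dir / "association.tsv", sep="\t", index=False
    )
    effects_frame(bundle.effects).to_csv(out_dir / "effects.tsv", sep="\t", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2) + "\n")


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for s in r.class_summaries:
            rows.append(
                {
                    "locus_id": r.locus_id,
                    "trait": r.trait,
                    "class": s.label,
                    "n": s.n,
                    "mean": s.mean,
                    "sem": s.sem,
                    "letters_005": r.letters_005[s.label],
                    "letters_010": r.letters_010[s.label],
                    "F": r.anova.F,
                    "df_between": r.anova.df[0],
                    "df_within": r.anova.df[1],
                    "p_anova": r.anova.p,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id", "trait", "class", "n", "mean", "sem",
            "letters_005", "letters_010", "F", "df_between", "df_within", "p_anova",
        ],
    )


def effects_frame(effects: list[EffectDecomposition]) -> pd.DataFrame:
    rows = [
        {
            "locus_id": e.locus_id,
            "trait": e.trait,
            "X11": e.X11,
            "X12": e.X12,
            "X22": e.X22,
            "Xbar": e.Xbar,
            "p": e.p,
            "q": e.q,
            "A_printed": e.A_printed,
            "A_halfdiff": e.A_halfdiff,
            "D": e.D,
            "m1": e.m1,
            "m2": e.m2,
            "alpha1": e.alpha1,
            "alpha2": e.alpha2,
            "s12": e.s12,
            "p_A": e.p_A,
            "p_D": e.p_D,
        }
        for e in effects
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id", "trait", "X11", "X12", "X22", "Xbar", "p", "q",
            "A_printed", "A_halfdiff", "D", "m1", "m2", "alpha1", "alpha2",
            "s12", "p_A", "p_D",
        ],
    )


def render_diversity_table(summaries: list[DiversitySummary]) -> str:
    """Publication-style diversity grid (2 dp frequencies, 3 dp PIC)."""
    header = f"{'Locus':<8}{'N(11/12/22)':>14}{'p':>7}{'q':>7}{'Ho':>7}{'He':>7}{'PIC':>8}"
    lines = [header, "-" * len(header)]
    for s in summaries:
        c = s.counts
        lines.append(
            f"{s.locus_id:<8}{f'{c.n11}/{c.n12}/{c.n22}':>14}"
            f"{round_half_up(s.p, 2):>7.2f}{round_half_up(s.q, 2):>7.2f}"
            f"{round_half_up(s.Ho, 2):>7.2f}{round_half_up(s.He, 2):>7.2f}"
            f"{round_half_up(s.PIC, 3):>8.3f}"
        )
    return "\n".join(lines)


def render_association_table(results: list[AssociationResult]) -> str:
    """LSMean +/- SEM cells with lowercase (strict) and uppercase
    (suggestive) significance letters."""
    header = f"{'Locus':<8}{'Trait':<18}{'Class':<7}{'n':>4}{'Mean±SEM':>18}{'Letters':>10}{'P(ANOVA)':>10}"
    lines = [header, "-" * len(header)]
    for r in results:
        for s in r.class_summaries:
            letters = r.letters_005[s.label]
            upper = r.letters_010[s.label]
            mark = f"{letters},{upper}" if upper.lower() != letters else letters
            lines.append(
                f"{r.locus_id:<8}{r.trait:<18}{s.label:<7}{s.n:>4}"
                f"{f'{s.mean:.2f}±{s.sem:.2f}':>18}{mark:>10}{r.anova.p:>10.4f}"
            )
    return "\n".join(lines)


def render_effects_table(effects: list[EffectDecomposition]) -> str:
    """Additive/dominance component table with allele effects and the
    substitution effect, both additive conventions shown."""
    header = (
        f"{'Locus':<8}{'Trait':<14}{'A(22-11)':>10}{'a(half)':>10}{'D':>10}"
        f"{'α1':>10}{'α2':>10}{'s(1→2)':>10}{'p(A)':>8}{'p(D)':>8}"
    )
    lines = [header, "-" * len(header)]
    for e in effects:
        pa = f"{e.p_A:.4f}" if e.p_A is not None else "-"
        pd_ = f"{e.p_D:.4f}" if e.p_D is not None else "-"
        lines.append(
            f"{e.locus_id:<8}{e.trait:<14}{e.A_printed:>10.4f}{e.A_halfdiff:>10.4f}"
            f"{e.D:>10.4f}{e.alpha1:>10.4f}{e.alpha2:>10.4f}{e.s12:>10.4f}"
            f"{pa:>8}{pd_:>8}"
        )
    return "\n".join(lines)


def render_paper_tables(bundle: ReportBundle) -> str:
    """All three text tables in study order."""
    parts = [
        "Marker diversity", render_diversity_table(bundle.diversity), "",
        "Genotype-trait association", render_association_table(bundle.associations), "",
        "Effect decomposition", render_effects_table(bundle.effects),
    ]
    return "\n".join(parts)
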