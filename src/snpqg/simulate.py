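"""Synthetic genotype-phenotype cohorts.

Generates cohorts with the statistical structure single-locus association
analysis assumes: biallelic genotypes drawn from Hardy-Weinberg (optionally
inbred) class probabilities, and traits built as

    y = mu + g + sex_effect * 1[male] + N(0, sigma^2)

with the Falconer genotype coding g = +a (class 11), d (class 12), -a
(class 22) about the homozygote midpoint mu.  The bundled reference
configuration mimics a 72-animal pig cohort: six biallelic candidate loci
at the study's allele frequencies (two informative, three near-monomorphic,
one fixed) and trait models whose noiseless class means equal the
published genotype-class means for the two informative loci.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import CohortError, GenotypeMatrix, Locus, TraitTable

import pandas as pd


@dataclass(frozen=True)
class TraitModel:
    """Single-locus trait model on the trait's own unit scale.

    ``a`` is the additive effect (allele-1 homozygote minus midpoint), ``d``
    the dominance deviation of the heterozygote, ``sex_effect`` a fixed
    shift added to males, ``sigma`` the residual SD.
    """

    mu: float
    a: float
    d: float
    sex_effect: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise CohortError(f"sigma must be > 0, got {self.sigma}")

    def noiseless_class_means(self) -> tuple[float, float, float]:
        """Expected (X11, X12, X22) for a sex-balanced or sexless cohort."""
        return (self.mu + self.a, self.mu + self.d, self.mu - self.a)


@dataclass(frozen=True)
class SimulatedLocus:
    locus: Locus
    p: float  # allele-1 frequency
    F: float = 0.0  # inbreeding coefficient

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise CohortError(f"allele frequency out of [0,1]: {self.p}")
        if not 0.0 <= self.F <= 1.0:
            raise CohortError(f"inbreeding coefficient out of [0,1]: {self.F}")


@dataclass
class SimulationConfig:
    n_samples: int
    male_fraction: float
    loci: list[SimulatedLocus]
    trait_models: dict[tuple[str, str], TraitModel]  # (locus_id, trait) -> model
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise CohortError("n_samples must be positive")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise CohortError("male_fraction out of [0,1]")
        known = {sl.locus.locus_id for sl in self.loci}
        for locus_id, _ in self.trait_models:
            if locus_id not in known:
                raise CohortError(f"trait model references unknown locus {locus_id!r}")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_samples": self.n_samples,
            "male_fraction": self.male_fraction,
            "seed": self.seed,
            "loci": [
                {
                    "locus_id": sl.locus.locus_id,
                    "gene": sl.locus.gene,
                    "variant_label": sl.locus.variant_label,
                    "allele1": sl.locus.allele1,
                    "allele2": sl.locus.allele2,
                    "p": sl.p,
                    "F": sl.F,
                }
                for sl in self.loci
            ],
            "trait_models": [
                {"locus_id": k[0], "trait": k[1], **vars(m)}
                for k, m in self.trait_models.items()
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        doc = json.loads(Path(path).read_text())
        loci = [
            SimulatedLocus(
                Locus(d["locus_id"], d["gene"], d["variant_label"], d["allele1"], d["allele2"]),
                d["p"],
                d.get("F", 0.0),
            )
            for d in doc["loci"]
        ]
        models = {
            (d["locus_id"], d["trait"]): TraitModel(
                mu=d["mu"], a=d["a"], d=d["d"],
                sex_effect=d.get("sex_effect", 0.0), sigma=d["sigma"],
            )
            for d in doc["trait_models"]
        }
        return cls(doc["n_samples"], doc["male_fraction"], loci, models, doc.get("seed", 0))


def genotype_class_probs(p: float, F: float = 0.0) -> tuple[float, float, float]:
    """Class probabilities (P11, P12, P22) under inbreeding coefficient F."""
    if not 0.0 <= p <= 1.0:
        raise CohortError(f"allele frequency out of [0,1]: {p}")
    if not 0.0 <= F <= 1.0:
        raise CohortError(f"inbreeding coefficient out of [0,1]: {F}")
    q = 1.0 - p
    return (p * p + F * p * q, 2 * p * q * (1 - F), q * q + F * p * q)


def simulate_genotypes(p: float, F: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n allele-2 dosage codes from the (p, F) class distribution."""
    probs = genotype_class_probs(p, F)
    return rng.choice(3, size=n, p=probs).astype(np.int8)


def simulate_sexes(n: int, male_fraction: float, rng: np.random.Generator) -> list[str]:
    return ["male" if u < male_fraction else "female" for u in rng.random(n)]


def simulate_traits(
    genotypes: np.ndarray,
    sexes: list[str],
    model: TraitModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Trait values for one locus model; reproducible for a fixed generator."""
    codes = np.asarray(genotypes)
    if codes.shape[0] != len(sexes):
        raise CohortError("genotype and sex lists must have equal length")
    g = np.choose(codes, [model.a, model.d, -model.a])
    male = np.array([s == "male" for s in sexes], dtype=float)
    return model.mu + g + model.sex_effect * male + rng.normal(0.0, model.sigma, codes.shape[0])


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, TraitTable]:
    """Generate a full cohort from a configuration.

    All randomness derives from one seed via named substreams (sexes, one
    per locus, one per trait model), so identical config + seed gives a
    bit-identical cohort regardless of evaluation order.  Each trait model
    produces its own column: a trait modelled at several loci yields one
    column per locus, suffixed with the gene name, so every column's
    genotype-class structure is driven by exactly one locus.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    n_streams = 1 + len(config.loci) + len(config.trait_models)
    streams = [np.random.default_rng(s) for s in root.spawn(n_streams)]
    sexes = simulate_sexes(config.n_samples, config.male_fraction, streams[0])
    codes = np.zeros((config.n_samples, len(config.loci)), dtype=np.int8)
    for j, sl in enumerate(config.loci):
        codes[:, j] = simulate_genotypes(sl.p, sl.F, config.n_samples, streams[1 + j])
    matrix = GenotypeMatrix(
        [f"s{i + 1:04d}" for i in range(config.n_samples)],
        [sl.locus for sl in config.loci],
        codes,
    )
    trait_count: dict[str, int] = {}
    for _, trait in config.trait_models:
        trait_count[trait] = trait_count.get(trait, 0) + 1
    locus_index = {sl.locus.locus_id: j for j, sl in enumerate(config.loci)}
    data = pd.DataFrame({"sex": sexes}, index=pd.Index(matrix.sample_ids, name="sample_id"))
    for k, ((locus_id, trait), model) in enumerate(config.trait_models.items()):
        gene = config.loci[locus_index[locus_id]].locus.gene
        column = trait if trait_count[trait] == 1 else f"{trait}_{gene.lower()}"
        data[column] = simulate_traits(
            codes[:, locus_index[locus_id]], sexes, model,
            streams[1 + len(config.loci) + k],
        )
    return matrix, TraitTable(data)


# ---------------------------------------------------------------------------
# Reference configuration: 72-animal pig cohort, six candidate loci.

_REFERENCE_LOCI: list[tuple[Locus, float]] = [
    (Locus("CTSB", "CTSB", "g.72A>C", "A", "C"), 0.96),
    (Locus("CTSL", "CTSL", "g.143C>T", "C", "T"), 0.91),
    (Locus("CTSS", "CTSS", "g.171G>A", "G", "A"), 1.00),
    (Locus("CTSK", "CTSK", "g.15G>A", "G", "A"), 0.98),
    (Locus("GHRH", "GHRH", "AluI", "A", "B"), 0.27),
    (Locus("LEPR", "LEPR", "c.1987C>T", "C", "T"), 0.67),
]

# Published genotype-class means and SEMs (class order 11/12/22) for the two
# informative loci; class sizes GHRH 5/29/38, LEPR 32/32/8.
_GHRH_CLASS_N = (5, 29, 38)
_LEPR_CLASS_N = (32, 32, 8)
_REFERENCE_CLASS_STATS: dict[tuple[str, str], tuple[tuple[float, ...], tuple[float, ...], tuple[int, ...]]] = {
    ("GHRH", "protein"): ((22.69, 21.65, 21.17), (0.81, 0.34, 0.30), _GHRH_CLASS_N),
    ("GHRH", "imf"): ((1.23, 1.41, 1.90), (0.38, 0.16, 0.14), _GHRH_CLASS_N),
    ("GHRH", "shear_force"): ((44.16, 40.86, 49.50), (1.18, 1.13, 1.62), _GHRH_CLASS_N),
    ("GHRH", "ph"): ((5.52, 5.49, 5.50), (0.08, 0.03, 0.03), _GHRH_CLASS_N),
    ("GHRH", "total_water"): ((73.53, 74.31, 74.04), (0.89, 0.37, 0.32), _GHRH_CLASS_N),
    ("GHRH", "ash"): ((1.12, 1.12, 1.09), (0.05, 0.02, 0.02), _GHRH_CLASS_N),
    ("LEPR", "protein"): ((21.75, 21.12, 20.97), (0.29, 0.34, 0.74), _LEPR_CLASS_N),
    ("LEPR", "imf"): ((1.73, 1.38, 2.61), (0.16, 0.19, 0.40), _LEPR_CLASS_N),
    ("LEPR", "shear_force"): ((50.71, 42.89, 51.65), (1.69, 1.72, 5.04), _LEPR_CLASS_N),
    ("LEPR", "ph"): ((5.45, 5.49, 5.53), (0.03, 0.03, 0.07), _LEPR_CLASS_N),
    ("LEPR", "total_water"): ((74.01, 74.62, 73.10), (0.30, 0.40, 0.85), _LEPR_CLASS_N),
    ("LEPR", "ash"): ((1.12, 1.12, 0.99), (0.02, 0.02, 0.04), _LEPR_CLASS_N),
}


def model_from_class_stats(
    means: tuple[float, ...], sems: tuple[float, ...], ns: tuple[int, ...]
) -> TraitModel:
    """Back out (mu, a, d, sigma) from class means and SEMs.

    mu is the homozygote midpoint, a the allele-1 homozygote deviation, d
    the heterozygote deviation; sigma is the class-averaged SD recovered
    as SEM * sqrt(n).
    """
    X11, X12, X22 = means
    mu = (X11 + X22) / 2.0
    sigma = float(np.mean([s * np.sqrt(n) for s, n in zip(sems, ns)]))
    return TraitModel(mu=mu, a=X11 - mu, d=X12 - mu, sex_effect=0.0, sigma=sigma)


def reference_config(seed: int = 0) -> SimulationConfig:
    """Study-scale configuration: n=72, ~1:1 sexes, six loci, trait models
    whose noiseless class means equal the published class means for the
    two informative loci."""
    models = {
        key: model_from_class_stats(*stats)
        for key, stats in _REFERENCE_CLASS_STATS.items()
    }
    return SimulationConfig(
        n_samples=72,
        male_fraction=0.5,
        loci=[SimulatedLocus(loc, p) for loc, p in _REFERENCE_LOCI],
        trait_models=models,
        seed=seed,
    )
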