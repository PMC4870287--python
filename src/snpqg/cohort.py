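"""Cohort data model and I/O.

Genotypes are stored as allele-2 dosage codes (0 = homozygous allele 1,
1 = heterozygous, 2 = homozygous allele 2, -1 = missing).  Allele 1 is
whichever allele the locus metadata lists first; it fixes the orientation
of every downstream effect estimate, so no automatic major/minor
reordering is ever applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SEX_TOKENS = {
    "male": "male", "m": "male", "castrate": "male", "barrow": "male",
    "female": "female", "f": "female", "gilt": "female", "sow": "female",
    "unknown": "unknown", "": "unknown", "na": "unknown", ".": "unknown",
}


class CohortError(ValueError):
    """Raised for malformed genotype/trait inputs."""


@dataclass(frozen=True)
class Locus:
    """A biallelic marker with a fixed effect-orientation allele.

    ``allele1`` is the reference allele for effect orientation: genotype
    class 11 means two copies of ``allele1``.
    """

    locus_id: str
    gene: str
    variant_label: str
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if not self.allele1 or not self.allele2:
            raise CohortError(f"locus {self.locus_id!r}: alleles must be non-empty")
        if self.allele1 == self.allele2:
            raise CohortError(f"locus {self.locus_id!r}: allele1 == allele2 ({self.allele1!r})")

    def genotype_labels(self) -> tuple[str, str, str]:
        """Class labels in (11, 12, 22) order, e.g. ('AA', 'AB', 'BB')."""
        return (
            self.allele1 + self.allele1,
            self.allele1 + self.allele2,
            self.allele2 + self.allele2,
        )

    def code_of(self, a: str, b: str) -> int:
        """Dosage code for an unordered allele pair; {x,y} == {y,x}."""
        pair = {a, b}
        if pair == {self.allele1}:
            return 0
        if pair == {self.allele1, self.allele2}:
            return 1
        if pair == {self.allele2}:
            return 2
        raise CohortError(
            f"alleles {a!r}/{b!r} not in {{{self.allele1!r}, {self.allele2!r}}}"
        )

    def call_string(self, code: int) -> str:
        if code == MISSING:
            return "./."
        return {
            0: f"{self.allele1}/{self.allele1}",
            1: f"{self.allele1}/{self.allele2}",
            2: f"{self.allele2}/{self.allele2}",
        }[int(code)]


@dataclass(frozen=True)
class GenotypeClassCounts:
    """Per-locus genotype class counts (11/12/22) plus missing calls."""

    n11: int
    n12: int
    n22: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n22, self.n_missing) < 0:
            raise CohortError("genotype counts must be non-negative")

    @property
    def n_called(self) -> int:
        return self.n11 + self.n12 + self.n22

    @property
    def n_total(self) -> int:
        return self.n_called + self.n_missing

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n11, self.n12, self.n22)


@dataclass
class GenotypeMatrix:
    """Samples x loci grid of unordered biallelic calls."""

    sample_ids: list[str]
    loci: list[Locus]
    codes: np.ndarray  # (n_samples, n_loci) int8 allele-2 dosage, -1 missing

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sample_ids), len(self.loci)):
            raise CohortError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CohortError("duplicate sample ids")
        ids = [loc.locus_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate locus ids")
        self._locus_index = {loc.locus_id: j for j, loc in enumerate(self.loci)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def locus(self, locus_id: str) -> Locus:
        try:
            return self.loci[self._locus_index[locus_id]]
        except KeyError:
            raise CohortError(f"unknown locus {locus_id!r}") from None

    def locus_codes(self, locus_id: str) -> np.ndarray:
        return self.codes[:, self._locus_index[self.locus(locus_id).locus_id]]

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep_set]
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx], list(self.loci), self.codes[idx, :]
        )

    def to_frame(self) -> pd.DataFrame:
        """Genotype calls as 'X/Y' strings, samples in rows."""
        data = {
            loc.locus_id: [loc.call_string(c) for c in self.codes[:, j]]
            for j, loc in enumerate(self.loci)
        }
        return pd.DataFrame(data, index=pd.Index(self.sample_ids, name="sample_id"))

    def write(self, path: str | Path, loci_path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")
        pd.DataFrame(
            [
                (l.locus_id, l.gene, l.variant_label, l.allele1, l.allele2)
                for l in self.loci
            ],
            columns=["locus_id", "gene", "variant_label", "allele1", "allele2"],
        ).to_csv(loci_path, sep="\t", index=False)


@dataclass
class TraitTable:
    """Per-sample sex and continuous trait values.

    Backed by a DataFrame indexed by sample_id with a 'sex' column followed
    by float trait columns; NaN marks a missing trait value.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise CohortError(f"duplicate sample ids in trait table: {dups}")
        if "sex" not in self.data.columns:
            raise CohortError("trait table must have a 'sex' column")
        bad = set(self.data["sex"]) - {"male", "female", "unknown"}
        if bad:
            raise CohortError(f"invalid sex values: {sorted(bad)}")
        for t in self.trait_names:
            vals = self.data[t]
            if np.isinf(vals.to_numpy(dtype=float, na_value=np.nan)).any():
                raise CohortError(f"non-finite values in trait {t!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.data.columns if c != "sex"]

    def values_for(self, trait: str, sample_ids: Sequence[str]) -> pd.Series:
        return self.data.loc[list(sample_ids), trait]

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path)


def read_loci_table(loci_path: str | Path) -> list[Locus]:
    meta = pd.read_csv(loci_path, sep="\t", dtype=str)
    required = {"locus_id", "gene", "variant_label", "allele1", "allele2"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise CohortError(f"locus metadata missing columns: {sorted(missing_cols)}")
    return [
        Locus(r.locus_id, r.gene, r.variant_label, r.allele1, r.allele2)
        for r in meta.itertuples()
    ]


def _parse_call(cell: str, locus: Locus, sample_id: str) -> int:
    cell = cell.strip()
    if cell in ("./.", ".|.", "", "."):
        return MISSING
    for sep in ("/", "|"):
        if sep in cell:
            a, b = cell.split(sep, 1)
            break
    else:
        raise CohortError(
            f"sample {sample_id!r}, locus {locus.locus_id!r}: "
            f"cannot parse genotype cell {cell!r}"
        )
    try:
        return locus.code_of(a, b)
    except CohortError:
        raise CohortError(
            f"sample {sample_id!r}, locus {locus.locus_id!r}: "
            f"unknown allele in {cell!r} (expected {locus.allele1!r}/{locus.allele2!r})"
        ) from None


def read_genotype_table(path: str | Path, loci_path: str | Path) -> GenotypeMatrix:
    """Read a genotype TSV plus its locus-metadata TSV.

    Cells use "X/Y" syntax ("|" accepted as "/"; phase is irrelevant here)
    with "./." for missing.  Unordered pairs are normalised so allele 1 is
    listed first; row order is preserved.
    """
    loci = read_loci_table(loci_path)
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("./.")
    if "sample_id" not in table.columns:
        raise CohortError("genotype table must have a 'sample_id' column")
    sample_ids = table["sample_id"].tolist()
    dup = [s for s, n in pd.Series(sample_ids).value_counts().items() if n > 1]
    if dup:
        raise CohortError(f"duplicate sample ids in genotype table: {dup}")
    for loc in loci:
        if loc.locus_id not in table.columns:
            raise CohortError(f"genotype table missing locus column {loc.locus_id!r}")
    codes = np.full((len(sample_ids), len(loci)), MISSING, dtype=np.int8)
    for j, loc in enumerate(loci):
        col = table[loc.locus_id].tolist()
        for i, cell in enumerate(col):
            codes[i, j] = _parse_call(cell, loc, sample_ids[i])
    return GenotypeMatrix(sample_ids, loci, codes)


def read_trait_table(path: str | Path) -> TraitTable:
    """Read a trait CSV (sample_id, sex, then trait columns).

    Non-numeric or empty trait cells become missing values (counted and
    logged); an unrecognised sex token is recorded as 'unknown' with a
    warning; a duplicate sample id is a hard error.
    """
    raw = pd.read_csv(path, dtype=str)
    if list(raw.columns[:2]) != ["sample_id", "sex"]:
        raise CohortError("trait CSV must start with columns sample_id, sex")
    dup = raw["sample_id"][raw["sample_id"].duplicated()].tolist()
    if dup:
        raise CohortError(f"duplicate sample ids in trait table: {dup}")
    sexes = []
    for s in raw["sex"].fillna(""):
        token = s.strip().lower()
        if token not in SEX_TOKENS:
            logger.warning("unrecognised sex token %r, recording as unknown", s)
            token = "unknown"
        sexes.append(SEX_TOKENS[token])
    out = pd.DataFrame({"sex": sexes}, index=pd.Index(raw["sample_id"], name="sample_id"))
    for col in raw.columns[2:]:
        vals = pd.to_numeric(raw[col], errors="coerce")
        n_bad = int(vals.isna().sum() - raw[col].isna().sum())
        if n_bad:
            logger.warning("trait %r: %d non-numeric cells set to missing", col, n_bad)
        n_missing = int(vals.isna().sum())
        if n_missing:
            logger.info("trait %r: %d missing values", col, n_missing)
        out[col] = vals.to_numpy(dtype=float)
    return TraitTable(out)


def read_vcf_biallelic(path: str | Path, locus_map: Mapping[tuple[str, int], Locus]) -> GenotypeMatrix:
    """Import genotypes from a biallelic VCF.

    ``locus_map`` maps (CHROM, POS) — POS 1-based as in the VCF standard —
    to the Locus it represents; the VCF REF allele must be the locus
    allele 1 or allele 2.  Unphased and phased separators are treated
    identically.  Sites absent from the map are skipped with a log line;
    a multiallelic mapped site is a hard error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    found: dict[str, np.ndarray] = {}
    loci_found: list[Locus] = []
    for rec in vcf:
        key = (rec.CHROM, rec.POS)
        if key not in locus_map:
            logger.info("VCF site %s:%d not in locus map, skipped", rec.CHROM, rec.POS)
            continue
        locus = locus_map[key]
        if len(rec.ALT) != 1:
            raise CohortError(
                f"site {rec.CHROM}:{rec.POS} is not biallelic (ALT={rec.ALT})"
            )
        alleles = [rec.REF, rec.ALT[0]]
        for a in alleles:
            if a not in (locus.allele1, locus.allele2):
                raise CohortError(
                    f"site {rec.CHROM}:{rec.POS}: VCF allele {a!r} not in locus "
                    f"{locus.locus_id!r} ({locus.allele1!r}/{locus.allele2!r})"
                )
        col = np.full(len(sample_ids), MISSING, dtype=np.int8)
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        for i, g in enumerate(rec.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                continue
            col[i] = locus.code_of(alleles[a], alleles[b])
        found[locus.locus_id] = col
        loci_found.append(locus)
    codes = (
        np.stack([found[l.locus_id] for l in loci_found], axis=1)
        if loci_found
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids, loci_found, codes)


def genotype_class_counts(matrix: GenotypeMatrix, locus_id: str) -> GenotypeClassCounts:
    """Genotype class counts (Table-2 style N column) for one locus."""
    codes = matrix.locus_codes(locus_id)
    return GenotypeClassCounts(
        n11=int(np.sum(codes == 0)),
        n12=int(np.sum(codes == 1)),
        n22=int(np.sum(codes == 2)),
        n_missing=int(np.sum(codes == MISSING)),
    )


@dataclass
class ScreeningReport:
    """Outcome of a screening-locus filter (e.g. the RYR1 stress screen)."""

    locus_id: str
    required_class: str
    retained: list[str]
    excluded: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)


def screen_samples(
    matrix: GenotypeMatrix, screening_locus: str, required_class: str
) -> ScreeningReport:
    """Retain samples whose call at a screening locus equals ``required_class``.

    ``required_class`` is a genotype label such as "CC" (allele order
    irrelevant).  Samples with a missing call are excluded but flagged as
    missing rather than as carrying the unwanted genotype.
    """
    locus = matrix.locus(screening_locus)
    if len(required_class) != 2:
        raise CohortError(f"required_class must be a two-allele label, got {required_class!r}")
    want = locus.code_of(required_class[0], required_class[1])
    codes = matrix.locus_codes(screening_locus)
    report = ScreeningReport(screening_locus, required_class, retained=[])
    for sid, c in zip(matrix.sample_ids, codes):
        if c == MISSING:
            report.missing.append(sid)
        elif c == want:
            report.retained.append(sid)
        else:
            report.excluded.append(sid)
    return report


@dataclass(frozen=True)
class EligibilityDecision:
    locus_id: str
    eligible: bool
    reason: str  # machine-readable: "ok" | "monomorphic" | "only {k} class(es) with n>={m}"


def eligible_loci(
    counts_by_locus: Mapping[str, GenotypeClassCounts],
    min_class_n: int = 3,
    min_classes: int = 2,
) -> tuple[list[str], list[EligibilityDecision]]:
    """Decide which loci enter association testing.

    A locus is eligible when at least ``min_classes`` genotype classes each
    have n >= ``min_class_n``.  Monomorphic loci are always ineligible.  The
    defaults admit a locus with only two populated classes (six
    heterozygotes suffice) while rejecting one with a lone two-animal
    heterozygote class.
    """
    if min_class_n < 1:
        raise CohortError("min_class_n must be >= 1")
    if min_classes not in (2, 3):
        raise CohortError("min_classes must be 2 or 3")
    eligible: list[str] = []
    decisions: list[EligibilityDecision] = []
    for locus_id, counts in counts_by_locus.items():
        triple = counts.as_tuple()
        n_polymorphic = sum(1 for n in triple if n > 0)
        if n_polymorphic <= 1:
            decisions.append(EligibilityDecision(locus_id, False, "monomorphic"))
            continue
        k = sum(1 for n in triple if n >= min_class_n)
        if k >= min_classes:
            eligible.append(locus_id)
            decisions.append(EligibilityDecision(locus_id, True, "ok"))
        else:
            decisions.append(
                EligibilityDecision(
                    locus_id,
                    False,
                    f"only {k} class(es) with n>={min_class_n}",
                )
            )
    return eligible, decisions
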