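"""Core data containers shared across the pipeline.

The analysis operates on three tables:

* a genotype matrix of effect-allele dosages (subjects x SNPs, values in
  {0, 1, 2} with NaN for failed genotyping calls),
* a phenotype table (subject, disease, age at onset in years, expanded CAG
  repeat length, sex), and
* a SNP prior table carrying each SNP's reference-study (GeM-HD) effect
  direction and effect-size weight in years of onset shift per effect allele.

Dosage counts the prior table's *effect allele*, not the sample minor
allele: effect directions and score weights are defined relative to the
reference study's alleles, and the sample minor allele can differ between
cohorts while still corresponding to the same allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The polyglutamine diseases in the panel, in canonical order.
DISEASES: tuple[str, ...] = ("HD", "SCA1", "SCA2", "SCA3", "SCA6", "SCA7", "SCA17")

VALID_SEX = ("M", "F", "unknown")

VALID_BASES = frozenset("ACGT")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(base: str) -> str:
    """Watson-Crick complement of a single base."""
    return _COMPLEMENT[base]


class CohortError(ValueError):
    """Raised for invalid cohort inputs (malformed tables, bad alleles...)."""


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs effect-allele dosage matrix.

    Parameters
    ----------
    dosage
        DataFrame indexed by subject id with one column per SNP id; values
        are floats in {0.0, 1.0, 2.0} or NaN for a missing call.
    effect_allele, other_allele
        Per-SNP allele labels (Series indexed by SNP id). Dosage counts
        copies of ``effect_allele``.
    """

    dosage: pd.DataFrame
    effect_allele: pd.Series
    other_allele: pd.Series

    def __post_init__(self) -> None:
        if self.dosage.index.has_duplicates:
            raise CohortError("duplicated subject ids in genotype matrix")
        if self.dosage.columns.has_duplicates:
            raise CohortError("duplicated SNP ids in genotype matrix")
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise CohortError(f"dosage values outside {{0,1,2,missing}}: {bad[:5]}")
        for s in (self.effect_allele, self.other_allele):
            missing = [c for c in self.dosage.columns if c not in s.index]
            if missing:
                raise CohortError(f"allele labels missing for SNPs: {missing[:5]}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def call_rate(self) -> pd.Series:
        """Per-SNP fraction of non-missing genotype calls."""
        return self.dosage.notna().mean(axis=0)

    def effect_allele_freq(self) -> pd.Series:
        """Per-SNP effect-allele frequency among non-missing calls."""
        return self.dosage.mean(axis=0, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        """Folded minor-allele frequency, min(f, 1-f)."""
        f = self.effect_allele_freq()
        return np.minimum(f, 1.0 - f)

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        keep = [s for s in snp_ids if s in self.dosage.columns]
        return GenotypeMatrix(
            dosage=self.dosage[keep].copy(),
            effect_allele=self.effect_allele.loc[keep].copy(),
            other_allele=self.other_allele.loc[keep].copy(),
        )

    def subset_subjects(self, subject_ids) -> "GenotypeMatrix":
        keep = [s for s in subject_ids if s in self.dosage.index]
        return GenotypeMatrix(
            dosage=self.dosage.loc[keep].copy(),
            effect_allele=self.effect_allele.copy(),
            other_allele=self.other_allele.copy(),
        )


@dataclass(frozen=True)
class SnpPrior:
    """Reference-study metadata for one panel SNP.

    ``gem_direction`` is +1 if one copy of the effect allele was associated
    with *later* onset in the reference GWAS, -1 for earlier onset.
    ``gem_weight_years`` is the signed onset shift in years per effect
    allele; its sign must agree with ``gem_direction`` when nonzero.
    """

    snp_id: str
    gene: str
    effect_allele: str
    other_allele: str
    gem_direction: int
    gem_weight_years: float
    gem_p: float = float("nan")
    strand_flag: str = "forward"

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise CohortError(
                f"{self.snp_id}: alleles must be A/C/G/T, got "
                f"{self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise CohortError(f"{self.snp_id}: effect and other allele identical")
        if self.gem_direction not in (-1, 1):
            raise CohortError(f"{self.snp_id}: gem_direction must be +1 or -1")
        if self.gem_weight_years != 0 and not np.isnan(self.gem_weight_years):
            if int(np.sign(self.gem_weight_years)) != self.gem_direction:
                raise CohortError(
                    f"{self.snp_id}: sign of gem_weight_years disagrees with gem_direction"
                )
        if self.strand_flag not in ("forward", "reverse-assay"):
            raise CohortError(f"{self.snp_id}: bad strand_flag {self.strand_flag!r}")


def priors_to_frame(priors: list[SnpPrior]) -> pd.DataFrame:
    """Tabulate a list of priors, indexed by snp_id."""
    df = pd.DataFrame(
        {
            "snp_id": [p.snp_id for p in priors],
            "gene": [p.gene for p in priors],
            "effect_allele": [p.effect_allele for p in priors],
            "other_allele": [p.other_allele for p in priors],
            "gem_direction": [p.gem_direction for p in priors],
            "gem_weight_years": [p.gem_weight_years for p in priors],
            "gem_p": [p.gem_p for p in priors],
            "strand_flag": [p.strand_flag for p in priors],
        }
    )
    return df.set_index("snp_id", drop=False)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a phenotype table, dropping invalid rows.

    Required columns: subject_id, disease, aao_years, cag_expanded, sex.
    Rows with a disease outside the panel, non-positive age at onset, or a
    non-positive repeat length are rejected; the number of rejected rows is
    recorded in ``df.attrs["n_rejected"]``.
    """
    required = ["subject_id", "disease", "aao_years", "cag_expanded", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"phenotype table missing columns: {missing}")
    out = df[required].copy()
    out["aao_years"] = pd.to_numeric(out["aao_years"], errors="coerce")
    out["cag_expanded"] = pd.to_numeric(out["cag_expanded"], errors="coerce")
    out["sex"] = out["sex"].fillna("unknown").astype(str)
    out.loc[~out["sex"].isin(VALID_SEX), "sex"] = "unknown"
    ok = (
        out["disease"].isin(DISEASES)
        & (out["aao_years"] > 0)
        & (out["cag_expanded"] >= 1)
        & out["aao_years"].notna()
        & out["cag_expanded"].notna()
    )
    n_rejected = int((~ok).sum())
    out = out.loc[ok].reset_index(drop=True)
    if out["subject_id"].duplicated().any():
        dups = out.loc[out["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortError(f"duplicated subject ids in phenotype table: {dups[:5]}")
    out["cag_expanded"] = out["cag_expanded"].astype(int)
    out.attrs["n_rejected"] = n_rejected
    return out


@dataclass(frozen=True)
class DiseaseGroup:
    """A named grouping of diseases analyzed together.

    The study analyzes eight groups; SCA17 is too small to stand alone and
    enters only the pooled groups.
    """

    name: str
    members: tuple[str, ...]

    def mask(self, phenotypes: pd.DataFrame) -> pd.Series:
        return phenotypes["disease"].isin(self.members)


#: The eight disease groups of the primary analysis.
DISEASE_GROUPS: tuple[DiseaseGroup, ...] = (
    DiseaseGroup("HD+SCAs", DISEASES),
    DiseaseGroup("HD", ("HD",)),
    DiseaseGroup("allSCAs", ("SCA1", "SCA2", "SCA3", "SCA6", "SCA7", "SCA17")),
    DiseaseGroup("SCA1", ("SCA1",)),
    DiseaseGroup("SCA2", ("SCA2",)),
    DiseaseGroup("SCA3", ("SCA3",)),
    DiseaseGroup("SCA6", ("SCA6",)),
    DiseaseGroup("SCA7", ("SCA7",)),
)

GROUPS_BY_NAME = {g.name: g for g in DISEASE_GROUPS}
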