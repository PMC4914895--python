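"""Reading and writing genotypes, phenotypes and SNP priors.

Genotypes travel either as a minimal VCF (GT field only, one ALT) or as a
transparent dosage TSV (rows = subjects, columns = SNPs, "NA" for a missing
call). On read, every genotype is harmonized to count the prior table's
effect allele, resolving strand-flipped assays where possible: several
candidate-panel assays are designed in reverse orientation to the
chromosome, so their called alleles are the complement of the reference
nomenclature.
"""

from __future__ import annotations

import logging
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CohortError,
    GenotypeMatrix,
    SnpPrior,
    complement,
    priors_to_frame,
    validate_phenotypes,
)

logger = logging.getLogger("polyqmod")

_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


class Orientation(Enum):
    """Action needed to express observed alleles on the prior's strand."""

    KEEP = "keep"
    FLIP_DOSAGE = "flip-dosage"
    COMPLEMENT = "complement-then-resolve"
    FAIL = "fail"


def harmonize_alleles(
    observed: tuple[str, str], prior: SnpPrior
) -> tuple[Orientation, bool]:
    """Reconcile an observed (ref, alt) allele pair with a SNP prior.

    Returns the orientation action and whether the ALT-allele dosage must be
    flipped (d -> 2 - d) so that it counts the prior's effect allele.
    Strand-ambiguous pairs (A/T, C/G) fail outright: with reverse-orientation
    assays in the panel, their orientation cannot be established.
    """
    a1, a2 = observed
    obs = {a1, a2}
    if obs in _AMBIGUOUS_PAIRS:
        return Orientation.FAIL, False
    target = {prior.effect_allele, prior.other_allele}
    if obs == target:
        return Orientation.KEEP, a2 != prior.effect_allele
    comp = {complement(a1), complement(a2)}
    if comp == target:
        return Orientation.COMPLEMENT, complement(a2) != prior.effect_allele
    return Orientation.FAIL, False


# ---------------------------------------------------------------------------
# priors

PRIOR_COLUMNS = [
    "snp_id",
    "gene",
    "effect_allele",
    "other_allele",
    "gem_direction",
    "gem_weight_years",
    "gem_p",
    "strand_flag",
]


def read_priors(path: str | Path) -> pd.DataFrame:
    """Read a SNP prior table (TSV), validating every row."""
    raw = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene": str})
    missing = [c for c in PRIOR_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortError(f"priors file missing columns: {missing}")
    priors = [
        SnpPrior(
            snp_id=row.snp_id,
            gene=row.gene,
            effect_allele=row.effect_allele,
            other_allele=row.other_allele,
            gem_direction=int(row.gem_direction),
            gem_weight_years=float(row.gem_weight_years),
            gem_p=float(row.gem_p) if pd.notna(row.gem_p) else float("nan"),
            strand_flag=row.strand_flag,
        )
        for row in raw.itertuples(index=False)
    ]
    return priors_to_frame(priors)


def write_priors(priors: pd.DataFrame, path: str | Path) -> None:
    priors[PRIOR_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read and validate a phenotype TSV; invalid rows are dropped and
    counted in ``df.attrs["n_rejected"]``."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    out = validate_phenotypes(df)
    if out.attrs["n_rejected"]:
        logger.warning(
            "phenotypes: rejected %d invalid rows from %s",
            out.attrs["n_rejected"], path,
        )
    return out


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    cols = ["subject_id", "disease", "aao_years", "cag_expanded", "sex"]
    phenotypes[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes: dosage TSV

def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Dosage TSV: first column subject_id, then one integer column per SNP,
    "NA" for missing."""
    out = genotypes.dosage.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def _read_dosage_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="subject_id", na_values=["NA"])
    if df.index.has_duplicates:
        raise CohortError(f"duplicated subject ids in {path}")
    return df.astype(float)


# ---------------------------------------------------------------------------
# genotypes: minimal VCF

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##source=polyqmod synthetic panel (coordinates are placeholders)\n"
)


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal single-ALT, GT-only VCF.

    REF is the prior's other allele and ALT the effect allele, so the ALT
    count equals the stored dosage. Chromosome/position are synthetic: the
    analysis is id-keyed and coordinate-free.
    """
    subjects = genotypes.subject_ids
    lines = [VCF_HEADER]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(subjects) + "\n"
    )
    dose = genotypes.dosage.to_numpy(dtype=float)
    for j, sid in enumerate(genotypes.snp_ids):
        ref = genotypes.other_allele[sid]
        alt = genotypes.effect_allele[sid]
        calls = []
        for d in dose[:, j]:
            if np.isnan(d):
                calls.append("./.")
            else:
                d = int(d)
                calls.append({0: "0/0", 1: "0/1", 2: "1/1"}[d])
        lines.append(
            f"1\t{j + 1}\t{sid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(calls) + "\n"
        )
    Path(path).write_text("".join(lines))


def _read_vcf(path: str | Path) -> tuple[pd.DataFrame, dict[str, tuple[str, str]]]:
    """Read a GT-only VCF into an ALT-dosage frame plus (ref, alt) pairs."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    if len(subjects) != len(set(subjects)):
        raise CohortError(f"duplicated subject ids in {path}")
    cols: dict[str, np.ndarray] = {}
    alleles: dict[str, tuple[str, str]] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            raise CohortError(f"multi-allelic record for SNP {var.ID}")
        sid = var.ID
        gts = var.genotypes  # [allele1, allele2, phased]
        d = np.empty(len(subjects), dtype=float)
        for i, g in enumerate(gts):
            a = [x for x in g[:-1] if x >= 0]
            d[i] = float(sum(a)) if len(a) == 2 else np.nan
        cols[sid] = d
        alleles[sid] = (var.REF, var.ALT[0])
    vcf.close()
    frame = pd.DataFrame(cols, index=subjects)
    return frame, alleles


def read_genotypes(
    path: str | Path, format: str, priors: pd.DataFrame
) -> GenotypeMatrix:
    """Read genotypes and harmonize dosages to count each prior's effect
    allele.

    SNPs absent from the prior table are dropped with a warning; SNPs whose
    alleles cannot be reconciled with the prior (including strand-ambiguous
    A/T and C/G pairs) raise.
    """
    if format == "dosage-tsv":
        frame = _read_dosage_tsv(path)
        alleles = None  # TSV is effect-allele-coded by convention
    elif format == "vcf":
        frame, alleles = _read_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    keep, eff, oth = [], {}, {}
    for sid in frame.columns:
        if sid not in priors.index:
            logger.warning("genotypes: SNP %s absent from priors, dropped", sid)
            continue
        prior_row = priors.loc[sid]
        prior = SnpPrior(
            snp_id=sid,
            gene=prior_row["gene"],
            effect_allele=prior_row["effect_allele"],
            other_allele=prior_row["other_allele"],
            gem_direction=int(prior_row["gem_direction"]),
            gem_weight_years=float(prior_row["gem_weight_years"]),
            gem_p=float(prior_row["gem_p"]),
            strand_flag=prior_row["strand_flag"],
        )
        if alleles is not None:
            action, flip = harmonize_alleles(alleles[sid], prior)
            if action is Orientation.FAIL:
                raise CohortError(
                    f"SNP {sid}: observed alleles {alleles[sid]} irreconcilable "
                    f"with prior {prior.effect_allele}/{prior.other_allele}"
                )
            if flip:
                frame[sid] = 2.0 - frame[sid]
        keep.append(sid)
        eff[sid] = prior.effect_allele
        oth[sid] = prior.other_allele
    if not keep:
        raise CohortError("no genotyped SNP matched the prior table")
    return GenotypeMatrix(
        dosage=frame[keep],
        effect_allele=pd.Series(eff),
        other_allele=pd.Series(oth),
    )
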