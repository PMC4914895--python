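"""Per-SNP additive association of residual age at onset with
effect-allele dosage.

For each SNP and disease group, residual AAO is regressed on the number of
effect alleles (0/1/2). The regression is an intercept + dosage OLS solved
in closed form from the normal equations; subjects with a missing call at a
SNP are dropped pairwise for that SNP only, so each SNP keeps the n its
assay success rate allows.

Besides the usual two-sided t-test p-value, each association carries a
directional one-sided p-value aligned with the reference study's effect
direction: p_one = p_two/2 when the fitted slope has the prior's sign,
1 - p_two/2 otherwise. A slope of exactly zero has no direction and gets
p_one = 0.5 by continuity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DISEASE_GROUPS, DiseaseGroup, GenotypeMatrix

__all__ = ["SnpAssociation", "associate", "associate_all", "MIN_GROUP_N"]

MIN_GROUP_N = 10


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP x disease-group regression result."""

    snp_id: str
    group: str
    n_used: int
    beta: float        # years (or ln-years) of residual shift per effect allele
    se: float
    t_stat: float
    p_two: float
    p_one: float
    concordant: bool
    computable: bool = True
    note: str = ""


def _one_sided(p_two: float, beta: float, direction: int) -> tuple[float, bool]:
    if beta == 0.0:
        return 0.5, False
    concordant = int(np.sign(beta)) == direction
    p_one = p_two / 2.0 if concordant else 1.0 - p_two / 2.0
    return min(max(p_one, np.nextafter(0, 1)), 1.0), concordant


def _not_computable(snp_id: str, group: str, n: int, note: str) -> SnpAssociation:
    nan = float("nan")
    return SnpAssociation(snp_id, group, n, nan, nan, nan, nan, nan, False, False, note)


def associate(
    residuals: pd.DataFrame,
    genotypes: GenotypeMatrix,
    prior: pd.Series,
    group: DiseaseGroup,
) -> SnpAssociation:
    """Regress residual AAO on effect-allele dosage within one disease group.

    ``prior`` is one row of the prior table (needs gem_direction). Requires
    at least :data:`MIN_GROUP_N` complete observations and nonzero dosage
    variance; otherwise the association is marked not computable.
    """
    snp_id = str(prior["snp_id"])
    in_group = residuals[group.mask(residuals)]
    dose = genotypes.dosage[snp_id].reindex(in_group["subject_id"]).to_numpy(dtype=float)
    y = in_group["residual"].to_numpy(dtype=float)
    ok = ~np.isnan(dose) & ~np.isnan(y)
    x, y = dose[ok], y[ok]
    n = int(ok.sum())
    if n < MIN_GROUP_N:
        return _not_computable(snp_id, group.name, n, f"n<{MIN_GROUP_N}")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        return _not_computable(snp_id, group.name, n, "monomorphic")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    syy = np.sum((y - y.mean()) ** 2)
    beta = sxy / sxx
    df = n - 2
    rss = max(syy - beta * sxy, 0.0)
    s2 = rss / df
    if s2 == 0:
        # perfect fit: infinite t, p -> 0
        se, t, p_two = 0.0, np.inf * np.sign(beta) if beta else 0.0, np.nextafter(0, 1)
        if beta == 0:
            p_two = 1.0
    else:
        se = float(np.sqrt(s2 / sxx))
        t = float(beta / se)
        p_two = float(2.0 * stats.t.sf(abs(t), df))
        p_two = min(max(p_two, np.nextafter(0, 1)), 1.0)
    direction = int(prior["gem_direction"])
    p_one, concordant = _one_sided(p_two, float(beta), direction)
    return SnpAssociation(
        snp_id=snp_id,
        group=group.name,
        n_used=n,
        beta=float(beta),
        se=float(se),
        t_stat=float(t),
        p_two=float(p_two),
        p_one=float(p_one),
        concordant=bool(concordant),
    )


def associate_all(
    residuals: pd.DataFrame,
    genotypes: GenotypeMatrix,
    priors: pd.DataFrame,
    groups: tuple[DiseaseGroup, ...] = DISEASE_GROUPS,
) -> pd.DataFrame:
    """All SNP x group associations as one tidy table.

    Rows appear in (group, SNP) order — one row per retained SNP per group.
    Not-computable associations are kept as rows with ``computable=False``
    so downstream combination can drop them explicitly.
    """
    rows = []
    for group in groups:
        for snp_id in genotypes.snp_ids:
            if snp_id not in priors.index:
                continue
            a = associate(residuals, genotypes, priors.loc[snp_id], group)
            rows.append(a)
    df = pd.DataFrame([vars(a) for a in rows])
    if not df.empty:
        df = df.merge(
            priors[["snp_id", "gene"]].reset_index(drop=True), on="snp_id", how="left"
        )
        df = df[
            [
                "snp_id", "gene", "group", "n_used", "beta", "se", "t_stat",
                "p_two", "p_one", "concordant", "computable", "note",
            ]
        ]
    return df
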