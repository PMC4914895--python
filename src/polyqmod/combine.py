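"""LD-aware combination of per-SNP p-values by Brown's method.

Fisher's statistic X = -2 * sum(ln p_i) is chi-square with 2k degrees of
freedom only when the k tests are independent. Candidate SNP panels are
not: proxy SNPs sit in linkage disequilibrium, correlating their test
statistics and making naive Fisher anti-conservative. Brown's method keeps
the statistic but moment-matches its null distribution with a scaled
chi-square c * chi2_f, where

    E[X]   = 2k
    Var[X] = 4k + 2 * sum_{i<j} delta_ij
    c = Var[X] / (2 E[X]),   f = 2 E[X]^2 / Var[X]

and delta_ij = cov(-2 ln p_i, -2 ln p_j) under the null. The covariance is
mapped from the correlation rho of the underlying test statistics by the
Kost-McDermott cubic polynomial

    delta(rho) = 3.263*rho + 0.710*rho^2 + 0.027*rho^3

evaluated at the signed correlation (the same cubic tracks the exact
covariance on both branches; see :func:`kost_mcdermott_delta`). For the
one-sided, direction-aligned flavor the statistic correlation is
rho_ij = d_i * d_j * r_ij (prior directions d, dosage correlation r); for
the two-sided flavor the dependence is direction-free and r_ij^2 is used.
A seeded Monte-Carlo estimate of delta is available as a cross-check on
the polynomial.

With identity LD the method reduces exactly to Fisher; with a single test
it returns the input p-value unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix

logger = logging.getLogger("polyqmod")

__all__ = [
    "LdMatrix",
    "BrownResult",
    "ld_matrix",
    "kost_mcdermott_delta",
    "brown_combine",
    "fisher_combine",
    "bonferroni_tiers",
    "sensitivity_subsets",
    "high_ld_proxy_scan",
]

MIN_COMPLETE_PAIRS = 10


@dataclass
class LdMatrix:
    """Pairwise dosage correlations for a SNP panel.

    ``r`` is the symmetric Pearson correlation matrix of dosage columns over
    pairwise-complete subjects (NaN where fewer than the minimum number of
    complete pairs exist); ``n_pairs`` counts complete pairs per entry.
    """

    r: pd.DataFrame
    n_pairs: pd.DataFrame

    @property
    def snp_ids(self) -> list[str]:
        return list(self.r.columns)

    def submatrix(self, snp_ids: list[str]) -> "LdMatrix":
        return LdMatrix(
            r=self.r.loc[snp_ids, snp_ids].copy(),
            n_pairs=self.n_pairs.loc[snp_ids, snp_ids].copy(),
        )


def ld_matrix(
    genotypes: GenotypeMatrix,
    subjects: list[str] | None = None,
    min_pairs: int = MIN_COMPLETE_PAIRS,
) -> LdMatrix:
    """Pairwise-complete Pearson correlation of dosage vectors.

    Entries supported by fewer than ``min_pairs`` complete observations are
    set missing (NaN) and later treated as zero covariance with a warning.
    """
    dose = genotypes.dosage if subjects is None else genotypes.dosage.loc[subjects]
    if dose.shape[1] < 2:
        raise ValueError("need >=2 SNPs for an LD matrix")
    r = dose.corr(min_periods=min_pairs)
    np.fill_diagonal(r.to_numpy(), 1.0)
    obs = dose.notna().to_numpy(dtype=float)
    n_pairs = pd.DataFrame(obs.T @ obs, index=dose.columns, columns=dose.columns)
    n_missing = int(np.isnan(r.to_numpy()).sum())
    if n_missing:
        logger.warning("ld_matrix: %d entries below %d complete pairs set missing",
                       n_missing // 2, min_pairs)
    return LdMatrix(r=r, n_pairs=n_pairs)


def kost_mcdermott_delta(rho: np.ndarray) -> np.ndarray:
    """cov(-2 ln p_i, -2 ln p_j) from statistic correlation rho.

    The cubic is evaluated at the signed correlation: the even-power term
    keeps its sign, which reproduces the true covariance on the negative
    branch as well (at rho = -1 the exact value is 4 - 2*pi^2/3 ~ -2.58,
    not -4; an odd-symmetric reflection of the positive branch would
    overstate negative covariance by up to 55%).
    """
    rho = np.asarray(rho, dtype=float)
    return 3.263 * rho + 0.710 * rho**2 + 0.027 * rho**3


def _mc_delta(rho: np.ndarray, flavor: str, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo estimate of the -2 ln p covariance matrix under the
    multivariate-normal null with statistic correlation ``rho``."""
    k = rho.shape[0]
    # nearest-PSD guard: clip tiny negative eigenvalues from estimated LD
    w, v = np.linalg.eigh(rho)
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal((n_draws, k)) @ (v * np.sqrt(w)).T
    if flavor == "one_sided":
        p = stats.norm.sf(z)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    x = -2.0 * np.log(np.clip(p, 1e-300, 1.0))
    return np.cov(x, rowvar=False)


@dataclass
class BrownResult:
    """Combined evidence for one SNP set in one disease group."""

    group: str
    flavor: str             # one_sided | two_sided
    k: int
    X: float                # -2 sum ln p
    c: float                # scale of the matched chi-square
    f: float                # degrees of freedom of the matched chi-square
    p_combined: float
    n_missing_ld: int = 0   # LD entries treated as zero covariance

    @property
    def mean_null(self) -> float:
        return 2.0 * self.k

    @property
    def var_null(self) -> float:
        return 2.0 * self.mean_null * self.c


def fisher_combine(p_values: np.ndarray) -> float:
    """Fisher's method: -2 sum ln p ~ chi2 with 2k df (independence)."""
    p = np.asarray(p_values, dtype=float)
    X = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(X, 2 * p.size))


def brown_combine(
    p_values: pd.Series | np.ndarray,
    ld: LdMatrix | None,
    flavor: str,
    directions: pd.Series | np.ndarray | None = None,
    group: str = "",
    cov_method: str = "polynomial",
    mc_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> BrownResult:
    """Combine dependent p-values by Brown's scaled chi-square.

    Parameters
    ----------
    p_values
        Per-SNP p-values in (0, 1]; a Series indexed by snp_id or an array
        aligned with ``ld.snp_ids``.
    ld
        Dosage LD matrix covering the SNPs (None -> identity, i.e. Fisher).
    flavor
        "one_sided" for direction-aligned p-values (statistic correlation
        d_i*d_j*r_ij) or "two_sided" (correlation r_ij^2).
    directions
        Per-SNP prior directions (+1/-1), required for the one-sided flavor.
    cov_method
        "polynomial" (Kost-McDermott cubic) or "montecarlo" (seeded draw
        from the multivariate-normal null; cross-check path).
    """
    if flavor not in ("one_sided", "two_sided"):
        raise ValueError(f"flavor must be one_sided or two_sided, got {flavor!r}")
    if isinstance(p_values, pd.Series):
        snp_ids = list(p_values.index)
        p = p_values.to_numpy(dtype=float)
    else:
        p = np.asarray(p_values, dtype=float)
        snp_ids = list(ld.snp_ids) if ld is not None else [str(i) for i in range(p.size)]
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    k = p.size
    X = float(-2.0 * np.sum(np.log(p)))

    if k == 1:
        return BrownResult(group, flavor, 1, X, 1.0, 2.0, float(p[0]))

    if ld is None:
        r = np.eye(k)
        n_missing = 0
    else:
        r = ld.r.loc[snp_ids, snp_ids].to_numpy(dtype=float).copy()
        n_missing = int(np.isnan(r).sum()) // 2
        if n_missing:
            logger.warning(
                "brown_combine[%s/%s]: %d missing LD entries treated as independent",
                group, flavor, n_missing,
            )
            r = np.where(np.isnan(r), 0.0, r)
        np.fill_diagonal(r, 1.0)

    if flavor == "one_sided":
        if directions is None:
            raise ValueError("one_sided flavor requires per-SNP directions")
        if isinstance(directions, pd.Series):
            d = directions.loc[snp_ids].to_numpy(dtype=float)
        else:
            d = np.asarray(directions, dtype=float)
        rho = np.outer(d, d) * r
    else:
        rho = r**2

    if cov_method == "polynomial":
        delta = kost_mcdermott_delta(rho)
    elif cov_method == "montecarlo":
        if rng is None:
            rng = np.random.default_rng(0)
        delta = _mc_delta(rho, flavor, mc_draws, rng)
    else:
        raise ValueError(f"unknown cov_method {cov_method!r}")

    iu = np.triu_indices(k, 1)
    mean_null = 2.0 * k
    var_null = 4.0 * k + 2.0 * float(np.sum(delta[iu]))
    var_null = max(var_null, 2.0 * mean_null * 1e-6)  # floor against pathological delta sums
    c = var_null / (2.0 * mean_null)
    f = 2.0 * mean_null**2 / var_null
    p_combined = float(stats.chi2.sf(X / c, f))
    p_combined = min(max(p_combined, np.nextafter(0, 1)), 1.0)
    return BrownResult(group, flavor, k, X, c, f, p_combined, n_missing)


def bonferroni_tiers(n_snps: int, n_groups: int, alpha: float = 0.05) -> dict[str, float]:
    """Multiplicity thresholds for the single-SNP and combined analyses.

    tier1: alpha / (n_snps * n_groups)  — single-SNP, all groups
    tier2: alpha / n_snps               — single-SNP, one group
    group: alpha / n_groups             — combined (primary) analysis
    Each is also reported rounded to 3 significant figures.
    """
    if n_snps < 1 or n_groups < 1:
        raise ValueError("n_snps and n_groups must be >= 1")

    def sig3(x: float) -> float:
        return float(f"{x:.3g}")

    tier1 = alpha / (n_snps * n_groups)
    tier2 = alpha / n_snps
    group = alpha / n_groups
    return {
        "tier1": tier1,
        "tier1_3sf": sig3(tier1),
        "tier2": tier2,
        "tier2_3sf": sig3(tier2),
        "group": group,
        "group_3sf": sig3(group),
    }


def high_ld_proxy_scan(ld: LdMatrix, threshold: float = 0.8) -> pd.DataFrame:
    """All unordered SNP pairs with r^2 strictly above ``threshold``.

    These flag proxy SNPs whose signals are not independent; the pair list
    feeds the named LD-pruning sensitivity subset.
    """
    ids = ld.snp_ids
    r = ld.r.to_numpy(dtype=float)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r2 = r[i, j] ** 2
            if not np.isnan(r2) and r2 > threshold:
                rows.append((ids[i], ids[j], r[i, j], r2))
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r", "r2"])


def sensitivity_subsets(
    p_values: pd.Series,
    ld: LdMatrix | None,
    subsets: dict[str, list[str]],
    flavor: str,
    directions: pd.Series | None = None,
    group: str = "",
    cov_method: str = "polynomial",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Recombine after removing named SNP subsets.

    ``subsets`` maps a subset name to the SNP ids to *remove*. Each variant
    reports its BrownResult fields plus the change in -log10(p_combined)
    relative to the full panel (negative = less significant after removal).
    """
    full = brown_combine(
        p_values, ld, flavor, directions, group=group, cov_method=cov_method, rng=rng
    )
    rows = [
        {
            "subset": "full_panel",
            "removed": "",
            **{k: getattr(full, k) for k in ("k", "X", "c", "f", "p_combined")},
            "delta_log10p": 0.0,
        }
    ]
    for name, removed in subsets.items():
        keep = [s for s in p_values.index if s not in set(removed)]
        if not keep:
            raise ValueError(f"sensitivity subset {name!r} removes every SNP")
        sub_ld = ld.submatrix(keep) if ld is not None else None
        res = brown_combine(
            p_values.loc[keep],
            sub_ld,
            flavor,
            directions.loc[keep] if directions is not None else None,
            group=group,
            cov_method=cov_method,
            rng=rng,
        )
        rows.append(
            {
                "subset": name,
                "removed": ",".join(s for s in p_values.index if s in set(removed)),
                **{k: getattr(res, k) for k in ("k", "X", "c", "f", "p_combined")},
                "delta_log10p": float(
                    -np.log10(res.p_combined) - (-np.log10(full.p_combined))
                ),
            }
        )
    return pd.DataFrame(rows)
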