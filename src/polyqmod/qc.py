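"""Per-SNP quality control.

The panel's only hard filter is departure from Hardy-Weinberg equilibrium
(exact test p < 0.001 computed on the whole pooled data set), a guard
against population stratification and genotyping artefacts. Call rate and
folded minor-allele frequency are reported for every SNP; an optional
minimum-call-rate filter is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeMatrix

__all__ = ["HweResult", "hwe_exact_test", "snp_qc", "HWE_THRESHOLD_DEFAULT"]

HWE_THRESHOLD_DEFAULT = 0.001


@dataclass(frozen=True)
class HweResult:
    """Genotype counts and the exact Hardy-Weinberg p-value for one SNP."""

    snp_id: str
    n_hom_effect: int
    n_het: int
    n_hom_other: int
    p_exact: float


def _log_het_probs(n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities of each attainable heterozygote count.

    Conditions on n diploid subjects carrying m copies of the minor allele;
    attainable heterozygote counts share the parity of m. Computed in log
    space via log-gamma and normalized, so counts into the hundreds of
    thousands are safe.
    """
    hs = np.arange(m % 2, min(m, 2 * n - m) + 1, 2)
    a = (m - hs) // 2          # minor-allele homozygotes
    b = n - a - hs             # major-allele homozygotes
    logp = (
        hs * np.log(2.0)
        - gammaln(a + 1)
        - gammaln(hs + 1)
        - gammaln(b + 1)
    )
    logp -= np.max(logp)
    p = np.exp(logp)
    p /= p.sum()
    return hs, p


def hwe_exact_test(n_hom_effect: int, n_het: int, n_hom_other: int) -> float:
    """Exact Hardy-Weinberg equilibrium test from genotype counts.

    Enumerates every heterozygote count attainable given the observed allele
    counts and sums the conditional probabilities of configurations no more
    probable than the observed one (no mid-p correction). Symmetric in the
    two homozygote classes; monomorphic SNPs return p = 1.
    """
    counts = (n_hom_effect, n_het, n_hom_other)
    if any(c < 0 for c in counts) or any(c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be nonnegative integers, got {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    m = min(2 * n_hom_effect + n_het, 2 * n_hom_other + n_het)
    if m == 0:
        return 1.0
    hs, probs = _log_het_probs(n, m)
    p_obs = probs[hs == n_het][0]
    # tolerance absorbs round-off so exactly-tied configurations are included
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def snp_qc(
    genotypes: GenotypeMatrix,
    hwe_threshold: float = HWE_THRESHOLD_DEFAULT,
    min_call_rate: float = 0.0,
) -> pd.DataFrame:
    """Per-SNP QC report over the whole pooled cohort.

    A SNP is excluded iff its exact HWE p-value is strictly below
    ``hwe_threshold`` (the study's rule; a p of exactly the threshold is
    retained), or its call rate falls below ``min_call_rate`` when that
    optional filter is enabled. SNPs with no calls at all are flagged
    degenerate and excluded.

    Returns a DataFrame indexed by snp_id with columns n_hom_effect, n_het,
    n_hom_other, call_rate, maf, hwe_p, excluded, reason.
    """
    rows = []
    dose = genotypes.dosage
    for sid in genotypes.snp_ids:
        d = dose[sid].dropna().to_numpy()
        n_obs = d.size
        call_rate = n_obs / dose.shape[0]
        if n_obs == 0:
            rows.append((sid, 0, 0, 0, 0.0, np.nan, np.nan, True, "no_calls"))
            continue
        n2 = int((d == 2).sum())
        n1 = int((d == 1).sum())
        n0 = int((d == 0).sum())
        f = (2 * n2 + n1) / (2 * n_obs)
        maf = min(f, 1 - f)
        p = hwe_exact_test(n2, n1, n0)
        excluded = False
        reason = ""
        if p < hwe_threshold:
            excluded = True
            reason = f"HWE<{hwe_threshold:g}"
        elif min_call_rate > 0 and call_rate < min_call_rate:
            excluded = True
            reason = f"call_rate<{min_call_rate:g}"
        rows.append((sid, n2, n1, n0, call_rate, maf, p, excluded, reason))
    report = pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "n_hom_effect",
            "n_het",
            "n_hom_other",
            "call_rate",
            "maf",
            "hwe_p",
            "excluded",
            "reason",
        ],
    ).set_index("snp_id", drop=False)
    return report
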