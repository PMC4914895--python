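"""Per-disease log-linear onset models and repeat-length-corrected
residual age at onset.

In every polyglutamine disease, longer expanded CAG tracts give earlier
onset, approximately log-linearly: ln(AAO) = A + B*CAG. Each disease gets
its own ordinary-least-squares fit; the fitted curve yields an expected
onset for each subject, and the residual (observed minus expected) is the
phenotype all downstream modifier analyses use.

Two residual scales are supported. The default, "years", subtracts the
back-transformed expectation exp(A + B*CAG) from the observed AAO in
years — the literal construction of an expected onset age. The "log"
option instead subtracts A + B*CAG from ln(AAO), the convention of the
reference GWAS. The two are rank-concordant whenever predictions are
positive; both are exposed and the choice is explicit everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OnsetModel",
    "fit_onset_model",
    "fit_all_onset_models",
    "residualize",
    "sex_effect_check",
]


@dataclass(frozen=True)
class OnsetModel:
    """Fitted ln(AAO) = A + B*CAG for one disease."""

    disease: str
    A: float
    B: float
    p_slope: float
    n: int
    r2: float

    def predicted_aao(self, cag: np.ndarray) -> np.ndarray:
        """Expected AAO in years at the given repeat lengths (plug-in
        back-transform, no log-normal bias correction)."""
        return np.exp(self.A + self.B * np.asarray(cag, dtype=float))


def fit_onset_model(phenotypes: pd.DataFrame) -> OnsetModel:
    """OLS of ln(AAO) on expanded repeat length for a single disease.

    Requires at least 3 subjects and a non-degenerate repeat distribution.
    ``p_slope`` is the two-sided t-test on the slope B.
    """
    diseases = phenotypes["disease"].unique()
    if len(diseases) != 1:
        raise ValueError(f"expected a single disease, got {list(diseases)}")
    y = np.log(phenotypes["aao_years"].to_numpy(dtype=float))
    x = phenotypes["cag_expanded"].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError(f"{diseases[0]}: need >=3 subjects to fit, got {len(y)}")
    if np.ptp(x) == 0:
        raise ValueError(f"{diseases[0]}: degenerate repeat distribution (zero CAG variance)")
    fit = stats.linregress(x, y)
    return OnsetModel(
        disease=str(diseases[0]),
        A=float(fit.intercept),
        B=float(fit.slope),
        p_slope=float(fit.pvalue),
        n=len(y),
        r2=float(fit.rvalue**2),
    )


def fit_all_onset_models(phenotypes: pd.DataFrame) -> dict[str, OnsetModel]:
    """Fit one onset model per disease present in the table."""
    return {
        str(d): fit_onset_model(sub)
        for d, sub in phenotypes.groupby("disease", sort=False)
    }


def residualize(
    phenotypes: pd.DataFrame,
    models: dict[str, OnsetModel],
    scale: str = "years",
) -> pd.DataFrame:
    """Residual AAO per subject given per-disease onset models.

    years scale: residual = AAO - exp(A + B*CAG)
    log scale:   residual = ln(AAO) - (A + B*CAG)

    Returns a DataFrame (subject_id, disease, residual) in phenotype order.
    """
    if scale not in ("years", "log"):
        raise ValueError(f"scale must be 'years' or 'log', got {scale!r}")
    unmodeled = sorted(set(phenotypes["disease"]) - set(models))
    if unmodeled:
        subjects = phenotypes.loc[
            phenotypes["disease"].isin(unmodeled), "subject_id"
        ].tolist()
        raise ValueError(
            f"no onset model for diseases {unmodeled}; affected subjects: {subjects[:10]}"
        )
    aao = phenotypes["aao_years"].to_numpy(dtype=float)
    cag = phenotypes["cag_expanded"].to_numpy(dtype=float)
    lin = np.array(
        [models[d].A + models[d].B * c for d, c in zip(phenotypes["disease"], cag)]
    )
    if scale == "years":
        resid = aao - np.exp(lin)
    else:
        resid = np.log(aao) - lin
    return pd.DataFrame(
        {
            "subject_id": phenotypes["subject_id"].to_numpy(),
            "disease": phenotypes["disease"].to_numpy(),
            "residual": resid,
        }
    )


def sex_effect_check(
    residuals: pd.DataFrame, phenotypes: pd.DataFrame
) -> pd.DataFrame:
    """Per-disease test of a sex effect on residual AAO.

    OLS of residual on a male indicator, two-sided slope p-value. The
    pipeline never adjusts for sex (the study tested it and found it
    nonsignificant in every disorder) — this is a reported diagnostic only.
    Groups without both sexes represented (>=2 subjects each) get NaN.
    """
    merged = residuals.merge(
        phenotypes[["subject_id", "sex"]], on="subject_id", how="left"
    )
    rows = []
    for d, sub in merged.groupby("disease", sort=False):
        known = sub[sub["sex"].isin(["M", "F"])]
        n_m = int((known["sex"] == "M").sum())
        n_f = int((known["sex"] == "F").sum())
        if n_m < 2 or n_f < 2:
            rows.append((d, n_m, n_f, np.nan))
            continue
        x = (known["sex"] == "M").to_numpy(dtype=float)
        y = known["residual"].to_numpy(dtype=float)
        if np.allclose(y - y.mean(), 0) or np.ptp(x) == 0:
            rows.append((d, n_m, n_f, 1.0))
            continue
        fit = stats.linregress(x, y)
        p = float(fit.pvalue) if np.isfinite(fit.pvalue) else 1.0
        rows.append((d, n_m, n_f, p))
    return pd.DataFrame(rows, columns=["disease", "n_male", "n_female", "p_sex"])
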