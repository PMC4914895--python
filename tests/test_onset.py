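"""Onset-law fitting, residual construction, sex diagnostic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyqmod.onset import (
    fit_all_onset_models,
    fit_onset_model,
    residualize,
    sex_effect_check,
)


def _pheno(cag, aao, disease="HD", sex=None):
    n = len(cag)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "disease": disease,
            "aao_years": aao,
            "cag_expanded": cag,
            "sex": sex if sex is not None else ["F"] * n,
        }
    )


class TestFit:
    def test_noise_free_data_fitted_exactly(self):
        cag = np.arange(40, 60)
        aao = np.exp(6.0 - 0.05 * cag)
        m = fit_onset_model(_pheno(cag, aao))
        assert m.A == pytest.approx(6.0, abs=1e-10)
        assert m.B == pytest.approx(-0.05, abs=1e-12)
        assert m.p_slope < 1e-100
        assert m.r2 == pytest.approx(1.0)
        resid = residualize(_pheno(cag, aao), {"HD": m}, "years")
        np.testing.assert_allclose(resid["residual"], 0.0, atol=1e-9)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            fit_onset_model(_pheno([40, 41], [50.0, 48.0]))

    def test_degenerate_repeat_distribution_rejected(self):
        with pytest.raises(ValueError, match="degenerate repeat"):
            fit_onset_model(_pheno([44] * 10, np.linspace(30, 60, 10)))


class TestResiduals:
    def test_years_residual_from_fitted_hd_law(self):
        # subject with CAG 40 and onset at 60 under the fitted HD law
        from polyqmod.onset import OnsetModel

        m = OnsetModel("HD", A=6.119939, B=-0.052966, p_slope=0.0, n=445, r2=0.5)
        pheno = _pheno([40], [60.0])
        resid = residualize(pheno, {"HD": m}, "years")
        expected = 60.0 - np.exp(6.119939 - 0.052966 * 40)
        assert resid["residual"].item() == pytest.approx(expected, abs=1e-12)
        log_resid = residualize(pheno, {"HD": m}, "log")
        assert log_resid["residual"].item() == pytest.approx(
            np.log(60.0) - (6.119939 - 0.052966 * 40), abs=1e-12
        )

    def test_log_residuals_sum_to_zero_per_disease(self, study_cohort):
        models = fit_all_onset_models(study_cohort.phenotypes)
        resid = residualize(study_cohort.phenotypes, models, "log")
        sums = resid.groupby("disease")["residual"].sum()
        np.testing.assert_allclose(sums, 0.0, atol=1e-8)

    def test_years_and_log_residuals_rank_concordant(self):
        # concordance holds when predicted onsets are positive and the
        # repeat spread is cohort-realistic (~1 SD around the mean); very
        # wide uniform CAG ranges decouple the two scales because the
        # years-scale residual is the log-scale one amplified by exp(pred)
        from polyqmod.simulate import OnsetParams, SimConfig, simulate_cohort

        cfg = SimConfig(
            n_per_disease={"HD": 800, "SCA3": 800},
            onset_params={
                "HD": OnsetParams(6.119939, -0.052966, 0.2),
                "SCA3": OnsetParams(7.137211, -0.049477, 0.2),
            },
            cag_range={"HD": (39, 49), "SCA3": (66, 76)},
            n_snps=2,
            ld_blocks=[(1, 0.0)] * 2,
            maf=0.3,
            effect_sizes=0.0,
            missing_rate=0.0,
            seed=31,
        )
        cohort = simulate_cohort(cfg)
        models = fit_all_onset_models(cohort.phenotypes)
        years = residualize(cohort.phenotypes, models, "years")
        log = residualize(cohort.phenotypes, models, "log")
        for d in ("HD", "SCA3"):
            a = years.loc[years["disease"] == d, "residual"]
            b = log.loc[log["disease"] == d, "residual"]
            rho = stats.spearmanr(a, b).statistic
            assert rho > 0.99

    def test_unmodeled_disease_raises_with_subjects(self, study_cohort):
        models = fit_all_onset_models(study_cohort.phenotypes)
        models.pop("SCA6")
        with pytest.raises(ValueError, match="SCA6"):
            residualize(study_cohort.phenotypes, models)

    def test_study_scale_slope_significance_pattern(self, study_cohort):
        # large disease groups pin the slope hard; the smallest (SCA17-sized,
        # weak positive true slope) does not reach that certainty
        models = fit_all_onset_models(study_cohort.phenotypes)
        for d in ("HD", "SCA1", "SCA2", "SCA3", "SCA7"):
            assert models[d].p_slope < 1e-10, d
        assert models["SCA17"].p_slope > 1e-6


class TestSexCheck:
    def test_null_sex_effect_p_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            n = 200
            sex = np.where(rng.random(n) < 0.5, "M", "F")
            resid = pd.DataFrame(
                {
                    "subject_id": [f"S{i}" for i in range(n)],
                    "disease": "HD",
                    "residual": rng.normal(0, 8, n),
                }
            )
            pheno = _pheno(
                rng.integers(40, 50, n), np.full(n, 45.0), sex=list(sex)
            )
            out = sex_effect_check(resid, pheno)
            pvals.append(out["p_sex"].item())
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_injected_sex_shift_detected(self):
        rng = np.random.default_rng(6)
        detected = 0
        reps = 100
        for _ in range(reps):
            n = 400
            sex = np.where(rng.random(n) < 0.5, "M", "F")
            resid_vals = rng.normal(0, 8, n) + np.where(sex == "F", 5.0, 0.0)
            resid = pd.DataFrame(
                {"subject_id": [f"S{i}" for i in range(n)], "disease": "HD",
                 "residual": resid_vals}
            )
            pheno = _pheno(rng.integers(40, 50, n), np.full(n, 45.0), sex=list(sex))
            if sex_effect_check(resid, pheno)["p_sex"].item() < 0.001:
                detected += 1
        assert detected / reps >= 0.95

    def test_single_sex_group_not_computable(self):
        resid = pd.DataFrame(
            {"subject_id": [f"S{i}" for i in range(10)], "disease": "HD",
             "residual": np.arange(10.0)}
        )
        pheno = _pheno(np.arange(40, 50), np.full(10, 45.0), sex=["M"] * 10)
        out = sex_effect_check(resid, pheno)
        assert np.isnan(out["p_sex"].item())

    def test_identical_residuals_across_sexes_gives_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        resid = pd.DataFrame(
            {"subject_id": [f"S{i}" for i in range(8)], "disease": "HD",
             "residual": vals + vals}
        )
        pheno = _pheno(
            np.arange(40, 48), np.full(8, 45.0), sex=["M"] * 4 + ["F"] * 4
        )
        out = sex_effect_check(resid, pheno)
        assert out["p_sex"].item() == pytest.approx(1.0)
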