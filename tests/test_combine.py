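"""Brown's method, LD matrices, Bonferroni tiers, sensitivity subsets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from polyqmod.combine import (
    LdMatrix,
    bonferroni_tiers,
    brown_combine,
    fisher_combine,
    high_ld_proxy_scan,
    kost_mcdermott_delta,
    ld_matrix,
    sensitivity_subsets,
)
from polyqmod.containers import GenotypeMatrix


def _identity_ld(k):
    ids = [f"s{i}" for i in range(k)]
    return LdMatrix(
        r=pd.DataFrame(np.eye(k), index=ids, columns=ids),
        n_pairs=pd.DataFrame(np.full((k, k), 1000), index=ids, columns=ids),
    )


def _equicorr_ld(k, rho):
    ids = [f"s{i}" for i in range(k)]
    r = np.full((k, k), float(rho))
    np.fill_diagonal(r, 1.0)
    return LdMatrix(
        r=pd.DataFrame(r, index=ids, columns=ids),
        n_pairs=pd.DataFrame(np.full((k, k), 1000), index=ids, columns=ids),
    )


def _series(p, ld):
    return pd.Series(np.asarray(p, dtype=float), index=ld.snp_ids[: len(p)])


class TestBrown:
    def test_reduces_to_fisher_with_identity_ld(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            k = int(rng.integers(2, 23))
            p = rng.uniform(1e-6, 1, k)
            ld = _identity_ld(k)
            got = brown_combine(_series(p, ld), ld, "two_sided").p_combined
            assert abs(got - fisher_combine(p)) < 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p=st.lists(
            st.floats(min_value=1e-10, max_value=1.0, allow_nan=False),
            min_size=2, max_size=22,
        )
    )
    def test_fisher_reduction_property(self, p):
        arr = np.asarray(p)
        ld = _identity_ld(arr.size)
        got = brown_combine(_series(arr, ld), ld, "two_sided").p_combined
        assert abs(got - fisher_combine(arr)) < 1e-12

    def test_frozen_two_test_closed_form(self):
        # k=2 independent, p=(1/2, 1/2): X = -2 ln(1/4) = 2.772589,
        # chi2_4 survival = exp(-X/2)*(1+X/2) = 0.59657...
        ld = _identity_ld(2)
        res = brown_combine(_series([0.5, 0.5], ld), ld, "two_sided")
        assert res.X == pytest.approx(2.772588722239781, abs=1e-12)
        assert res.p_combined == pytest.approx(0.5965735902799727, abs=1e-12)

    def test_boundary_all_ones(self):
        ld = _equicorr_ld(2, 0.9)
        res = brown_combine(
            _series([1.0, 1.0], ld), ld, "one_sided", _series([1, 1], ld)
        )
        assert res.X == 0.0
        assert res.p_combined == pytest.approx(1.0)

    def test_single_test_returns_input(self):
        res = brown_combine(np.array([0.0317]), None, "two_sided")
        assert res.p_combined == pytest.approx(0.0317)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [-0.1, 0.5]])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(ValueError):
            brown_combine(np.asarray(bad), None, "two_sided")

    def test_monotone_in_each_input_p(self):
        ld = _equicorr_ld(3, 0.5)
        d = _series([1, 1, 1], ld)
        base = np.array([0.3, 0.5, 0.7])
        prev = brown_combine(_series(base, ld), ld, "one_sided", d)
        for p0 in (0.2, 0.1, 0.01, 1e-6):
            cur = brown_combine(
                _series([p0, 0.5, 0.7], ld), ld, "one_sided", d
            )
            assert cur.X >= prev.X
            assert cur.p_combined <= prev.p_combined
            prev = cur

    def test_mc_covariance_agrees_with_polynomial(self):
        ld = _equicorr_ld(4, 0.7)
        d = _series([1, 1, -1, -1], ld)
        p = _series([0.05, 0.2, 0.4, 0.6], ld)
        poly = brown_combine(p, ld, "one_sided", d)
        mc = brown_combine(
            p, ld, "one_sided", d, cov_method="montecarlo",
            rng=np.random.default_rng(5),
        )
        assert mc.p_combined == pytest.approx(poly.p_combined, abs=0.01)

    def test_missing_ld_entries_fall_back_to_independence(self):
        ids = ["a", "b"]
        r = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]], index=ids, columns=ids)
        ld = LdMatrix(r=r, n_pairs=pd.DataFrame(np.full((2, 2), 3), index=ids, columns=ids))
        res = brown_combine(pd.Series([0.1, 0.2], index=ids), ld, "two_sided")
        assert res.n_missing_ld == 1
        assert res.p_combined == pytest.approx(fisher_combine([0.1, 0.2]), abs=1e-12)


def test_delta_negative_branch_matches_exact_anchor():
    # at rho = -1 the exact covariance of -2 ln p for one-sided normal
    # p-values is 4 - 2*pi^2/3
    exact = 4 - 2 * np.pi**2 / 3
    assert kost_mcdermott_delta(-1.0) == pytest.approx(exact, abs=0.03)
    assert kost_mcdermott_delta(1.0) == pytest.approx(4.0, abs=0.03)


class TestLdMatrix:
    def test_duplicated_column_gives_unit_correlation(self, small_cohort):
        ld = ld_matrix(small_cohort.genotypes)
        # first two SNPs are a perfect-LD block
        s0, s1 = small_cohort.genotypes.snp_ids[:2]
        assert ld.r.loc[s0, s1] == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(17)
        d = rng.integers(0, 3, size=(5000, 2)).astype(float)
        geno = GenotypeMatrix(
            dosage=pd.DataFrame(d, index=[f"S{i}" for i in range(5000)], columns=["a", "b"]),
            effect_allele=pd.Series("A", index=["a", "b"]),
            other_allele=pd.Series("G", index=["a", "b"]),
        )
        ld = ld_matrix(geno)
        assert abs(ld.r.loc["a", "b"]) < 0.05

    def test_sparse_overlap_set_missing(self):
        d = np.full((20, 2), np.nan)
        d[:10, 0] = [0, 1, 2, 1, 0, 1, 2, 0, 1, 2]
        d[12:, 1] = [0, 1, 2, 1, 0, 1, 2, 0]
        geno = GenotypeMatrix(
            dosage=pd.DataFrame(d, index=[f"S{i}" for i in range(20)], columns=["a", "b"]),
            effect_allele=pd.Series("A", index=["a", "b"]),
            other_allele=pd.Series("G", index=["a", "b"]),
        )
        ld = ld_matrix(geno)
        assert np.isnan(ld.r.loc["a", "b"])


class TestProxyScan:
    def test_perfect_block_of_three_yields_three_pairs(self):
        ld = _equicorr_ld(3, 1.0)
        pairs = high_ld_proxy_scan(ld, 0.8)
        assert len(pairs) == 3

    def test_independent_panel_empty(self):
        assert len(high_ld_proxy_scan(_identity_ld(5), 0.8)) == 0

    def test_zero_threshold_returns_all_pairs(self):
        ld = _equicorr_ld(4, 0.2)
        assert len(high_ld_proxy_scan(ld, 0.0)) == 6

    def test_study_panel_proxy_block_flagged(self, study_cohort):
        ld = ld_matrix(study_cohort.genotypes)
        pairs = high_ld_proxy_scan(ld, 0.8)
        block = set(study_cohort.genotypes.snp_ids[:3])
        assert len(pairs) >= 3
        assert set(pairs["snp_a"]).union(pairs["snp_b"]) >= block


class TestBonferroni:
    def test_printed_thresholds_at_three_figures(self):
        tiers = bonferroni_tiers(22, 8)
        assert tiers["tier1_3sf"] == pytest.approx(2.84e-4)
        assert tiers["tier2_3sf"] == pytest.approx(2.27e-3)

    def test_single_test_threshold(self):
        assert bonferroni_tiers(1, 1)["tier1"] == pytest.approx(0.05)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_tiers(0, 8)


class TestSensitivity:
    def test_full_panel_subset_is_identity(self):
        ld = _equicorr_ld(4, 0.3)
        p = _series([0.01, 0.2, 0.5, 0.9], ld)
        d = _series([1, 1, 1, 1], ld)
        out = sensitivity_subsets(p, ld, {"none_removed": []}, "one_sided", d)
        full = out[out["subset"] == "full_panel"].iloc[0]
        sub = out[out["subset"] == "none_removed"].iloc[0]
        assert sub["p_combined"] == pytest.approx(full["p_combined"], abs=1e-15)
        assert sub["delta_log10p"] == pytest.approx(0.0, abs=1e-12)

    def test_removing_every_snp_rejected(self):
        ld = _equicorr_ld(2, 0.0)
        p = _series([0.1, 0.2], ld)
        with pytest.raises(ValueError, match="every SNP"):
            sensitivity_subsets(p, ld, {"all": ["s0", "s1"]}, "two_sided")

    def test_removing_signal_vs_null_snp(self):
        # one strong SNP among nulls: dropping a null concentrates the
        # signal; dropping the signal SNP pushes the combination to null
        rng = np.random.default_rng(23)
        reps = 200
        k = 6
        ld = _identity_ld(k)
        d = _series([1] * k, ld)
        p_keep, p_drop_signal, p_drop_null = [], [], []
        for _ in range(reps):
            z = rng.standard_normal(k)
            z[0] += 3.0  # aligned signal at the first SNP
            p = pd.Series(np.clip(stats.norm.sf(z), 1e-300, 1), index=ld.snp_ids)
            out = sensitivity_subsets(
                p, ld, {"no_signal": ["s0"], "no_null": ["s5"]}, "one_sided", d
            ).set_index("subset")["p_combined"]
            p_keep.append(out["full_panel"])
            p_drop_signal.append(out["no_signal"])
            p_drop_null.append(out["no_null"])
        assert np.median(p_drop_signal) > np.median(p_keep)
        assert np.median(p_drop_null) <= np.median(p_keep) * 1.5
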