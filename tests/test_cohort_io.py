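"""Cohort I/O: round trips, allele harmonization, row validation."""

import numpy as np
import pandas as pd
import pytest

from polyqmod.cohort_io import (
    Orientation,
    harmonize_alleles,
    read_genotypes,
    read_phenotypes,
    read_priors,
    write_dosage_tsv,
    write_phenotypes,
    write_priors,
    write_vcf,
)
from polyqmod.containers import CohortError, SnpPrior


def _prior(effect="C", other="T", snp_id="rs1"):
    return SnpPrior(
        snp_id=snp_id, gene="G1", effect_allele=effect, other_allele=other,
        gem_direction=1, gem_weight_years=1.4,
    )


class TestHarmonize:
    @pytest.mark.parametrize(
        "observed,effect,other,action,flip",
        [
            (("T", "C"), "C", "T", Orientation.KEEP, False),       # ALT is effect
            (("C", "T"), "C", "T", Orientation.KEEP, True),        # ALT is other
            (("A", "G"), "C", "T", Orientation.COMPLEMENT, False), # comp(G)=C=effect
            (("G", "A"), "C", "T", Orientation.COMPLEMENT, True),  # comp(A)=T=other
        ],
    )
    def test_orientation_resolution(self, observed, effect, other, action, flip):
        got_action, got_flip = harmonize_alleles(observed, _prior(effect, other))
        assert got_action is action
        assert got_flip is flip

    @pytest.mark.parametrize("observed", [("A", "T"), ("T", "A"), ("C", "G")])
    def test_strand_ambiguous_pairs_fail(self, observed):
        prior = SnpPrior(
            snp_id="rs2", gene="G", effect_allele=observed[0],
            other_allele=observed[1], gem_direction=-1, gem_weight_years=-6.0,
        )
        action, _ = harmonize_alleles(observed, prior)
        assert action is Orientation.FAIL

    def test_irreconcilable_alleles_fail(self):
        action, _ = harmonize_alleles(("A", "C"), _prior("C", "T"))
        assert action is Orientation.FAIL

    def test_resolution_is_idempotent_on_dosage(self):
        # once harmonized to the prior orientation, re-harmonizing changes nothing
        prior = _prior("C", "T")
        _, flip1 = harmonize_alleles(("T", "C"), prior)
        assert not flip1
        _, flip2 = harmonize_alleles((prior.other_allele, prior.effect_allele), prior)
        assert not flip2


class TestRoundTrips:
    def test_dosage_tsv_round_trip(self, small_cohort, tmp_path):
        geno = small_cohort.genotypes
        write_dosage_tsv(geno, tmp_path / "g.tsv")
        write_priors(small_cohort.priors, tmp_path / "p.tsv")
        back = read_genotypes(tmp_path / "g.tsv", "dosage-tsv", read_priors(tmp_path / "p.tsv"))
        pd.testing.assert_frame_equal(back.dosage, geno.dosage, check_names=False)

    def test_vcf_round_trip(self, small_cohort, tmp_path):
        geno = small_cohort.genotypes
        write_vcf(geno, tmp_path / "g.vcf")
        back = read_genotypes(tmp_path / "g.vcf", "vcf", small_cohort.priors)
        pd.testing.assert_frame_equal(back.dosage, geno.dosage, check_names=False)
        pd.testing.assert_series_equal(back.effect_allele, geno.effect_allele)

    def test_phenotype_round_trip(self, small_cohort, tmp_path):
        write_phenotypes(small_cohort.phenotypes, tmp_path / "ph.tsv")
        back = read_phenotypes(tmp_path / "ph.tsv")
        pd.testing.assert_frame_equal(
            back, small_cohort.phenotypes, check_dtype=False
        )


VCF_TEXT = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t1\trs_alt_eff\tT\tC\t.\tPASS\t.\tGT\t0/1\t1/1\t./.
1\t2\trs_ref_eff\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/0\t0/1
"""


def test_vcf_dosage_counts_effect_allele(tmp_path):
    path = tmp_path / "two.vcf"
    path.write_text(VCF_TEXT)
    priors_df = pd.DataFrame(
        {
            "snp_id": ["rs_alt_eff", "rs_ref_eff"],
            "gene": ["A", "B"],
            "effect_allele": ["C", "C"],
            "other_allele": ["T", "T"],
            "gem_direction": [1, 1],
            "gem_weight_years": [1.0, 1.0],
            "gem_p": [np.nan, np.nan],
            "strand_flag": ["forward", "forward"],
        }
    ).set_index("snp_id", drop=False)
    geno = read_genotypes(path, "vcf", priors_df)
    # ALT is the effect allele: het -> 1, hom-alt -> 2-ish, ./. -> missing
    assert geno.dosage.loc["S1", "rs_alt_eff"] == 1
    assert geno.dosage.loc["S2", "rs_alt_eff"] == 2
    assert np.isnan(geno.dosage.loc["S3", "rs_alt_eff"])
    # REF is the effect allele: hom-ALT means zero effect alleles
    assert geno.dosage.loc["S1", "rs_ref_eff"] == 0
    assert geno.dosage.loc["S2", "rs_ref_eff"] == 2
    assert geno.dosage.loc["S3", "rs_ref_eff"] == 1


def test_snp_absent_from_priors_dropped(tmp_path, small_cohort):
    geno = small_cohort.genotypes
    write_vcf(geno, tmp_path / "g.vcf")
    pruned = small_cohort.priors.drop(index=geno.snp_ids[0])
    back = read_genotypes(tmp_path / "g.vcf", "vcf", pruned)
    assert geno.snp_ids[0] not in back.snp_ids
    assert back.n_snps == geno.n_snps - 1


class TestPhenotypeValidation:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["subject_id", "disease", "aao_years", "cag_expanded", "sex"]
        )

    def test_valid_and_invalid_rows(self, tmp_path):
        df = self._table(
            [
                ("S1", "HD", 45, 44, "M"),
                ("S2", "SCA8", 30, 80, "F"),   # not a panel disease
                ("S3", "SCA2", 0, 40, "F"),    # non-positive onset
                ("S4", "SCA6", 55, 22, None),  # missing sex tolerated
            ]
        )
        path = tmp_path / "ph.tsv"
        df.to_csv(path, sep="\t", index=False)
        out = read_phenotypes(path)
        assert list(out["subject_id"]) == ["S1", "S4"]
        assert out.attrs["n_rejected"] == 2
        assert out.loc[out["subject_id"] == "S4", "sex"].item() == "unknown"

    def test_duplicate_subjects_rejected(self):
        from polyqmod.containers import validate_phenotypes

        df = self._table([("S1", "HD", 45, 44, "M"), ("S1", "HD", 50, 42, "F")])
        with pytest.raises(CohortError, match="duplicated"):
            validate_phenotypes(df)


def test_prior_sign_consistency_enforced():
    with pytest.raises(CohortError, match="disagrees"):
        SnpPrior(
            snp_id="rs9", gene="G", effect_allele="A", other_allele="G",
            gem_direction=1, gem_weight_years=-2.0,
        )
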