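"""Genotype loading, QC filtering, imputation, and the stratified split."""

import numpy as np
import pandas as pd
import pytest
from conftest import write_toy_vcf

from gruyere.cohort import (
    impute_missing,
    load_covariates,
    load_genotypes,
    minmax_scale_columns,
    qc_filter,
    split_train_test,
)
from gruyere.datatypes import CohortData, GenotypeBlock


def _block(G, maf=None, sample_prefix="S"):
    G = np.asarray(G, float)
    n, p = G.shape
    if maf is None:
        maf = np.nanmean(G, axis=0) / 2
    return GenotypeBlock(
        [f"v{j}" for j in range(p)], ["1"] * p, np.arange(1, p + 1), ["A"] * p,
        ["T"] * p, G, np.asarray(maf, float), [f"{sample_prefix}{i}" for i in range(n)],
    )


class TestLoadGenotypes:
    def test_maf_filter_on_toy_vcf(self, tmp_path):
        # 50 samples; alt-allele counts give MAFs 0.01, 0.04, 0.20
        n = 50

        def gts(n_het):
            return ["0/1"] * n_het + ["0/0"] * (n - n_het)

        vcf = write_toy_vcf(
            tmp_path / "toy.vcf",
            [(100, "A", "T", gts(1)), (200, "C", "G", gts(4)), (300, "G", "A", gts(20))],
            n,
        )
        block = load_genotypes(str(vcf), "vcf", maf_max=0.05)
        assert block.n_variants == 2
        assert np.allclose(block.maf, [0.01, 0.04])

    def test_monomorphic_site_retained(self, tmp_path):
        vcf = write_toy_vcf(tmp_path / "m.vcf", [(5, "A", "T", ["0/0"] * 10)], 10)
        block = load_genotypes(str(vcf), "vcf")
        assert block.n_variants == 1 and block.maf[0] == 0.0

    def test_multiallelic_dropped(self, tmp_path):
        vcf = write_toy_vcf(
            tmp_path / "tri.vcf",
            [(5, "A", "T,G", ["0/0"] * 10), (9, "A", "T", ["0/1"] + ["0/0"] * 9)],
            10,
        )
        block = load_genotypes(str(vcf), "vcf")
        assert block.variant_ids == ["1:9:A:T"]

    def test_minor_allele_orientation(self, tmp_path):
        # alt is the major allele (AF 0.9): dosages must be flipped
        vcf = write_toy_vcf(
            tmp_path / "flip.vcf", [(7, "A", "T", ["1/1"] * 9 + ["0/1"])], 10
        )
        block = load_genotypes(str(vcf), "vcf", maf_max=0.5)
        assert block.maf[0] == pytest.approx(0.05)
        assert block.G[:, 0].sum() == pytest.approx(1.0)  # one reference allele

    def test_dosage_text_roundtrip(self, tmp_path):
        f = tmp_path / "d.txt"
        f.write_text(
            "sample_id 1:10:A:T 1:20:C:G\nS0 0 1\nS1 NA 2\nS2 1 0\n"
        )
        block = load_genotypes(str(f), "dosage", maf_max=0.5)
        assert block.n_variants == 2
        assert np.isnan(block.G[1, 0])
        assert block.positions.tolist() == [10, 20]

    def test_bad_dosage_reports_line(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("sample_id v1\nS0 0\nS1 7\n")
        with pytest.raises(ValueError, match="line 3"):
            load_genotypes(str(f), "dosage")

    def test_all_filtered_warns_not_raises(self, tmp_path):
        vcf = write_toy_vcf(
            tmp_path / "c.vcf", [(5, "A", "T", ["0/1"] * 5 + ["0/0"] * 5)], 10
        )
        with pytest.warns(UserWarning, match="empty"):
            block = load_genotypes(str(vcf), "vcf", maf_max=0.01)
        assert block.n_variants == 0


class TestQcFilter:
    def test_sample_then_variant_removal(self):
        G = np.zeros((10, 10))
        G[0, :3] = np.nan  # sample 0: 30% missing
        block, _ = qc_filter(_block(G), sample_missing_max=0.10)
        assert block.n_samples == 9
        assert block.n_variants == 10  # call rates rebound after sample removal

    def test_low_callrate_variant_removed(self):
        # 20 variants so per-sample missingness stays below the sample filter
        G = np.zeros((20, 20))
        G[:3, 1] = np.nan  # variant 1: 85% call rate
        block, _ = qc_filter(_block(G), variant_callrate_min=0.90)
        assert "v1" not in block.variant_ids and block.n_variants == 19

    def test_planted_missingness_matches_mask_oracle(self, rng):
        G = rng.binomial(2, 0.05, size=(20, 50)).astype(float)
        miss = rng.random((20, 50)) < 0.08
        G[miss] = np.nan
        smax, cmin = 0.10, 0.90
        block, _ = qc_filter(_block(G), sample_missing_max=smax, variant_callrate_min=cmin)
        # brute-force oracle on the raw mask
        keep_s = np.isnan(G).mean(axis=1) <= smax
        keep_v = (~np.isnan(G[keep_s])).mean(axis=0) >= cmin
        assert block.n_samples == keep_s.sum()
        assert block.n_variants == keep_v.sum()

    def test_idempotent(self, rng):
        # realistic pattern: low background missingness plus a few clearly bad
        # samples and variants, so thresholds are not straddled
        G = rng.binomial(2, 0.05, size=(30, 20)).astype(float)
        G[rng.random((30, 20)) < 0.01] = np.nan
        G[:2, ::2] = np.nan  # two bad samples (50% missing)
        G[2:, 5] = np.nan  # one bad variant
        once, _ = qc_filter(_block(G))
        twice, _ = qc_filter(once)
        assert once.variant_ids == twice.variant_ids
        assert once.sample_ids == twice.sample_ids

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            qc_filter(_block(np.zeros((4, 4))), sample_missing_max=0.0)
        with pytest.raises(ValueError):
            qc_filter(_block(np.zeros((4, 4))), variant_callrate_min=1.5)

    def test_cohort_rows_follow_samples(self):
        G = np.zeros((5, 4))
        G[2, :] = np.nan
        cohort = CohortData([f"S{i}" for i in range(5)], np.array([0, 1, 0, 1, 0]),
                            np.linspace(0, 1, 5)[:, None], ["c"])
        block, new_cohort = qc_filter(_block(G), cohort)
        assert new_cohort.sample_ids == ["S0", "S1", "S3", "S4"]
        assert new_cohort.Y.tolist() == [0, 1, 1, 0]


class TestImpute:
    def test_expected_dosage_is_twice_maf(self):
        G = np.array([[0.0], [np.nan], [0.0]])
        block = _block(G, maf=[0.02])
        out = impute_missing(block)
        assert out.G[1, 0] == pytest.approx(0.04)

    def test_maf_mode(self):
        G = np.array([[0.0], [np.nan]])
        out = impute_missing(_block(G, maf=[0.02]), mode="maf")
        assert out.G[1, 0] == pytest.approx(0.02)

    def test_zero_maf_imputes_zero(self):
        out = impute_missing(_block(np.array([[0.0], [np.nan]]), maf=[0.0]))
        assert out.G[1, 0] == 0.0

    def test_no_missing_identity(self, rng):
        G = rng.binomial(2, 0.03, size=(10, 5)).astype(float)
        block = _block(G)
        out = impute_missing(block)
        assert out is block  # bit-identical passthrough

    def test_undefined_maf_errors(self):
        G = np.full((3, 1), np.nan)
        with pytest.raises(ValueError, match="zero observed calls"):
            impute_missing(_block(G, maf=[np.nan]))

    def test_allele_frequency_preserved(self, rng):
        G = rng.binomial(2, 0.04, size=(200, 8)).astype(float)
        G[rng.random((200, 8)) < 0.05] = np.nan
        maf_before = np.nanmean(G, axis=0) / 2
        out = impute_missing(_block(G, maf=maf_before))
        assert np.allclose(out.G.mean(axis=0) / 2, maf_before, atol=1e-12)


class TestSplit:
    def _cohort(self, n, ancestry=None):
        return CohortData([f"S{i}" for i in range(n)], np.zeros(n, dtype=int),
                          np.linspace(0, 1, n)[:, None], ["c"],
                          ancestry=None if ancestry is None else np.asarray(ancestry))

    def test_single_stratum_counts(self):
        out = split_train_test(self._cohort(100), 0.8, seed=7)
        assert (out.split == "train").sum() == 80

    def test_per_stratum_rounding(self):
        ancestry = ["EUR"] * 60 + ["AFR"] * 40
        out = split_train_test(self._cohort(100, ancestry), 0.8, seed=7)
        for grp, expect in (("EUR", 48), ("AFR", 32)):
            assert ((out.split == "train") & (out.ancestry == grp)).sum() == expect

    def test_deterministic_and_partition(self):
        a = split_train_test(self._cohort(50), 0.8, seed=3)
        b = split_train_test(self._cohort(50), 0.8, seed=3)
        assert (a.split == b.split).all()
        assert set(np.unique(a.split)) == {"train", "test"}

    def test_tiny_stratum_goes_to_train(self):
        ancestry = ["EUR"] * 10 + ["EAS"]
        with pytest.warns(UserWarning, match="wholly in train"):
            out = split_train_test(self._cohort(11, ancestry), 0.8, seed=1)
        assert out.split[10] == "train"

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_train_test(self._cohort(10), 1.0, seed=0)


class TestCovariates:
    def test_minmax_scaling_and_constant_column(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0], "icpt": [1.0, 1.0, 1.0]})
        out = minmax_scale_columns(df)
        assert out["a"].tolist() == [0.0, 0.5, 1.0]
        assert out["icpt"].tolist() == [1.0, 1.0, 1.0]
        with pytest.raises(ValueError):
            minmax_scale_columns(pd.DataFrame({"bad": [7.0, 7.0]}))

    def test_load_covariates_roundtrip(self, tmp_path):
        f = tmp_path / "cov.tsv"
        pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "phenotype": [0, 1, 0],
             "age": [60, 70, 80], "pop": ["EUR", "AFR", "EUR"]}
        ).to_csv(f, sep="\t", index=False)
        cohort = load_covariates(str(f), ancestry_col="pop")
        assert cohort.Y.tolist() == [0, 1, 0]
        assert cohort.X.min() >= 0 and cohort.X.max() <= 1
        assert cohort.ancestry.tolist() == ["EUR", "AFR", "EUR"]
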