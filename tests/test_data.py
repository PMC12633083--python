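"""I/O, harmonization, QC, PRS scoring and treatment coding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlearner.data import (
    GenotypeMatrix,
    ScoringFile,
    SummaryStats,
    SumstatsFormatError,
    VariantRecord,
    harmonize_variants,
    qc_filter_variants,
    read_scoring_file,
    read_sumstats,
    score_prs,
    standardize_treatment,
    write_sumstats,
)


def rec(vid, a1="A", a2="G", z=1.0, n=1000, **kw):
    return VariantRecord(variant_id=vid, allele_effect=a1, allele_other=a2,
                         z=z, n=n, **kw)


class TestReadSumstats:
    def test_parses_z_column(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("SNP\tA1\tA2\tZ\tN\nrs1\tA\tG\t1.5\t1000\n"
                     "rs2\tC\tG\t-0.2\t1000\nrs3\tA\tC\t0.0\t999\n")
        ss = read_sumstats(f, kind="gwis_interaction")
        assert len(ss) == 3
        assert ss.z.tolist() == [1.5, -0.2, 0.0]
        assert ss.variant_ids == ["rs1", "rs2", "rs3"]  # row order preserved

    def test_derives_z_from_beta_se(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("SNP A1 A2 BETA SE N\nrs1 A G 0.2 0.1 500\n")
        ss = read_sumstats(f, kind="gwas_marginal")
        assert ss.records[0].z == pytest.approx(2.0)

    def test_invalid_allele_names_line(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("SNP\tA1\tA2\tZ\tN\nrs1\tAT\tG\t1.0\t100\n")
        with pytest.raises(SumstatsFormatError, match="line 2"):
            read_sumstats(f, kind="gwas_marginal")

    def test_missing_mandatory_column(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("SNP\tA1\tZ\tN\nrs1\tA\t1.0\t100\n")
        with pytest.raises(SumstatsFormatError, match="allele_other"):
            read_sumstats(f, kind="gwas_marginal")

    def test_non_numeric_z_names_line(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("SNP\tA1\tA2\tZ\tN\nrs1\tA\tG\t1.0\t100\nrs2\tA\tG\txx\t100\n")
        with pytest.raises(SumstatsFormatError, match="line 3"):
            read_sumstats(f, kind="gwas_marginal")

    def test_round_trip_bit_exact(self, tmp_path):
        records = [
            rec("rs1", z=0.1234567890123, maf=0.21, info=0.97),
            rec("rs2", "C", "T", z=-2.5, n=77, maf=0.05, info=0.91),
        ]
        ss = SummaryStats(records=records, kind="gwis_interaction", trait_label="t")
        path = tmp_path / "out.tsv"
        write_sumstats(ss, path)
        back = read_sumstats(path, kind="gwis_interaction", trait_label="t")
        for a, b in zip(ss.records, back.records):
            assert a.variant_id == b.variant_id
            assert a.allele_effect == b.allele_effect
            assert a.z == b.z and a.maf == b.maf and a.info == b.info
            assert a.n == b.n


class TestVariantRecord:
    def test_z_beta_se_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            rec("rs1", z=1.0, beta=0.2, se=0.1)

    def test_alleles_must_differ(self):
        with pytest.raises(ValueError):
            rec("rs1", a1="A", a2="A")


class TestHarmonize:
    def test_identity_case(self):
        ref = SummaryStats([rec("rs1"), rec("rs2", "C", "T", z=2.0)],
                           "gwis_interaction")
        other = SummaryStats([rec("rs1", z=0.5), rec("rs2", "C", "T", z=-1.0)],
                             "gwas_marginal")
        pairs = harmonize_variants(ref, other)
        assert len(pairs) == 2
        assert pairs.z_other.tolist() == [0.5, -1.0]
        assert pairs.n_flipped == 0

    def test_swapped_alleles_flip_sign(self):
        ref = SummaryStats([rec("rs1", "A", "G", z=1.0)], "gwis_interaction")
        other = SummaryStats([rec("rs1", "G", "A", z=1.5)], "gwas_marginal")
        pairs = harmonize_variants(ref, other)
        assert pairs.z_other.tolist() == [-1.5]
        assert pairs.n_flipped == 1
        assert pairs.other[0].allele_effect == "A"

    def test_palindromic_dropped(self):
        ref = SummaryStats([rec("rs1", "A", "T"), rec("rs2", "A", "G")],
                           "gwis_interaction")
        other = SummaryStats([rec("rs1", "A", "T", z=2.0), rec("rs2", z=1.0)],
                             "gwas_marginal")
        pairs = harmonize_variants(ref, other)
        assert len(pairs) == 1
        assert pairs.n_dropped_palindromic == 1

    def test_mismatch_dropped_with_count(self):
        ref = SummaryStats([rec("rs1", "A", "G"), rec("rs2", "A", "C")],
                           "gwis_interaction")
        other = SummaryStats([rec("rs1", "A", "C", z=2.0), rec("rs2", "A", "C")],
                             "gwas_marginal")
        pairs = harmonize_variants(ref, other)
        assert len(pairs) == 1 and pairs.n_dropped_mismatch == 1

    def test_idempotent(self):
        ref = SummaryStats([rec("rs1"), rec("rs2", "C", "T", z=-0.7)],
                           "gwis_interaction")
        other = SummaryStats([rec("rs1", "G", "A", z=1.5), rec("rs2", "C", "T")],
                             "gwas_marginal")
        once = harmonize_variants(ref, other)
        again = harmonize_variants(
            ref, SummaryStats(once.other, "gwas_marginal"))
        assert again.n_flipped == 0
        assert np.array_equal(once.z_other, again.z_other)

    def test_empty_intersection_errors(self):
        ref = SummaryStats([rec("rs1")], "gwis_interaction")
        other = SummaryStats([rec("rs9")], "gwas_marginal")
        with pytest.raises(ValueError, match="no harmonizable"):
            harmonize_variants(ref, other)


class TestQcFilter:
    def full(self, vid, **kw):
        base = dict(maf=0.2, info=0.95, missing_rate=0.0, hwe_p=0.5)
        base.update(kw)
        return rec(vid, **base)

    def test_passing_record_kept(self):
        kept, counts = qc_filter_variants([self.full("rs1")])
        assert len(kept) == 1 and counts.n_kept == 1

    def test_low_info_dropped(self):
        kept, counts = qc_filter_variants([self.full("rs1", info=0.85)])
        assert kept == [] and counts.n_failed_info == 1

    def test_toy_list_three_survivors(self):
        # five records, two each violating exactly one rule:
        # rs2 fails MAF (0.04 < 0.05), rs4 fails HWE (1e-7 < 1e-6)
        records = [
            self.full("rs1"),
            self.full("rs2", maf=0.04),
            self.full("rs3"),
            self.full("rs4", hwe_p=1e-7),
            self.full("rs5"),
        ]
        kept, counts = qc_filter_variants(records)
        assert [r.variant_id for r in kept] == ["rs1", "rs3", "rs5"]
        assert counts.n_failed_maf == 1 and counts.n_failed_hwe == 1

    def test_missing_field_policy(self):
        r = rec("rs1", maf=0.2)  # info/missing/hwe absent
        strict, _ = qc_filter_variants([r])
        permissive, _ = qc_filter_variants([r], permissive_missing_fields=True)
        assert strict == [] and len(permissive) == 1


class TestScorePrs:
    def make_gm(self, dosages, ids=None):
        dosages = np.asarray(dosages, dtype=float)
        ids = ids or [f"rs{j}" for j in range(dosages.shape[1])]
        return GenotypeMatrix(dosages=dosages, variant_ids=ids)

    def test_zero_weights_zero_scores(self):
        gm = self.make_gm([[0, 1], [2, 2]])
        sf = ScoringFile([("rs0", "A", 0.0), ("rs1", "A", 0.0)])
        assert score_prs(gm, sf).tolist() == [0.0, 0.0]

    def test_single_variant_arithmetic(self):
        gm = self.make_gm([[2.0]])
        sf = ScoringFile([("rs0", "A", 0.5)])
        assert score_prs(gm, sf).tolist() == [1.0]

    def test_standardized_output(self):
        rng = np.random.default_rng(0)
        gm = self.make_gm(rng.integers(0, 3, size=(50, 4)))
        sf = ScoringFile([(f"rs{j}", "A", w) for j, w in
                          enumerate([0.5, -1.0, 0.2, 0.9])])
        s = score_prs(gm, sf, standardize_output=True)
        assert abs(s.mean()) < 1e-8 and abs(s.var() - 1.0) < 1e-8

    def test_no_matches_errors(self):
        gm = self.make_gm([[1.0]])
        sf = ScoringFile([("rsX", "A", 1.0)])
        with pytest.raises(ValueError, match="0 of 1"):
            score_prs(gm, sf)

    def test_mean_imputation_of_missing_dosages(self):
        gm = self.make_gm([[np.nan], [1.0], [2.0]])
        sf = ScoringFile([("rs0", "A", 1.0)])
        assert score_prs(gm, sf).tolist() == [1.5, 1.0, 2.0]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(2, 20), st.integers(1, 20), st.integers(0, 10**6))
    def test_matches_brute_force_double_loop(self, n, j, seed):
        rng = np.random.default_rng(seed)
        dosages = rng.integers(0, 3, size=(n, j)).astype(float)
        weights = rng.normal(size=j)
        gm = self.make_gm(dosages)
        sf = ScoringFile([(f"rs{k}", "A", float(weights[k])) for k in range(j)])
        expected = np.zeros(n)
        for i in range(n):
            for k in range(j):
                expected[i] += dosages[i, k] * weights[k]
        np.testing.assert_allclose(score_prs(gm, sf), expected, atol=1e-12)

    def test_read_scoring_file_skips_comments(self, tmp_path):
        f = tmp_path / "pgs.txt"
        f.write_text("# PGS Catalog style header\n"
                     "rsID\teffect_allele\teffect_weight\nrs1\tA\t0.3\n")
        sf = read_scoring_file(f)
        assert sf.entries == [("rs1", "A", 0.3)]


class TestStandardizeTreatment:
    def test_symmetric_at_half(self):
        out = standardize_treatment(np.array([1.0, 0.0]), 0.5)
        assert out.tolist() == [1.0, -1.0]

    def test_p02_values(self):
        out = standardize_treatment(np.array([1.0, 0.0]), 0.2)
        assert out[0] == pytest.approx(2.0)
        assert out[1] == pytest.approx(-0.5)

    def test_balanced_vector_mean0_var1(self):
        t = np.tile([1.0, 0.0], 25)
        out = standardize_treatment(t, 0.5)
        assert abs(out.mean()) < 1e-12 and abs(out.var() - 1.0) < 1e-12

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.01, 0.99))
    def test_gap_is_inverse_sqrt_p_one_minus_p(self, p):
        out = standardize_treatment(np.array([1.0, 0.0]), p)
        assert out[0] - out[1] == pytest.approx(1.0 / np.sqrt(p * (1 - p)))

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            standardize_treatment(np.array([1.0]), 1.0)


class TestVcfReader:
    VCF_TEXT = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT:DS\t0/0:0.1\t0/1:1.0\t1/1:1.9
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT:DS\t0/1:0.9\t0/0:0.0\t0/1:1.1
1\t300\trs3\tA\tC\t.\tPASS\t.\tGT:DS\t1/1:2.0\t0/1:1.0\t0/0:0.0
"""

    def test_ds_field(self, tmp_path):
        from mlearner.data import read_vcf_dosages

        f = tmp_path / "toy.vcf"
        f.write_text(self.VCF_TEXT)
        samples, gm = read_vcf_dosages(f, field="DS")
        assert samples == ["S1", "S2", "S3"]
        assert gm.variant_ids == ["rs1", "rs2", "rs3"]
        assert gm.effect_alleles == ["G", "T", "C"]
        np.testing.assert_allclose(gm.dosages[:, 0], [0.1, 1.0, 1.9])

    def test_gt_field_counts_alt_alleles(self, tmp_path):
        from mlearner.data import read_vcf_dosages

        f = tmp_path / "toy.vcf"
        f.write_text(self.VCF_TEXT)
        _, gm = read_vcf_dosages(f, field="GT")
        np.testing.assert_allclose(gm.dosages[:, 0], [0.0, 1.0, 2.0])
        np.testing.assert_allclose(gm.dosages[:, 1], [1.0, 0.0, 1.0])
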