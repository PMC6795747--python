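"""Genotype QC: call rates, MAF, the exact HWE test, filtering, grouping,
segmentation and digital encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from conftest import make_table

from mrfusion import qc


def hom(a):
    return (a, a)


HET = ("A", "C")
MISS = ("0", "0")


class TestCallRates:
    def test_complete_table_has_unit_rates(self):
        table = make_table([[hom("A"), HET]] * 3)
        assert qc.sample_call_rate(table).tolist() == [1.0] * 3
        assert qc.snp_call_rate(table).tolist() == [1.0, 1.0]

    def test_one_missing_of_ten_snps_gives_09(self):
        calls = [[hom("A")] * 10, [MISS] + [hom("A")] * 9]
        table = make_table(calls)
        assert qc.sample_call_rate(table).tolist() == [1.0, 0.9]

    def test_snp_call_rate_boundary_at_default_threshold(self):
        # 1 missing of 1000 passes (0.999 >= 0.999); 2 missing fails (0.998)
        calls = np.empty((1000, 2, 2), dtype="U1")
        calls[:] = "A"
        calls[0, 0] = "0"
        calls[:2, 1] = "0"
        table = make_table(calls)
        rates = qc.snp_call_rate(table)
        thr = qc.QCThresholds().snp_call_rate_min
        assert rates[0] >= thr > rates[1]


class TestMAF:
    def test_monomorphic_is_zero(self):
        table = make_table([[hom("A")]] * 5, allele_a=["A"], allele_b=["C"])
        assert qc.minor_allele_frequency(table)[0] == 0.0

    def test_hand_counted_het_mixture(self):
        # 10 subjects: 4 het + 6 hom-major -> 4 minor alleles of 20
        calls = [[HET]] * 4 + [[hom("A")]] * 6
        table = make_table(calls, allele_a=["A"], allele_b=["C"])
        assert qc.minor_allele_frequency(table)[0] == pytest.approx(0.2)

    def test_balanced_alleles_give_half(self):
        calls = [[hom("A")]] * 3 + [[hom("C")]] * 3
        table = make_table(calls, allele_a=["A"], allele_b=["C"])
        assert qc.minor_allele_frequency(table)[0] == pytest.approx(0.5)

    def test_missing_excluded_from_denominator(self):
        calls = [[HET], [MISS], [hom("A")]]
        table = make_table(calls, allele_a=["A"], allele_b=["C"])
        assert qc.minor_allele_frequency(table)[0] == pytest.approx(0.25)

    def test_all_missing_column_raises(self):
        table = make_table([[MISS]] * 3, allele_a=["A"], allele_b=["C"])
        with pytest.raises(ValueError, match="all-missing"):
            qc.minor_allele_frequency(table)


def hwe_enumeration_oracle(n_hom_a, n_het, n_hom_b):
    """Brute-force exact HWE p-value by enumerating the conditional
    distribution of heterozygote counts via binomial coefficients."""
    n = n_hom_a + n_het + n_hom_b
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    rare = min(n_a, n_b)
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        if hom_common < 0:
            continue
        # multinomial count of genotype configurations x 2^het allele orders
        probs[het] = (
            comb(n, hom_rare, exact=True)
            * comb(n - hom_rare, het, exact=True)
            * 2**het
        )
    total = sum(probs.values())
    p_obs = probs[n_het]
    return sum(v for v in probs.values() if v <= p_obs) / total


class TestHWEExactTest:
    def test_symmetric_equilibrium_counts_give_one(self):
        assert qc.hwe_exact_test(25, 50, 25) == pytest.approx(
            hwe_enumeration_oracle(25, 50, 25), abs=1e-9
        )
        assert qc.hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-9)

    def test_monomorphic_is_one(self):
        assert qc.hwe_exact_test(17, 0, 0) == 1.0

    def test_extreme_het_deficit_below_default_threshold(self):
        assert qc.hwe_exact_test(20, 0, 20) < 1e-4

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            qc.hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            qc.hwe_exact_test(-1, 2, 3)

    @pytest.mark.parametrize("total", [2, 5, 9, 14])
    def test_matches_enumeration_exhaustively_small_n(self, total):
        for n_hom_a in range(total + 1):
            for n_het in range(total - n_hom_a + 1):
                n_hom_b = total - n_hom_a - n_het
                expected = hwe_enumeration_oracle(n_hom_a, n_het, n_hom_b)
                assert qc.hwe_exact_test(n_hom_a, n_het, n_hom_b) == pytest.approx(
                    expected, abs=1e-12
                )


class TestApplyQC:
    def _noisy_table(self, seed=0, n=60, p=40):
        rng = np.random.default_rng(seed)
        calls = np.empty((n, p, 2), dtype="U1")
        for j in range(p):
            maf = rng.uniform(0.05, 0.5)
            geno = rng.choice(3, size=n, p=[(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
            col = np.empty((n, 2), dtype="U1")
            col[geno == 0] = ("A", "A")
            col[geno == 1] = ("A", "C")
            col[geno == 2] = ("C", "C")
            calls[:, j] = col
        miss = rng.random((n, p)) < 0.03
        calls[miss] = "0"
        return make_table(calls, allele_a=["A"] * p, allele_b=["C"] * p)

    def test_vacuous_thresholds_are_identity(self):
        table = self._noisy_table()
        out, report = qc.apply_qc(table, qc.QCThresholds(0.0, 0.0, 0.0, 0.0))
        assert out.equals(table)
        assert report.subjects_removed_call_rate == 0
        assert (
            report.snps_removed_call_rate
            == report.snps_removed_maf
            == report.snps_removed_hwe
            == 0
        )

    def test_tightening_any_threshold_shrinks_survivors(self):
        table = self._noisy_table(seed=3)
        base = qc.QCThresholds(0.9, 0.9, 0.05, 1e-4)
        out_base, _ = qc.apply_qc(table, base)
        # SNP-level thresholds: surviving SNPs shrink at a fixed subject set
        for tightened in [
            qc.QCThresholds(0.9, 0.99, 0.05, 1e-4),
            qc.QCThresholds(0.9, 0.9, 0.2, 1e-4),
            qc.QCThresholds(0.9, 0.9, 0.05, 0.5),
        ]:
            out_tight, _ = qc.apply_qc(table, tightened)
            assert set(out_tight.snps["snp_id"]) <= set(out_base.snps["snp_id"])
            assert set(out_tight.subject_ids) == set(out_base.subject_ids)
        # sample threshold: surviving subjects shrink (per-SNP statistics are
        # recomputed on the reduced cohort, so the SNP set may differ)
        out_tight, _ = qc.apply_qc(table, qc.QCThresholds(0.99, 0.9, 0.05, 1e-4))
        assert set(out_tight.subject_ids) <= set(out_base.subject_ids)

    def test_planted_hwe_violator_removed(self):
        rng = np.random.default_rng(7)
        n, p = 500, 20
        calls = np.empty((n, p, 2), dtype="U1")
        for j in range(p):
            if j == 11:  # violator: pure homozygotes at 50/50 allele frequency
                geno = rng.permutation([0] * 250 + [2] * 250)
            else:
                geno = rng.choice(3, size=n, p=[0.36, 0.48, 0.16])
            col = np.empty((n, 2), dtype="U1")
            col[geno == 0] = ("A", "A")
            col[geno == 1] = ("A", "G")
            col[geno == 2] = ("G", "G")
            calls[:, j] = col
        table = make_table(calls, allele_a=["A"] * p, allele_b=["G"] * p)
        out, report = qc.apply_qc(table)
        assert "snp11" not in set(out.snps["snp_id"])
        assert report.snps_removed_hwe == 1
        assert out.n_snps == p - 1


class TestGrouping:
    def _gene_table(self, sizes):
        gene_ids = []
        for g, size in enumerate(sizes):
            gene_ids += [f"g{g}"] * size
        calls = np.full((4, len(gene_ids), 2), "A", dtype="U1")
        return make_table(calls, allele_a=["A"] * len(gene_ids),
                          allele_b=["C"] * len(gene_ids), gene_ids=gene_ids)

    def test_strictly_more_than_threshold_required(self):
        table = self._gene_table([30, 31])
        groups, _ = qc.group_by_gene(table, min_snps=30)
        assert [g.gene_id for g in groups] == ["g1"]
        assert groups[0].group_size == 31

    def test_unmapped_snps_dropped_and_counted(self):
        table = self._gene_table([35])
        table.snps.loc[0, "gene_id"] = None
        groups, n_unmapped = qc.group_by_gene(table, min_snps=30)
        assert n_unmapped == 1
        assert groups[0].group_size == 34

    def test_requires_gene_assignments(self):
        table = make_table(np.full((2, 3, 2), "A", dtype="U1"))
        with pytest.raises(ValueError, match="gene"):
            qc.group_by_gene(table)


class TestSegmentation:
    def _grouped_table(self, sizes, seed=0):
        rng = np.random.default_rng(seed)
        gene_ids = []
        for g, size in enumerate(sizes):
            gene_ids += [f"g{g}"] * size
        p = len(gene_ids)
        geno = rng.choice(3, size=(6, p), p=[0.5, 0.3, 0.2])
        calls = np.empty((6, p, 2), dtype="U1")
        calls[geno == 0] = ("A", "A")
        calls[geno == 1] = ("A", "C")
        calls[geno == 2] = ("C", "C")
        table = make_table(calls, allele_a=["A"] * p, allele_b=["C"] * p,
                           gene_ids=gene_ids)
        groups, _ = qc.group_by_gene(table, min_snps=min(sizes) - 1)
        return table, groups

    def test_common_length_is_minimum_group_size(self):
        table, groups = self._grouped_table([31, 34, 40])
        sequences, L, _ = qc.segment_to_length(table, groups)
        assert L == 31
        assert all(seq.shape == (6, 31) for seq in sequences.values())

    def test_single_gene_keeps_own_length(self):
        table, groups = self._grouped_table([33])
        _, L, _ = qc.segment_to_length(table, groups)
        assert L == 33

    @pytest.mark.parametrize("policy", qc.ALLELE_POLICIES)
    def test_policies_agree_on_homozygotes(self, policy):
        calls = np.full((3, 32, 2), "G", dtype="U1")
        table = make_table(calls, allele_a=["G"] * 32, allele_b=["T"] * 32,
                           gene_ids=["g0"] * 32)
        groups, _ = qc.group_by_gene(table, min_snps=31)
        sequences, _, _ = qc.segment_to_length(table, groups, policy=policy, seed=1)
        assert (sequences["g0"] == "G").all()

    def test_missing_calls_imputed_to_major_and_counted(self):
        table, groups = self._grouped_table([32])
        table.calls[0, 0] = "0"
        sequences, _, n_imputed = qc.segment_to_length(table, groups)
        assert n_imputed == 1
        assert sequences["g0"][0, 0] in "AC"


class TestEncoding:
    def test_stated_mapping(self):
        assert qc.encode_sequence("ATCG").tolist() == [1, 2, 3, 4]

    def test_empty_and_constant(self):
        assert qc.encode_sequence("").tolist() == []
        assert qc.encode_sequence("GGGG").tolist() == [4, 4, 4, 4]

    @pytest.mark.parametrize("bad", ["N", "0", "ATXG"])
    def test_non_nucleotide_raises(self, bad):
        with pytest.raises(ValueError, match="encode"):
            qc.encode_sequence(bad)

    @settings(deadline=None, max_examples=50)
    @given(st.text(alphabet="ACGT", max_size=64))
    def test_encode_decode_roundtrip(self, seq):
        codes = qc.encode_sequence(seq)
        assert len(codes) == len(seq)
        assert qc.decode_sequence(codes) == seq
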