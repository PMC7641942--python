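"""Score computation, weight-table loading and VCF dosage extraction."""

import math

import numpy as np
import pandas as pd
import pytest

from t1dgrs.grs import (
    DosageMatrix,
    WeightEntry,
    WeightTable,
    classify_high_low,
    compute_grs,
    dosages_from_vcf,
    load_weight_table,
)

from conftest import make_weight_table, per_allele_oracle


class TestLoadWeightTable:
    def test_single_row_weight_is_log10_or(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("snp_id\teffect_allele\tother_allele\todds_ratio\nrs1\tA\tG\t10.0\n")
        table = load_weight_table(p)
        assert table.m == 1
        assert table.entries[0].weight == pytest.approx(1.0, abs=1e-15)

    def test_unit_odds_ratio_contributes_nothing(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("snp_id\teffect_allele\tother_allele\todds_ratio\nrs1\tA\tG\t1.0\n")
        assert load_weight_table(p).entries[0].weight == 0.0

    def test_synthetic_panel_weights_match_log10_recomputation(self, synthetic_weights):
        # independent recomputation of each weight from the raw file
        raw = pd.read_csv(
            __import__("t1dgrs.grs", fromlist=["x"]).synthetic_weight_table_path(), sep="\t"
        )
        assert synthetic_weights.m == 30
        for entry, odds in zip(synthetic_weights.entries, raw["odds_ratio"]):
            assert entry.weight == pytest.approx(math.log(odds) / math.log(10), abs=1e-14)

    @pytest.mark.parametrize(
        "row,match",
        [
            ("rs1\tA\tG\t10\nrs1\tC\tT\t2", "duplicate"),
            ("rs1\tA\tG\t-1", "odds_ratio"),
            ("rs1\tA\tG\tabc", "not numeric"),
            ("rs1\tA\tG\t.", "not numeric"),
            ("rs1\tAA\tG\t2", "alleles"),
        ],
    )
    def test_malformed_tables_raise_with_context(self, tmp_path, row, match):
        p = tmp_path / "w.tsv"
        p.write_text("snp_id\teffect_allele\tother_allele\todds_ratio\n" + row + "\n")
        with pytest.raises(ValueError, match=match):
            load_weight_table(p)


class TestDosagesFromVcf:
    def test_matches_hand_tabulated_companion(self, toy_vcf_path, toy_weights, toy_dosage_path):
        dm = dosages_from_vcf(toy_vcf_path, toy_weights)
        expected = pd.read_csv(toy_dosage_path, sep="\t", index_col=0)
        got = dm.to_frame()
        assert list(got.index) == list(expected.index)
        np.testing.assert_array_equal(
            got.to_numpy(), expected.to_numpy(dtype=float)
        )

    def test_ref_as_effect_allele_counts_reference_copies(self, toy_vcf_path, toy_weights):
        # rs2 has REF=C=effect allele: GT 1/1 means zero effect alleles
        dm = dosages_from_vcf(toy_vcf_path, toy_weights)
        assert dm.to_frame().loc["s2", "rs2"] == 0.0

    def test_uncalled_genotype_is_missing(self, toy_vcf_path, toy_weights):
        dm = dosages_from_vcf(toy_vcf_path, toy_weights)
        assert np.isnan(dm.to_frame().loc["s3", "rs2"])

    def test_snp_absent_from_vcf_missing_for_all(self, tmp_path, toy_vcf_path):
        table = load_weight_table(
            _write_weights(tmp_path, "rs1\tA\tG\t10.0\nrs99\tC\tT\t2.0")
        )
        dm = dosages_from_vcf(toy_vcf_path, table)
        assert np.isnan(dm.to_frame()["rs99"]).all()

    def test_strand_flip_accepted_only_when_unambiguous(self, tmp_path):
        # VCF alleles are the complement strand (T/C) of the table's A/G SNP
        vcf = _write_vcf(tmp_path, "1\t100\trs1\tC\tT\t.\tPASS\t.\tGT\t0/1\n")
        table = load_weight_table(_write_weights(tmp_path, "rs1\tA\tG\t10.0"))
        with pytest.raises(ValueError, match="do not match"):
            dosages_from_vcf(vcf, table, strand_policy="strict")
        dm = dosages_from_vcf(vcf, table, strand_policy="flip-unambiguous")
        assert dm.dosages[0, 0] == 1.0

    def test_ambiguous_snp_never_silently_flipped(self, tmp_path):
        # A/T SNP: the flipped orientation is indistinguishable from a swap
        vcf = _write_vcf(tmp_path, "1\t100\trs1\tA\tT\t.\tPASS\t.\tGT\t0/1\n")
        table = load_weight_table(_write_weights(tmp_path, "rs1\tA\tT\t2.0"))
        # direct match works (no flip needed)
        assert dosages_from_vcf(vcf, table, strand_policy="flip-unambiguous").dosages[0, 0] == 1.0
        # a genuinely mismatching ambiguous site errors under both policies
        vcf2 = _write_vcf(tmp_path, "1\t100\trs1\tG\tC\t.\tPASS\t.\tGT\t0/1\n", name="b.vcf")
        with pytest.raises(ValueError):
            dosages_from_vcf(vcf2, table, strand_policy="flip-unambiguous")

    def test_multiallelic_scored_site_rejected(self, tmp_path):
        vcf = _write_vcf(tmp_path, "1\t100\trs1\tG\tA,C\t.\tPASS\t.\tGT\t0/1\n")
        table = load_weight_table(_write_weights(tmp_path, "rs1\tA\tG\t10.0"))
        with pytest.raises(ValueError, match="multiallelic"):
            dosages_from_vcf(vcf, table)


class TestComputeGrs:
    def test_all_zero_dosages_give_zero_score(self):
        table = make_weight_table([2.0, 3.0, 1.5])
        dm = _matrix(["i1", "i2"], table, np.zeros((2, 3)))
        for r in compute_grs(dm, table):
            assert r.grs == 0.0

    def test_single_snp_homozygote_scores_the_weight(self):
        table = make_weight_table([10.0])  # weight 1.0
        dm = _matrix(["i1"], table, np.array([[2.0]]))
        (r,) = compute_grs(dm, table)
        assert r.grs == pytest.approx(1.0)
        assert r.n_alleles == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_allele_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = make_weight_table(rng.uniform(0.5, 8.0, size=4))
        dose = rng.integers(0, 3, size=(5, 4)).astype(float)
        dose[rng.random((5, 4)) < 0.2] = np.nan
        dose[:, 0] = np.nan_to_num(dose[:, 0])  # keep every individual scoreable
        dm = _matrix([f"i{k}" for k in range(5)], table, dose)
        for r in compute_grs(dm, table):
            i = int(r.individual_id[1:])
            expected = per_allele_oracle(dose[i], table, list(table.snp_ids))
            assert r.grs == pytest.approx(expected, abs=1e-12)

    def test_reduce_denominator_uses_non_missing_snps(self):
        table = make_weight_table([10.0, 10.0])
        dose = np.array([[2.0, np.nan]])
        (r,) = compute_grs(dm := _matrix(["i1"], table, dose), table)
        assert r.grs == pytest.approx(1.0)  # 2*1.0 / 2 alleles
        assert r.n_snps_used == 1 and r.missing_count == 1

    def test_drop_individual_policy_omits_high_missingness(self):
        table = make_weight_table([2.0, 2.0, 2.0])
        dose = np.array([[1.0, np.nan, np.nan], [1.0, 1.0, 1.0]])
        records = compute_grs(
            _matrix(["i1", "i2"], table, dose), table,
            missing_policy="drop-individual", max_missing=1,
        )
        assert [r.individual_id for r in records] == ["i2"]

    def test_no_genotypes_at_all_is_an_error(self):
        table = make_weight_table([2.0])
        dm = _matrix(["i1"], table, np.array([[np.nan]]))
        with pytest.raises(ValueError, match="no non-missing"):
            compute_grs(dm, table)

    def test_unknown_snp_in_dosages_is_an_error(self):
        table = make_weight_table([2.0])
        dm = DosageMatrix(("i1",), ("rsX",), np.array([[1.0]]))
        with pytest.raises(ValueError, match="rsX"):
            compute_grs(dm, table)

    def test_power_transform_of_odds_ratios_scales_scores(self, rng):
        # replacing OR by OR^2 doubles every weight, hence every score
        ors = rng.uniform(1.1, 5.0, size=6)
        dose = rng.integers(0, 3, size=(8, 6)).astype(float)
        t1, t2 = make_weight_table(ors), make_weight_table(ors**2)
        s1 = [r.grs for r in compute_grs(_matrix([f"i{k}" for k in range(8)], t1, dose), t1)]
        s2 = [r.grs for r in compute_grs(_matrix([f"i{k}" for k in range(8)], t2, dose), t2)]
        np.testing.assert_allclose(np.array(s2), 2 * np.array(s1), rtol=1e-12)

    def test_consistent_snp_permutation_leaves_scores_unchanged(self, rng):
        ors = rng.uniform(1.1, 5.0, size=6)
        dose = rng.integers(0, 3, size=(4, 6)).astype(float)
        table = make_weight_table(ors)
        perm = rng.permutation(6)
        table_p = WeightTable(entries=tuple(table.entries[j] for j in perm))
        ids = [f"i{k}" for k in range(4)]
        s1 = [r.grs for r in compute_grs(_matrix(ids, table, dose), table)]
        dm_p = DosageMatrix(tuple(ids), tuple(table_p.snp_ids), dose[:, perm])
        s2 = [r.grs for r in compute_grs(dm_p, table_p)]
        np.testing.assert_allclose(s1, s2, rtol=1e-14)

    def test_scores_bounded_by_max_weight_for_positive_weights(self, rng):
        ors = rng.uniform(1.0, 8.0, size=10)
        table = make_weight_table(ors)
        dose = rng.integers(0, 3, size=(50, 10)).astype(float)
        scores = [r.grs for r in compute_grs(_matrix([f"i{k}" for k in range(50)], table, dose), table)]
        assert all(0.0 <= s <= table.weights.max() + 1e-12 for s in scores)


class TestClassify:
    def test_strictly_above_threshold_is_high(self):
        labels = dict(classify_high_low({"a": 0.281, "b": 0.280, "c": 0.279}, 0.280))
        assert labels == {"a": "high", "b": "low", "c": "low"}

    def test_order_preserved(self):
        out = classify_high_low({"z": 1.0, "a": 0.0}, 0.5)
        assert [i for i, _ in out] == ["z", "a"]

    def test_non_finite_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_high_low({"a": 1.0}, float("nan"))


def _matrix(ids, table, dose):
    return DosageMatrix(tuple(ids), tuple(table.snp_ids), dose)


def _write_weights(tmp_path, body, name="w.tsv"):
    p = tmp_path / name
    p.write_text("snp_id\teffect_allele\tother_allele\todds_ratio\n" + body + "\n")
    return p


def _write_vcf(tmp_path, body, name="a.vcf"):
    p = tmp_path / name
    p.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n" + body
    )
    return p
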