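"""Summary-statistics parsing, validation, QC, and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adipoclass.errors import ContractError, EmptyInputError, FormatError
from adipoclass.sumstats import (
    CorrelationSpec,
    apply_qc,
    harmonize_alleles,
    read_sumstats,
    write_sumstats,
)

from conftest import make_giant_file


class TestRead:
    def test_well_formed_table_parses_identically(self, giant_file):
        table = read_sumstats(giant_file, trait="BMI")
        assert len(table) == 3
        assert list(table["variant_id"]) == ["rs1", "rs2", "rs3"]
        assert table["beta"].tolist() == [0.05, -0.02, 0.001]
        assert (table["trait"] == "BMI").all()
        assert (table["stratum"] == "combined").all()

    @pytest.mark.parametrize(
        "bad_row",
        [
            ("rsbad", "1", 500, "A", "G", 0.0, 0.05, 0.01, 50_000),  # eaf = 0
            ("rsbad", "1", 500, "A", "A", 0.3, 0.05, 0.01, 50_000),  # same alleles
            ("rsbad", "1", 500, "A", "N", 0.3, 0.05, 0.01, 50_000),  # bad allele
            ("rsbad", "1", 500, "A", "G", 0.3, 0.05, -1.0, 50_000),  # se <= 0
            ("rsbad", "1", 500, "A", "G", 0.3, 0.05, 0.01, 50_000, 0.5),  # p inconsistent
        ],
    )
    def test_invalid_rows_dropped(self, tmp_path, bad_row):
        path = make_giant_file(
            tmp_path / "t.tsv",
            [("rs1", "1", 100, "A", "G", 0.3, 0.05, 0.01, 50_000), bad_row],
        )
        table = read_sumstats(path, trait="BMI")
        assert list(table["variant_id"]) == ["rs1"]

    def test_missing_p_imputed_from_normal_tail(self, tmp_path):
        path = tmp_path / "nop.tsv"
        pd.DataFrame(
            {
                "MarkerName": ["rs1"],
                "Allele1": ["A"],
                "Allele2": ["G"],
                "FreqAllele1HapMapCEU": [0.3],
                "b": [0.05],
                "se": [0.02],
                "N": [30_000],
            }
        ).to_csv(path, sep="\t", index=False)
        table = read_sumstats(path, trait="BMI")
        expected = 2 * stats.norm.sf(0.05 / 0.02)
        assert table["p"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_missing_mandatory_column_is_format_error(self, tmp_path):
        path = tmp_path / "broken.tsv"
        pd.DataFrame({"MarkerName": ["rs1"], "b": [0.1]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError):
            read_sumstats(path, trait="BMI")

    def test_empty_after_filtering_raises(self, tmp_path):
        path = make_giant_file(
            tmp_path / "allbad.tsv",
            [("rs1", "1", 100, "A", "G", 1.5, 0.05, 0.01, 50_000)],
        )
        with pytest.raises(EmptyInputError):
            read_sumstats(path, trait="BMI")

    def test_custom_column_map(self, tmp_path):
        path = tmp_path / "custom.tsv"
        pd.DataFrame(
            {
                "ID": ["rs9"],
                "EFF": ["T"],
                "REF": ["C"],
                "AF": [0.2],
                "ES": [0.03],
                "SE": [0.01],
                "NS": [20_000],
            }
        ).to_csv(path, sep="\t", index=False)
        table = read_sumstats(
            path,
            trait="T2D",
            column_map={
                "ID": "variant_id", "EFF": "effect_allele", "REF": "other_allele",
                "AF": "eaf", "ES": "beta", "NS": "n",
            },
        )
        assert table["variant_id"].iloc[0] == "rs9"
        assert table["trait"].iloc[0] == "T2D"

    def test_gzip_round_trip_bit_identical(self, tmp_path, giant_file):
        table = read_sumstats(giant_file, trait="BMI")
        out = tmp_path / "rt.tsv.gz"
        write_sumstats(table, out)
        back = read_sumstats(out, trait="BMI")
        pd.testing.assert_frame_equal(table, back)


class TestQC:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                     "eaf", "beta", "se", "p", "n", "trait", "stratum"],
        )

    def test_min_n_boundary(self):
        t = self._table(
            [
                ["rs1", "1", 1, "A", "G", 0.3, 0.1, 0.02, 1e-6, 10_000, "BMI", "combined"],
                ["rs2", "1", 2, "A", "G", 0.3, 0.1, 0.02, 1e-6, 9_999, "BMI", "combined"],
            ]
        )
        kept = apply_qc(t, min_n=10_000)
        assert list(kept["variant_id"]) == ["rs1"]

    def test_sex_chromosomes_dropped(self):
        rows = [
            ["rs%d" % i, str(c), 1, "A", "G", 0.3, 0.1, 0.02, 1e-6, 50_000, "BMI", "combined"]
            for i, c in enumerate([1, 2, 3, 4, 5, "X", "Y"])
        ]
        kept = apply_qc(self._table(rows), min_n=0, drop_sex_chroms=True)
        assert len(kept) == 5
        assert not kept["chrom"].isin(["X", "Y"]).any()

    def test_identity_when_no_filters_bind(self):
        t = self._table(
            [["rs1", "1", 1, "A", "G", 0.3, 0.1, 0.02, 1e-6, 50_000, "BMI", "combined"]]
        )
        pd.testing.assert_frame_equal(apply_qc(t, min_n=0), t)

    def test_negative_min_n_rejected(self):
        with pytest.raises(ContractError):
            apply_qc(self._table([]), min_n=-1)


class TestHarmonize:
    def _two_tables(self, tmp_path, second_rows):
        p1 = make_giant_file(
            tmp_path / "a.tsv",
            [("rs1", "1", 100, "A", "G", 0.3, 0.05, 0.01, 50_000)],
        )
        p2 = make_giant_file(tmp_path / "b.tsv", second_rows)
        return (
            read_sumstats(p1, trait="BMI"),
            read_sumstats(p2, trait="WHR"),
        )

    def test_same_orientation_unchanged(self, tmp_path):
        t1, t2 = self._two_tables(
            tmp_path, [("rs1", "1", 100, "A", "G", 0.3, 0.02, 0.01, 50_000)]
        )
        merged = harmonize_alleles([t1, t2])
        whr = merged[merged["trait"] == "WHR"]
        assert whr["beta"].iloc[0] == pytest.approx(0.02)
        assert whr["eaf"].iloc[0] == pytest.approx(0.3)

    def test_swapped_alleles_flip_beta_and_eaf(self, tmp_path):
        t1, t2 = self._two_tables(
            tmp_path, [("rs1", "1", 100, "G", "A", 0.7, 0.02, 0.01, 50_000)]
        )
        merged = harmonize_alleles([t1, t2])
        whr = merged[merged["trait"] == "WHR"]
        assert whr["effect_allele"].iloc[0] == "A"
        assert whr["beta"].iloc[0] == pytest.approx(-0.02)
        assert whr["eaf"].iloc[0] == pytest.approx(0.3)

    def test_strand_complement_resolved(self, tmp_path):
        # T/C on the other strand is A/G on the reference strand
        t1, t2 = self._two_tables(
            tmp_path, [("rs1", "1", 100, "T", "C", 0.3, 0.02, 0.01, 50_000)]
        )
        merged = harmonize_alleles([t1, t2])
        whr = merged[merged["trait"] == "WHR"]
        assert whr["effect_allele"].iloc[0] == "A"
        assert whr["beta"].iloc[0] == pytest.approx(0.02)

    def test_ambiguous_pairs_flagged_not_dropped(self, tmp_path):
        p1 = make_giant_file(
            tmp_path / "amb1.tsv",
            [
                ("rs1", "1", 100, "A", "T", 0.3, 0.05, 0.01, 50_000),
                ("rs2", "1", 200, "C", "G", 0.4, 0.04, 0.01, 50_000),
                ("rs3", "1", 300, "A", "G", 0.3, 0.03, 0.01, 50_000),
            ],
        )
        p2 = make_giant_file(
            tmp_path / "amb2.tsv",
            [
                ("rs1", "1", 100, "A", "T", 0.3, 0.02, 0.01, 50_000),
                ("rs2", "1", 200, "C", "G", 0.4, 0.01, 0.01, 50_000),
                ("rs3", "1", 300, "A", "G", 0.3, 0.02, 0.01, 50_000),
            ],
        )
        merged = harmonize_alleles(
            [read_sumstats(p1, trait="BMI"), read_sumstats(p2, trait="WHR")]
        )
        # flag count equals the number of A/T and C/G pairs in the fixture
        assert merged.groupby("variant_id")["ambiguous"].first().sum() == 2
        assert set(merged["variant_id"]) == {"rs1", "rs2", "rs3"}

    def test_irreconcilable_pair_dropped(self, tmp_path):
        t1, t2 = self._two_tables(
            tmp_path,
            [
                ("rs1", "1", 100, "A", "C", 0.3, 0.02, 0.01, 50_000),
                ("rs4", "1", 400, "A", "G", 0.3, 0.02, 0.01, 50_000),
            ],
        )
        merged = harmonize_alleles([t1, t2])
        assert "rs1" not in set(merged["variant_id"])
        assert "rs4" in set(merged["variant_id"])

    def test_idempotence(self, tmp_path):
        t1, t2 = self._two_tables(
            tmp_path, [("rs1", "1", 100, "G", "A", 0.7, 0.02, 0.01, 50_000)]
        )
        once = harmonize_alleles([t1, t2])
        twice = harmonize_alleles([once])
        pd.testing.assert_frame_equal(once, twice)

    def test_effect_alleles_identical_across_traits_after_harmonization(self, tmp_path):
        t1, t2 = self._two_tables(
            tmp_path, [("rs1", "1", 100, "G", "A", 0.7, 0.02, 0.01, 50_000)]
        )
        merged = harmonize_alleles([t1, t2])
        assert merged.groupby("variant_id")["effect_allele"].nunique().max() == 1


class TestCorrelationSpec:
    def test_stratum_dispatch(self):
        spec = CorrelationSpec(r_combined=0.44, r_women=0.46, r_men=0.60)
        assert spec.for_stratum("combined") == 0.44
        assert spec.for_stratum("women") == 0.46
        assert spec.for_stratum("men") == 0.60

    def test_bounds_enforced(self):
        with pytest.raises(ContractError):
            CorrelationSpec(r_combined=1.0)
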