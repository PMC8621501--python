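"""Summary-statistic I/O and allele harmonization."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidmr import (
    ConfigurationError,
    InputError,
    LDMatrix,
    SummaryStats,
    VariantAssociation,
    harmonize,
    harmonize_detailed,
    read_ld,
    read_sumstats,
    write_ld,
    write_sumstats,
)

from conftest import make_variant, stats_from_records


def random_stats(rng, n=100):
    alleles = ["A", "C", "G", "T"]
    records = []
    for i in range(n):
        ea, oa = rng.choice(alleles, size=2, replace=False)
        records.append(
            VariantAssociation(
                snp_id=f"rs{i + 1}",
                chrom=str(rng.integers(1, 23)),
                pos=int(rng.integers(1, 10**8)),
                effect_allele=ea,
                other_allele=oa,
                eaf=float(rng.uniform(0.01, 0.99)),
                beta=float(rng.normal(0, 0.1)),
                se=float(rng.uniform(1e-4, 0.1)),
                pvalue=float(rng.uniform(1e-12, 1)),
                n=float(rng.integers(1000, 500_000)),
            )
        )
    return SummaryStats("trait", "continuous", records)


class TestReadWrite:
    def test_roundtrip_preserves_values_to_10_significant_digits(self, rng, tmp_path):
        stats = random_stats(rng, 100)
        path = write_sumstats(stats, tmp_path / "s.tsv")
        back = read_sumstats(path, trait_type="continuous")
        assert len(back) == 100
        for a, b in zip(stats.records, back.records):
            assert a.snp_id == b.snp_id
            assert (a.chrom, a.pos, a.effect_allele, a.other_allele) == (
                b.chrom, b.pos, b.effect_allele, b.other_allele,
            )
            for field in ("eaf", "beta", "se", "pvalue", "n"):
                assert getattr(b, field) == pytest.approx(
                    getattr(a, field), rel=1e-10
                )

    def test_small_table_roundtrip_and_header(self, tmp_path):
        stats = stats_from_records([make_variant()])
        path = write_sumstats(stats, tmp_path / "one.tsv")
        lines = path.read_text().splitlines()
        assert len(lines) == 2
        assert lines[0].split("\t") == [
            "snp_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pvalue", "n",
        ]
        empty = write_sumstats(stats_from_records([]), tmp_path / "empty.tsv")
        assert len(empty.read_text().splitlines()) == 1

    def test_invalid_rows_dropped_and_logged(self, tmp_path, caplog):
        rows = [
            make_variant("rs1", pos=100),
            make_variant("rs2", pos=200),
            make_variant("rs3", pos=300),
        ]
        path = write_sumstats(stats_from_records(rows), tmp_path / "s.tsv")
        text = path.read_text().replace("\t0.01\t", "\t0\t", 1)  # se -> 0 on rs1
        bad = tmp_path / "bad.tsv"
        bad.write_text(text)
        with caplog.at_level(logging.WARNING):
            stats = read_sumstats(bad, trait_type="continuous")
        assert len(stats) == 2
        assert stats.snp_ids == ["rs2", "rs3"]
        assert "dropped 1" in caplog.text

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("snp_id\tbeta\nrs1\t0.1\n")
        with pytest.raises(ConfigurationError):
            read_sumstats(path)

    def test_column_map_renames(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "SNP\tCHR\tBP\tA1\tA2\tFRQ\tBETA\tSE\tP\tN\n"
            "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-8\t10000\n"
        )
        cmap = dict(
            snp_id="SNP", chrom="CHR", pos="BP", effect_allele="A1",
            other_allele="A2", eaf="FRQ", beta="BETA", se="SE", pvalue="P", n="N",
        )
        stats = read_sumstats(path, column_map=cmap)
        assert stats.records[0].beta == 0.1

    def test_zero_valid_rows_is_input_error(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
            "rs1\t1\t100\tA\tA\t0.3\t0.1\t0.01\t0.5\t100\n"
        )
        with pytest.raises(InputError):
            read_sumstats(path)

    def test_duplicate_ids_rejected_at_read_time(self, tmp_path):
        stats = stats_from_records([make_variant("rs1"), make_variant("rs2")])
        path = write_sumstats(stats, tmp_path / "s.tsv")
        text = path.read_text().replace("rs2", "rs1")
        (tmp_path / "dup.tsv").write_text(text)
        with pytest.raises(InputError, match="duplicate"):
            read_sumstats(tmp_path / "dup.tsv")


class TestLDMatrix:
    def test_roundtrip(self, rng, tmp_path):
        m = 8
        X = rng.normal(size=(40, m))
        r2 = np.corrcoef(X.T) ** 2
        ld = LDMatrix([f"rs{i}" for i in range(m)], r2, np.arange(1, m + 1) * 1000)
        back = read_ld(write_ld(ld, tmp_path / "ld.tsv"))
        assert back.snp_ids == ld.snp_ids
        np.testing.assert_allclose(back.r2, ld.r2, rtol=1e-10)
        np.testing.assert_array_equal(back.pos, ld.pos)

    @pytest.mark.parametrize(
        "mutation",
        ["asymmetric", "bad_diag", "out_of_range", "wrong_pos_len"],
    )
    def test_validation(self, mutation):
        r2 = np.eye(3)
        pos = np.array([1, 2, 3])
        if mutation == "asymmetric":
            r2 = r2.copy(); r2[0, 1] = 0.5
        elif mutation == "bad_diag":
            r2 = r2.copy(); r2[0, 0] = 0.9
        elif mutation == "out_of_range":
            r2 = r2.copy(); r2[0, 1] = r2[1, 0] = 1.5
        else:
            pos = np.array([1, 2])
        with pytest.raises(InputError):
            LDMatrix(["a", "b", "c"], r2, pos)


def _one_variant_stats(trait, ea, oa, beta, eaf, se=0.01):
    rec = make_variant("rs1", effect_allele=ea, other_allele=oa, beta=beta, eaf=eaf, se=se)
    return SummaryStats(trait, "continuous", [rec])


class TestHarmonize:
    def test_identity_case(self):
        exp = _one_variant_stats("x", "A", "G", 0.10, 0.3)
        out = _one_variant_stats("y", "A", "G", 0.05, 0.3)
        (pair,) = harmonize(exp, out)
        assert pair.beta_out == 0.05
        assert not pair.flipped

    def test_swapped_alleles_flip_sign_and_eaf(self):
        exp = _one_variant_stats("x", "A", "G", 0.10, 0.3)
        out = _one_variant_stats("y", "G", "A", 0.05, 0.30)
        (pair,) = harmonize(exp, out)
        assert pair.beta_out == pytest.approx(-0.05)
        assert pair.eaf_out == pytest.approx(0.70)
        assert pair.flipped

    def test_reverse_complement_strand_alignment(self):
        # outcome reported on the other strand: A/G on + is T/C on -
        exp = _one_variant_stats("x", "A", "G", 0.10, 0.3)
        out = _one_variant_stats("y", "T", "C", 0.05, 0.3)
        (pair,) = harmonize(exp, out)
        assert pair.beta_out == 0.05
        assert not pair.flipped
        # complement with swap
        out2 = _one_variant_stats("y", "C", "T", 0.05, 0.3)
        (pair2,) = harmonize(exp, out2)
        assert pair2.beta_out == pytest.approx(-0.05)
        assert pair2.flipped

    def test_mismatched_alleles_excluded(self):
        exp = SummaryStats(
            "x", "continuous",
            [make_variant("rs1", effect_allele="A", other_allele="G"),
             make_variant("rs2", pos=2000, effect_allele="A", other_allele="G")],
        )
        out = SummaryStats(
            "y", "continuous",
            [make_variant("rs1", effect_allele="A", other_allele="C"),
             make_variant("rs2", pos=2000, effect_allele="A", other_allele="G")],
        )
        pairs, excluded = harmonize_detailed(exp, out)
        assert [p.snp_id for p in pairs] == ["rs2"]
        assert excluded == [("rs1", "allele_mismatch")]

    def test_empty_intersection_raises(self):
        exp = _one_variant_stats("x", "A", "G", 0.1, 0.3)
        out = SummaryStats("y", "continuous", [make_variant("rs99")])
        with pytest.raises(InputError):
            harmonize(exp, out)

    @pytest.mark.parametrize("eaf_exp", [0.10, 0.30, 0.45, 0.50, 0.55, 0.70, 0.90])
    @pytest.mark.parametrize("eaf_out", [0.10, 0.30, 0.45, 0.50, 0.55, 0.70, 0.90])
    def test_palindromic_infer_by_eaf_decision_table(self, eaf_exp, eaf_out):
        """Brute-force the policy table: ambiguous band excludes; otherwise
        strand is aligned so minor/major status agrees."""
        exp = _one_variant_stats("x", "A", "T", 0.10, eaf_exp)
        out = _one_variant_stats("y", "A", "T", 0.05, eaf_out)
        pairs, excluded = harmonize_detailed(exp, out)
        ambiguous = (0.42 <= eaf_exp <= 0.58) or (0.42 <= eaf_out <= 0.58)
        if ambiguous:
            assert not pairs
            assert excluded[0][1] == "palindromic_ambiguous"
        else:
            (pair,) = pairs
            expect_flip = (eaf_exp < 0.5) != (eaf_out < 0.5)
            assert pair.flipped == expect_flip
            assert pair.beta_out == pytest.approx(-0.05 if expect_flip else 0.05)

    def test_palindromic_policies(self):
        exp = _one_variant_stats("x", "C", "G", 0.10, 0.2)
        out = _one_variant_stats("y", "C", "G", 0.05, 0.2)
        assert harmonize(exp, out, "drop") == []
        (kept,) = harmonize(exp, out, "keep")
        assert kept.beta_out == 0.05
        # missing EAF: palindromic excluded, non-palindromic kept
        exp_na = _one_variant_stats("x", "C", "G", 0.10, 0.2)
        out_na = SummaryStats(
            "y", "continuous",
            [make_variant("rs1", effect_allele="C", other_allele="G", eaf=None)],
        )
        pairs, excluded = harmonize_detailed(exp_na, out_na)
        assert not pairs and excluded[0][1] == "palindromic_missing_eaf"
        exp_ng = _one_variant_stats("x", "A", "G", 0.10, 0.2)
        out_ng = SummaryStats(
            "y", "continuous",
            [make_variant("rs1", effect_allele="A", other_allele="G", eaf=None)],
        )
        (pair,) = harmonize(exp_ng, out_ng)
        assert pair.eaf_out is None

    @given(
        beta_exp=st.floats(-0.5, 0.5, allow_nan=False),
        beta_out=st.floats(-0.5, 0.5, allow_nan=False),
        swap=st.booleans(),
        alleles=st.sampled_from([("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]),
    )
    @settings(max_examples=60, derandomize=True)
    def test_double_flip_is_identity(self, beta_exp, beta_out, swap, alleles):
        """Swapping the outcome's allele coding (and negating its beta)
        must yield identical harmonized effect pairs."""
        ea, oa = alleles
        exp = _one_variant_stats("x", ea, oa, beta_exp, 0.3)
        out = _one_variant_stats("y", ea if not swap else oa,
                                 oa if not swap else ea,
                                 beta_out if not swap else -beta_out, 0.3)
        out_flipped = _one_variant_stats("y", out.records[0].other_allele,
                                         out.records[0].effect_allele,
                                         -out.records[0].beta,
                                         1 - out.records[0].eaf)
        (a,) = harmonize(exp, out)
        (b,) = harmonize(exp, out_flipped)
        assert a.beta_exp == b.beta_exp
        assert a.beta_out == pytest.approx(b.beta_out, abs=1e-12)
        assert a.eaf_out == pytest.approx(b.eaf_out, abs=1e-12)

    def test_harmonization_idempotent_and_count_bounded(self, rng):
        exp = random_stats(rng, 50)
        out = random_stats(np.random.default_rng(7), 60)
        # share 40 ids
        pairs, _ = harmonize_detailed(exp, out)
        assert len(pairs) <= min(len(exp), len(out))
        # re-harmonizing the aligned outputs changes nothing
        exp2 = SummaryStats("x", "continuous", [
            make_variant(p.snp_id, effect_allele=p.effect_allele,
                         other_allele=p.other_allele, beta=p.beta_exp,
                         eaf=p.eaf_exp, se=p.se_exp, pos=p.pos)
            for p in pairs])
        out2 = SummaryStats("y", "continuous", [
            make_variant(p.snp_id, effect_allele=p.effect_allele,
                         other_allele=p.other_allele, beta=p.beta_out,
                         eaf=p.eaf_out, se=p.se_out, pos=p.pos)
            for p in pairs])
        if len(pairs):
            again = harmonize(exp2, out2)
            for p, q in zip(pairs, again):
                assert q.beta_out == pytest.approx(p.beta_out, abs=1e-12)
                assert not q.flipped or p.palindromic
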