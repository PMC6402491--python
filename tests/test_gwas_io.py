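"""Summary-statistics I/O and allele harmonization."""

import numpy as np
import pytest

from mrkit.gwas_io import (
    FormatError,
    SummaryRecord,
    harmonize,
    read_harmonized,
    read_summary_stats,
    write_harmonized,
    write_summary_stats,
)
from conftest import make_record


HEADER = "snp_id\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tinfo\n"


def write_rows(path, rows, header=HEADER):
    path.write_text(header + "".join(rows))


class TestReadSummaryStats:
    def test_identity_read_back(self, tmp_path):
        records = [make_record(f"rs{i}", beta=0.01 * (i + 1)) for i in range(3)]
        path = tmp_path / "stats.tsv"
        write_summary_stats(path, records)
        assert read_summary_stats(path) == records

    def test_column_map_invariance(self, tmp_path):
        canonical = tmp_path / "a.tsv"
        renamed = tmp_path / "b.tsv"
        write_rows(canonical, ["rs1\tA\tG\t0.3\t0.05\t0.01\t1e-9\t0.9\n"])
        write_rows(renamed, ["rs1\tA\tG\t0.3\t0.05\t0.01\t1e-9\t0.9\n"],
                   header="snp_id\teffect_allele\tother_allele\teaf\tlogOR\tse\tpvalue\tinfo\n")
        assert read_summary_stats(renamed, {"beta": "logOR"}) == read_summary_stats(canonical)

    def test_nonpositive_se_rejected_with_logged_reason(self, tmp_path, caplog):
        path = tmp_path / "stats.tsv"
        write_rows(path, [
            "rs1\tA\tG\t0.3\t0.05\t0.01\t1e-9\t0.9\n",
            "rs2\tA\tG\t0.3\t0.05\t0\t1e-9\t0.9\n",
            "rs3\tA\tG\t0.3\t0.05\t0.02\t1e-9\t0.9\n",
        ])
        with caplog.at_level("WARNING"):
            records = read_summary_stats(path)
        assert [r.snp_id for r in records] == ["rs1", "rs3"]
        assert any("rs2" in m or "line 3" in m for m in caplog.messages)

    def test_indel_and_multiallelic_rejected(self, tmp_path):
        path = tmp_path / "stats.tsv"
        write_rows(path, [
            "rs1\tAT\tG\t0.3\t0.05\t0.01\t1e-9\t0.9\n",
            "rs2\tA\tG\t0.3\t0.05\t0.01\t1e-9\t0.9\n",
        ])
        records = read_summary_stats(path)
        assert [r.snp_id for r in records] == ["rs2"]

    def test_missing_mapped_column_names_it(self, tmp_path):
        path = tmp_path / "stats.tsv"
        write_rows(path, ["rs1\tA\tG\t0.3\t0.05\t0.01\t1e-9\t0.9\n"])
        with pytest.raises(FormatError, match="logOR"):
            read_summary_stats(path, {"beta": "logOR"})

    def test_unparseable_numeric_reports_line(self, tmp_path):
        path = tmp_path / "stats.tsv"
        write_rows(path, [
            "rs1\tA\tG\t0.3\t0.05\t0.01\t1e-9\t0.9\n",
            "rs2\tA\tG\t0.3\tnot_a_number\t0.01\t1e-9\t0.9\n",
        ])
        with pytest.raises(FormatError, match="line 3"):
            read_summary_stats(path)

    def test_gzip_accepted(self, tmp_path):
        import gzip

        path = tmp_path / "stats.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(HEADER + "rs1\ta\tg\t0.3\t0.05\t0.01\t1e-9\t\n")
        (rec,) = read_summary_stats(path)
        assert rec.effect_allele == "A" and rec.other_allele == "G"  # upper-cased
        assert rec.info is None


class TestHarmonize:
    def test_allele_swap_negates_outcome_beta(self):
        exp = make_record("rs1", "A", "G", beta=0.05)
        out = make_record("rs1", "G", "A", beta=0.01, eaf=0.7)
        h = harmonize([exp], [out])
        assert h.snp_ids == ["rs1"]
        assert h.gamma[0] == pytest.approx(0.05)
        assert h.beta[0] == pytest.approx(-0.01)

    def test_exposure_increasing_reorientation_flips_both(self):
        exp = make_record("rs1", "A", "G", beta=-0.05, eaf=0.3)
        out = make_record("rs1", "A", "G", beta=0.01)
        h = harmonize([exp], [out])
        assert h.gamma[0] == pytest.approx(0.05)
        assert h.beta[0] == pytest.approx(-0.01)

    def test_strand_flip_resolves_complement_labels(self):
        exp = make_record("rs1", "A", "G", beta=0.05)
        out = make_record("rs1", "T", "C", beta=0.02)  # same variant, other strand
        h = harmonize([exp], [out])
        assert h.beta[0] == pytest.approx(0.02)

    def test_palindromic_ambiguous_dropped_by_eaf_window(self):
        exp = make_record("rs1", "A", "T", beta=0.05, eaf=0.50)
        out = make_record("rs1", "A", "T", beta=0.01, eaf=0.50)
        keeper_exp = make_record("rs2", "A", "G", beta=0.05)
        keeper_out = make_record("rs2", "A", "G", beta=0.01)
        h = harmonize([exp, keeper_exp], [out, keeper_out],
                      palindrome_policy="infer_by_eaf", eaf_ambiguity_window=0.08)
        assert h.drops["rs1"] == "palindromic-ambiguous"
        assert h.snp_ids == ["rs2"]

    def test_palindromic_eaf_disagreement_flips_sign(self):
        exp = make_record("rs1", "A", "T", beta=0.05, eaf=0.2)
        out = make_record("rs1", "A", "T", beta=0.01, eaf=0.85)
        h = harmonize([exp], [out])
        assert h.beta[0] == pytest.approx(-0.01)

    def test_palindromic_missing_eaf_dropped(self):
        exp = make_record("rs1", "A", "T", beta=0.05, eaf=None)
        out = make_record("rs1", "A", "T", beta=0.01, eaf=0.85)
        keeper_exp = make_record("rs2", "A", "G", beta=0.05)
        keeper_out = make_record("rs2", "A", "G", beta=0.01)
        h = harmonize([exp, keeper_exp], [out, keeper_out])
        assert h.drops["rs1"] == "palindromic-missing-eaf"

    def test_drop_ambiguous_policy_drops_all_palindromes(self):
        exp = [make_record("rs1", "C", "G", beta=0.05, eaf=0.1),
               make_record("rs2", "A", "G", beta=0.05)]
        out = [make_record("rs1", "C", "G", beta=0.01, eaf=0.1),
               make_record("rs2", "A", "G", beta=0.01)]
        h = harmonize(exp, out, palindrome_policy="drop_ambiguous")
        assert h.drops["rs1"] == "palindromic"

    def test_allele_mismatch_dropped(self):
        exp = [make_record("rs1", "A", "G", beta=0.05),
               make_record("rs2", "A", "G", beta=0.05)]
        out = [make_record("rs1", "A", "C", beta=0.01),
               make_record("rs2", "A", "G", beta=0.01)]
        h = harmonize(exp, out)
        assert h.drops["rs1"] == "allele-mismatch"

    def test_unmatched_and_intersection_accounting(self):
        exp = [make_record(f"rs{i}", beta=0.05) for i in range(4)]
        out = [make_record(f"rs{i}", beta=0.01) for i in range(2, 6)]
        h = harmonize(exp, out)
        shared = {"rs2", "rs3"}
        dropped_shared = {s for s, r in h.drops.items() if s in shared and r != "unmatched"}
        assert set(h.snp_ids) | dropped_shared == shared
        assert all(h.drops[s] == "unmatched" for s in ("rs0", "rs1", "rs4", "rs5"))

    def test_duplicate_id_raises(self):
        exp = [make_record("rs1"), make_record("rs1")]
        with pytest.raises(ValueError, match="rs1"):
            harmonize(exp, [make_record("rs1")])

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match="no shared instruments"):
            harmonize([make_record("rs1")], [make_record("rs2")])

    def test_orientation_invariance_of_inputs(self):
        """Flipping allele labels + negating beta of any input record
        must leave the harmonized set unchanged."""
        exp = [make_record(f"rs{i}", "A", "G", beta=0.05 + 0.01 * i, eaf=0.2) for i in range(5)]
        out = [make_record(f"rs{i}", "A", "G", beta=0.01 * (i - 2), eaf=0.2) for i in range(5)]
        base = harmonize(exp, out)
        for k in range(5):
            for which, records in (("exp", list(exp)), ("out", list(out))):
                records[k] = records[k].flipped()
                h = (harmonize(records, out) if which == "exp" else harmonize(exp, records))
                np.testing.assert_allclose(h.gamma, base.gamma)
                np.testing.assert_allclose(h.beta, base.beta)
                assert h.snp_ids == base.snp_ids

    def test_all_gamma_positive(self):
        exp = [make_record(f"rs{i}", beta=(-1) ** i * 0.05) for i in range(6)]
        out = [make_record(f"rs{i}", beta=0.01) for i in range(6)]
        h = harmonize(exp, out)
        assert (h.gamma > 0).all()


def test_harmonized_round_trip(tmp_path, three_snp_set):
    three_snp_set.drops["rsX"] = "palindromic-ambiguous"
    path = tmp_path / "h.tsv"
    write_harmonized(path, three_snp_set)
    back = read_harmonized(path)
    assert back.snp_ids == three_snp_set.snp_ids
    np.testing.assert_array_equal(back.gamma, three_snp_set.gamma)
    np.testing.assert_array_equal(back.se_gamma, three_snp_set.se_gamma)
    np.testing.assert_array_equal(back.beta, three_snp_set.beta)
    np.testing.assert_array_equal(back.se_beta, three_snp_set.se_beta)
    assert back.drops == three_snp_set.drops


@pytest.mark.parametrize("field,value", [
    ("se", 0.0), ("se", -1.0), ("pvalue", 0.0), ("pvalue", 1.5),
    ("effect_allele", "N"), ("eaf", 1.2), ("info", -0.1),
])
def test_record_invariants(field, value):
    kwargs = dict(snp_id="rs1", effect_allele="A", other_allele="G",
                  eaf=0.3, beta=0.1, se=0.01, pvalue=1e-9, info=0.9)
    kwargs[field] = value
    with pytest.raises(ValueError):
        SummaryRecord(**kwargs)


def test_identical_alleles_rejected():
    with pytest.raises(ValueError, match="identical"):
        make_record(ea="A", oa="A")
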