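"""Summary-statistics I/O, LD reading and allele harmonization."""

import numpy as np
import pytest

from protmr import (
    SNPRecord,
    harmonize_pair,
    is_palindromic,
    read_ld_matrix,
    read_sumstats,
    write_ld_matrix,
    write_sumstats,
)
from protmr.simulate import ScenarioConfig, simulate_region
from protmr.sumstats import FormatError, IntegrityError

from conftest import make_record, make_set


def write_table(path, rows, header="SNP\tCHR\tBP\tA1\tA2\tEAF\tBETA\tSE\tP\tN"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadSumstats:
    def test_well_formed_rows_become_records(self, tmp_path):
        f = tmp_path / "s.tsv"
        write_table(f, [
            "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.01\t1e-9\t5000",
            "rs2\t1\t200\tc\tt\t0.4\t-0.2\t0.02\t1e-5\t5000",
            "rs3\t2\t300\tG\tC\t0.1\t0.0\t0.03\t1.0\t5000",
        ])
        s = read_sumstats(f, trait_id="p1")
        assert len(s) == 3 and s.n_dropped == 0
        assert s.records["rs2"].effect_allele == "C"  # upper-cased
        assert s.records["rs3"].pvalue == 1.0

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        f = tmp_path / "s.tsv"
        write_table(f, [
            "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.0\t1e-9\t5000",   # se = 0
            "rs2\t1\t200\tA\tG\t0.2\t0.1\t0.01\t0.0\t5000",   # p = 0
            "rs3\t1\t300\tA\tG\t0.2\t0.1\t0.01\t0.5\t5000",
        ])
        s = read_sumstats(f)
        assert len(s) == 1 and s.n_dropped == 2

    def test_duplicate_ids_raise_listing_them(self, tmp_path):
        f = tmp_path / "s.tsv"
        write_table(f, [
            "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.01\t1e-9\t5000",
            "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.01\t1e-9\t5000",
        ])
        with pytest.raises(IntegrityError, match="rs1"):
            read_sumstats(f)

    def test_missing_mapped_column_names_it(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("SNP\tCHR\tBP\tA1\tA2\tBETA\tSE\tP\n" + "rs1\t1\t1\tA\tG\t0.1\t0.01\t0.5\n")
        with pytest.raises(FormatError, match="N"):
            read_sumstats(f)

    def test_comma_delimiter_and_column_aliases(self, tmp_path):
        f = tmp_path / "s.csv"
        f.write_text("rsid,chrom,bp,ea,oa,freq,b,stderr,pval,size\n"
                     "rs9,3,77,T,C,0.11,0.05,0.02,0.3,999\n")
        s = read_sumstats(f, column_map={
            "SNP": "rsid", "CHR": "chrom", "BP": "bp", "A1": "ea", "A2": "oa",
            "EAF": "freq", "BETA": "b", "SE": "stderr", "P": "pval", "N": "size"})
        assert s.records["rs9"].beta == 0.05

    def test_roundtrip_preserves_numeric_fields(self, tmp_path):
        region = simulate_region(ScenarioConfig(m_snps=25, seed=5))
        f = tmp_path / "round.tsv"
        write_sumstats(region.exposure, f)
        back = read_sumstats(f, trait_id=region.exposure.trait_id)
        for v, rec in region.exposure.records.items():
            got = back.records[v]
            for attr in ("pos", "beta", "se", "pvalue", "eaf", "n"):
                assert getattr(got, attr) == pytest.approx(getattr(rec, attr), abs=1e-12)


class TestLDMatrix:
    def test_identity_roundtrip(self, tmp_path):
        f = tmp_path / "ld.tsv"
        f.write_text("rs1\trs2\n1\t0\n0\t1\n")
        ld = read_ld_matrix(f)
        assert np.array_equal(ld.r, np.eye(2)) and ld.variant_ids == ["rs1", "rs2"]

    def test_small_asymmetry_averaged(self, tmp_path):
        f = tmp_path / "ld.tsv"
        f.write_text("rs1\trs2\n1\t0.5\n0.5000001\t1\n")
        ld = read_ld_matrix(f)
        assert ld.r[0, 1] == pytest.approx(0.50000005, abs=1e-12)
        assert ld.r[1, 0] == ld.r[0, 1]

    def test_large_asymmetry_rejected(self, tmp_path):
        f = tmp_path / "ld.tsv"
        f.write_text("rs1\trs2\n1\t0.5\n0.51\t1\n")
        with pytest.raises(IntegrityError):
            read_ld_matrix(f)

    def test_non_square_rejected(self, tmp_path):
        f = tmp_path / "ld.tsv"
        f.write_text("rs1\trs2\trs3\n1\t0\t0\n0\t1\t0\n")
        with pytest.raises(FormatError):
            read_ld_matrix(f)

    def test_reorder_to_expected_ids(self, tmp_path):
        f = tmp_path / "ld.tsv"
        f.write_text("rs1\trs2\n1\t0.3\n0.3\t1\n")
        ld = read_ld_matrix(f, ids=["rs2", "rs1"])
        assert ld.variant_ids == ["rs2", "rs1"]
        assert ld.r[0, 1] == pytest.approx(0.3)
        write_ld_matrix(ld, tmp_path / "out.tsv")
        again = read_ld_matrix(tmp_path / "out.tsv")
        assert np.allclose(again.r, ld.r)


@pytest.mark.parametrize("a1,a2,expected", [
    ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
    ("A", "G", False), ("A", "C", False), ("G", "T", False),
])
def test_is_palindromic(a1, a2, expected):
    assert is_palindromic(a1, a2) is expected


class TestHarmonize:
    def _pair(self, exp_alleles, out_alleles, out_beta=0.05, out_eaf=0.7):
        exp = make_set([make_record("rs1", a1=exp_alleles[0], a2=exp_alleles[1],
                                    beta=0.10)], trait_id="exp")
        out = make_set([make_record("rs1", a1=out_alleles[0], a2=out_alleles[1],
                                    beta=out_beta, eaf=out_eaf)], trait_id="out")
        return exp, out

    def test_swapped_alleles_flip_sign(self):
        exp, out = self._pair(("A", "G"), ("G", "A"))
        h = harmonize_pair(exp, out)
        assert h.by[0] == pytest.approx(-0.05)

    def test_identical_coding_unchanged(self):
        exp, out = self._pair(("A", "G"), ("A", "G"))
        h = harmonize_pair(exp, out)
        assert h.by[0] == pytest.approx(0.05) and h.bx[0] == pytest.approx(0.10)

    def test_complement_strand_same_orientation(self):
        exp, out = self._pair(("A", "G"), ("T", "C"))
        assert harmonize_pair(exp, out).by[0] == pytest.approx(0.05)

    def test_complement_strand_swapped(self):
        exp, out = self._pair(("A", "G"), ("C", "T"))
        assert harmonize_pair(exp, out).by[0] == pytest.approx(-0.05)

    def test_palindromic_dropped_and_counted(self):
        exp = make_set([make_record("rs1", a1="A", a2="T"),
                        make_record("rs2", a1="A", a2="G", pos=2000)], trait_id="e")
        out = make_set([make_record("rs1", a1="A", a2="T"),
                        make_record("rs2", a1="A", a2="G", pos=2000)], trait_id="o")
        h = harmonize_pair(exp, out)
        assert h.variant_ids == ["rs2"]
        assert h.drop_counts["palindromic"] == 1

    def test_irreconcilable_alleles_dropped(self):
        exp = make_set([make_record("rs1", a1="A", a2="G"),
                        make_record("rs2", a1="A", a2="G", pos=2000)], trait_id="e")
        out = make_set([make_record("rs1", a1="A", a2="C"),
                        make_record("rs2", a1="A", a2="G", pos=2000)], trait_id="o")
        h = harmonize_pair(exp, out)
        assert h.variant_ids == ["rs2"]
        assert h.drop_counts["allele_mismatch"] == 1

    def test_no_shared_variants_is_an_error(self):
        exp = make_set([make_record("rs1")], trait_id="e")
        out = make_set([make_record("rs2")], trait_id="o")
        with pytest.raises(IntegrityError):
            harmonize_pair(exp, out)

    def test_flipping_every_outcome_record_changes_nothing(self, rng):
        """Recoding the outcome's effect allele (swap alleles, negate beta,
        eaf -> 1-eaf) must produce the identical harmonized input."""
        records_e, records_o, records_o_flip = [], [], []
        for i in range(8):
            beta_o = rng.normal(0, 0.05)
            eaf = rng.uniform(0.1, 0.9)
            records_e.append(make_record(f"rs{i}", pos=1000 + i, a1="A", a2="G",
                                         beta=rng.normal(0.2, 0.05)))
            records_o.append(make_record(f"rs{i}", pos=1000 + i, a1="A", a2="G",
                                         beta=beta_o, eaf=eaf))
            records_o_flip.append(make_record(f"rs{i}", pos=1000 + i, a1="G", a2="A",
                                              beta=-beta_o, eaf=1 - eaf))
        exp = make_set(records_e, trait_id="e")
        h1 = harmonize_pair(exp, make_set(records_o, trait_id="o"))
        h2 = harmonize_pair(exp, make_set(records_o_flip, trait_id="o"))
        assert h1.variant_ids == h2.variant_ids
        assert np.allclose(h1.by, h2.by) and np.allclose(h1.sy, h2.sy)

    def test_harmonization_is_idempotent(self, small_region):
        h1 = harmonize_pair(small_region.exposure, small_region.outcome)
        # rebuild the outcome in the exposure's convention from h1 and redo
        out2 = make_set([
            make_record(v, pos=small_region.outcome.records[v].pos, a1="A", a2="G",
                        beta=float(h1.by[i]), se=float(h1.sy[i]),
                        p=small_region.outcome.records[v].pvalue,
                        n=small_region.outcome.records[v].n)
            for i, v in enumerate(h1.variant_ids)
        ], trait_id="o")
        h2 = harmonize_pair(small_region.exposure, out2)
        assert np.allclose(h1.by, h2.by) and h1.variant_ids == h2.variant_ids


def test_snprecord_validation():
    with pytest.raises(ValueError):
        SNPRecord("rs1", "1", 1, "A", "A", 0.1, 0.1, 0.01, 0.5, 100)
    with pytest.raises(ValueError):
        SNPRecord("rs1", "1", 1, "A", "G", 0.1, 0.1, -0.01, 0.5, 100)
    with pytest.raises(ValueError):
        SNPRecord("rs1", "1", 1, "A", "G", 1.5, 0.1, 0.01, 0.5, 100)
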