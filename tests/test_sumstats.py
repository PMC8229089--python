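import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methmr.coloc import ColocResult
from methmr.sumstats import (LDPanel, MonomorphicSNPError, SumStatsError,
                             harmonize, ld_matrix, read_ld_panel,
                             read_rare_variants, read_report, read_sumstats,
                             write_ld_panel, write_report)

from conftest import make_panel, make_sumstats


MA_HEADER = "SNP A1 A2 freq b se p N"


def write_ma(path, rows, header=MA_HEADER):
    path.write_text("\n".join([header] + rows) + "\n")


class TestReadMa:
    def test_three_row_file(self, tmp_path):
        f = tmp_path / "x.ma"
        write_ma(f, ["rs1 A G 0.3 0.1 0.02 5.7e-7 1000",
                     "rs2 C T 0.5 -0.2 0.05 6.3e-5 1000",
                     "rs3 G A 0.1 0.0 0.01 1.0 1000"])
        s = read_sumstats(f, format="ma")
        assert len(s) == 3
        assert s.record("rs2").beta == -0.2
        assert s.record("rs3").pvalue == 1.0

    def test_se_zero_rejected_with_line_number(self, tmp_path):
        f = tmp_path / "x.ma"
        write_ma(f, ["rs1 A G 0.3 0.1 0.0 1e-5 1000"])
        with pytest.raises(SumStatsError, match="line 2.*se"):
            read_sumstats(f, format="ma")

    def test_paper_scale_p_accepted(self, tmp_path):
        # z = 0.01 / 0.0016 = 6.25; the printed p = 3e-10 implies z = 6.29,
        # within the 20% relative tolerance on the z scale
        f = tmp_path / "x.ma"
        write_ma(f, ["rs1 A G 0.4 0.01 0.0016 3e-10 450000"])
        s = read_sumstats(f, format="ma", check_p_consistency=True)
        z_implied = stats.norm.isf(3e-10 / 2)
        assert abs(z_implied - 6.25) / 6.25 < 0.2
        assert len(s) == 1

    def test_grossly_inconsistent_p_rejected(self, tmp_path):
        f = tmp_path / "x.ma"
        write_ma(f, ["rs1 A G 0.4 0.01 0.0016 0.5 450000"])
        with pytest.raises(SumStatsError, match="inconsistent"):
            read_sumstats(f, format="ma")

    def test_missing_column_named(self, tmp_path):
        f = tmp_path / "x.ma"
        write_ma(f, ["rs1 A G 0.3 0.1 1e-5 1000"], header="SNP A1 A2 freq b p N")
        with pytest.raises(SumStatsError, match="se"):
            read_sumstats(f, format="ma")

    def test_non_numeric_beta_row_error(self, tmp_path):
        f = tmp_path / "x.ma"
        write_ma(f, ["rs1 A G 0.3 oops 0.02 1e-5 1000"])
        with pytest.raises(SumStatsError, match="line 2.*non-numeric b"):
            read_sumstats(f, format="ma")

    def test_duplicate_snp_id_error(self, tmp_path):
        f = tmp_path / "x.ma"
        write_ma(f, ["rs1 A G 0.3 0.1 0.02 5.7e-7 1000",
                     "rs1 A G 0.3 0.1 0.02 5.7e-7 1000"])
        with pytest.raises(SumStatsError, match="duplicate"):
            read_sumstats(f, format="ma")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_sumstats(tmp_path / "none.ma", format="ma")


class TestReadQtl:
    def test_groups_by_probe_and_cis(self, tmp_path):
        f = tmp_path / "q.tsv"
        hdr = "Probe ProbeChr ProbePos SNP Chr Pos A1 A2 freq b se p N"
        f.write_text("\n".join([
            hdr,
            "cgA 1 50000 rs1 1 49000 A G 0.3 0.5 0.05 1e-23 2000",
            "cgA 1 50000 rs2 1 51000 C T 0.4 0.1 0.05 0.0455 2000",
            "cgB 2 90000 rs9 2 90500 A C 0.2 0.2 0.05 6.3e-5 2000",
        ]) + "\n")
        tables = read_sumstats(f, format="qtl")
        assert [t.probe_id for t in tables] == ["cgA", "cgB"]
        assert len(tables[0].sset) == 2
        assert tables[1].probe_pos == 90000

    def test_outside_cis_window_rejected(self, tmp_path):
        f = tmp_path / "q.tsv"
        hdr = "Probe ProbeChr ProbePos SNP Chr Pos A1 A2 freq b se p N"
        f.write_text(hdr + "\ncgA 1 50000 rs1 1 9050000 A G 0.3 0.5 0.05 1e-23 2000\n")
        with pytest.raises(SumStatsError, match="cis window"):
            read_sumstats(f, format="qtl")


class TestHarmonize:
    def _panel(self):
        rng = np.random.default_rng(0)
        return make_panel(np.eye(3), 500, rng, ["rs1", "rs2", "rs3"])

    def test_allele_flip_identity(self):
        panel = self._panel()  # panel orientation A/G
        a = make_sumstats("a", ["rs1"], [0.2], [0.05], eaf=0.3)
        a.df.loc["rs1", ["effect_allele", "other_allele"]] = ["G", "A"]
        b = make_sumstats("b", ["rs1"], [0.1], [0.05], eaf=0.5)
        ha, hb = harmonize(a, b, panel)
        assert ha.record("rs1").beta == pytest.approx(-0.2)
        assert ha.record("rs1").eaf == pytest.approx(0.7)
        assert ha.record("rs1").effect_allele == "A"
        assert hb.record("rs1").beta == pytest.approx(0.1)

    def test_mismatched_alleles_dropped(self, caplog):
        panel = self._panel()
        a = make_sumstats("a", ["rs1", "rs2"], [0.2, 0.3], [0.05, 0.05])
        a.df.loc["rs2", ["effect_allele", "other_allele"]] = ["C", "T"]
        b = make_sumstats("b", ["rs1", "rs2"], [0.1, 0.1], [0.05, 0.05])
        with caplog.at_level("WARNING"):
            ha, hb = harmonize(a, b, panel)
        assert ha.snp_ids == ["rs1"]
        assert "mismatch" in caplog.text

    def test_ambiguous_dropped_by_default(self):
        rng = np.random.default_rng(1)
        panel = LDPanel(snp_index=[("rs1", "A", "T"), ("rs2", "A", "G")],
                        dosages=rng.integers(0, 3, size=(200, 2)).astype(float))
        a = make_sumstats("a", ["rs1", "rs2"], [0.2, 0.3], [0.05, 0.05])
        a.df.loc["rs1", ["effect_allele", "other_allele"]] = ["A", "T"]
        b = make_sumstats("b", ["rs1", "rs2"], [0.1, 0.1], [0.05, 0.05])
        b.df.loc["rs1", ["effect_allele", "other_allele"]] = ["A", "T"]
        ha, hb = harmonize(a, b, panel)
        assert "rs1" not in ha.snp_ids and "rs1" not in hb.snp_ids

    def test_empty_intersection_error(self):
        panel = self._panel()
        a = make_sumstats("a", ["rs1"], [0.2], [0.05])
        b = make_sumstats("b", ["rsX"], [0.1], [0.05])
        with pytest.raises(SumStatsError, match="no shared SNPs"):
            harmonize(a, b, panel)

    def test_idempotent(self, causal_locus):
        ha1, hb1 = harmonize(causal_locus.mqtl.sset, causal_locus.gwas,
                             causal_locus.panel)
        ha2, hb2 = harmonize(ha1, hb1, causal_locus.panel)
        pd.testing.assert_frame_equal(ha1.df, ha2.df)
        pd.testing.assert_frame_equal(hb1.df, hb2.df)


class TestLdMatrix:
    def test_diagonal_and_duplicate(self):
        rng = np.random.default_rng(2)
        dos = rng.integers(0, 3, size=(100, 2)).astype(float)
        dos = np.column_stack([dos, dos[:, 0]])
        panel = LDPanel(snp_index=[("a", "A", "G"), ("b", "A", "G"),
                                   ("c", "A", "G")], dosages=dos)
        R = ld_matrix(panel, ["a", "b", "c"])
        assert R[0, 0] == 1.0 and R[1, 1] == 1.0
        assert R[0, 2] == pytest.approx(1.0)

    def test_independent_snps_low_r_at_503(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, 0.3, size=(503, 20)).astype(float)
        panel = LDPanel(snp_index=[(f"s{i}", "A", "G") for i in range(20)],
                        dosages=dos)
        R = ld_matrix(panel, [f"s{i}" for i in range(20)])
        off = R[np.triu_indices(20, 1)]
        # null sampling bound: sd = 1/sqrt(503) ~ 0.045, so 0.15 is ~3.4 sd
        assert np.abs(off).max() < 0.15

    def test_monomorphic_error_names_snp(self):
        panel = LDPanel(snp_index=[("good", "A", "G"), ("mono", "A", "G")],
                        dosages=np.column_stack([
                            np.random.default_rng(0).binomial(2, .3, 50),
                            np.ones(50)]).astype(float))
        with pytest.raises(MonomorphicSNPError, match="mono"):
            ld_matrix(panel, ["good", "mono"])

    def test_small_panel_warns(self):
        rng = np.random.default_rng(4)
        panel = LDPanel(snp_index=[("a", "A", "G")],
                        dosages=rng.binomial(2, .4, (10, 1)).astype(float))
        with pytest.warns(UserWarning, match="noisy"):
            ld_matrix(panel, ["a"])

    def test_psd_and_shrinkage(self, causal_locus):
        snps = causal_locus.panel.snp_index[:30]
        ids = [s[0] for s in snps]
        R = ld_matrix(causal_locus.panel, ids)
        assert np.allclose(R, R.T)
        assert np.linalg.eigvalsh(R).min() > -1e-8
        Rs = ld_matrix(causal_locus.panel, ids, shrinkage=0.1)
        assert np.linalg.eigvalsh(Rs).min() > 0
        assert np.all(np.diag(Rs) == 1.0)


class TestReports:
    def test_empty_header_only(self, tmp_path):
        f = tmp_path / "r.tsv"
        write_report([], f, kind=ColocResult)
        assert f.read_text().splitlines() == ["\t".join(ColocResult.REPORT_COLUMNS)]

    def test_coloc_row_roundtrip(self, tmp_path):
        r = ColocResult(probe_id="cgA", probe_chr="1", probe_pos=123,
                        top_snp="rs1", b_smr=0.123456789012,
                        se_smr=0.01, p_smr=4.2e-10, p_heidi=0.51,
                        n_heidi_snps=7, passed=True)
        f = tmp_path / "r.tsv"
        write_report([r], f, kind=ColocResult)
        df = read_report(f)
        assert len(df) == 1
        assert df.loc[0, "probe_id"] == "cgA"
        assert df.loc[0, "b_smr"] == pytest.approx(r.b_smr, rel=1e-9)
        assert df.loc[0, "p_smr"] == pytest.approx(4.2e-10, rel=1e-9)
        assert bool(df.loc[0, "passed"]) is True

    def test_ld_panel_roundtrip(self, tmp_path, causal_locus):
        sub = LDPanel(snp_index=causal_locus.panel.snp_index[:5],
                      dosages=causal_locus.panel.dosages[:50, :5])
        f = tmp_path / "panel.tsv"
        write_ld_panel(sub, f)
        back = read_ld_panel(f)
        assert back.snp_index == sub.snp_index
        np.testing.assert_allclose(back.dosages, sub.dosages)

    def test_rare_variant_reader(self, tmp_path):
        f = tmp_path / "rv.tsv"
        f.write_text("variant_id\tchrom\tpos\tref\talt\tcondition\n"
                     "v1\t2\t25400100\tC\tT\tobesity\n")
        rv = read_rare_variants(f)
        assert len(rv) == 1 and rv.df.loc[0, "pos"] == 25400100


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_harmonize_idempotent_property(seed):
    rng = np.random.default_rng(seed)
    m = 6
    panel = make_panel(np.eye(m), 300, rng)
    ids = [s[0] for s in panel.snp_index]
    a = make_sumstats("a", ids, rng.normal(0, .2, m), rng.uniform(.01, .1, m))
    b = make_sumstats("b", ids, rng.normal(0, .2, m), rng.uniform(.01, .1, m))
    # scramble some orientations
    flip = rng.random(m) < 0.5
    a.df.loc[flip, "beta"] *= -1
    a.df.loc[flip, ["effect_allele", "other_allele"]] = ["G", "A"]
    a.df.loc[flip, "eaf"] = 1 - a.df.loc[flip, "eaf"]
    ha1, hb1 = harmonize(a, b, panel)
    ha2, hb2 = harmonize(ha1, hb1, panel)
    pd.testing.assert_frame_equal(ha1.df, ha2.df)
    pd.testing.assert_frame_equal(hb1.df, hb2.df)
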