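"""I/O, harmonisation, QC filtering and genomic-control correction."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stratinteract as si
from stratinteract.sumstats import SumstatsError

from conftest import small_study_table


META = si.StudyMeta(study_id="S1", stratum="M_le50",
                    imputation_software="MACH")


class TestReadWrite:
    def test_round_trip_identity(self, tmp_path):
        df = small_study_table(n=3)
        path = tmp_path / "study.tsv"
        si.write_sumstats(df, path)
        back, dropped = si.read_sumstats(path)
        assert dropped == 0
        pd.testing.assert_frame_equal(
            back[["MARKER", "CHR", "POS", "BETA", "SE", "N"]],
            df[["MARKER", "CHR", "POS", "BETA", "SE", "N"]])

    def test_unparseable_row_dropped_and_counted(self, tmp_path):
        path = tmp_path / "study.tsv"
        path.write_text("CHR\tPOS\tEA\tOA\tBETA\tSE\tN\n"
                        "1\t100\tA\tG\t0.1\t0.05\t1000\n"
                        "1\t200\tA\tG\tNA\t0.05\t1000\n"
                        "1\t300\tA\tG\t-0.2\t0.04\t1000\n")
        df, dropped = si.read_sumstats(path)
        assert len(df) == 2 and dropped == 1
        assert list(df["POS"]) == [100, 300]

    def test_column_map_renames_headers(self, tmp_path):
        path = tmp_path / "study.csv"
        path.write_text("chr,pos,A1,A2,Effect,StdErr,NMISS\n"
                        "2,500,a,g,0.12,0.03,2500\n")
        df, _ = si.read_sumstats(path, column_map={
            "A1": "EA", "A2": "OA", "Effect": "BETA",
            "StdErr": "SE", "NMISS": "N"})
        row = df.iloc[0]
        assert row["BETA"] == 0.12 and row["SE"] == 0.03 and row["N"] == 2500
        assert row["EA"] == "A" and row["OA"] == "G"  # upper-cased

    def test_missing_mandatory_column_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("CHR\tPOS\tEA\tOA\tBETA\tN\n1\t1\tA\tG\t0.1\t10\n")
        with pytest.raises(SumstatsError, match="SE"):
            si.read_sumstats(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("CHR\tPOS\tEA\tOA\tBETA\tSE\tN\n")
        with pytest.raises(SumstatsError):
            si.read_sumstats(path)


class TestHarmonize:
    def test_marker_renamed_to_chr_pos(self):
        df = small_study_table(n=1)
        df.loc[0, ["MARKER", "CHR", "POS"]] = ["rs2820443", 1, 217820132]
        out = si.harmonize_markers(df)
        assert out.loc[0, "MARKER"] == "1:217820132"

    def test_allele_swap_flips_beta_and_eaf(self):
        df = small_study_table(n=1)
        df.loc[0, ["EA", "OA", "BETA", "EAF"]] = ["G", "A", 0.05, 0.3]
        ref = pd.DataFrame({"MARKER": [df.loc[0, "MARKER"]],
                            "EA": ["A"], "OA": ["G"]})
        out = si.harmonize_markers(df, reference=ref)
        assert out.loc[0, "BETA"] == pytest.approx(-0.05)
        assert out.loc[0, "EAF"] == pytest.approx(0.7)
        assert (out.loc[0, "EA"], out.loc[0, "OA"]) == ("A", "G")

    def test_double_flip_is_identity(self, rng):
        df = small_study_table(n=20, seed=3)
        ref_swapped = df[["MARKER"]].assign(EA=df["OA"], OA=df["EA"])
        ref_orig = df[["MARKER", "EA", "OA"]]
        once = si.harmonize_markers(df, reference=ref_swapped)
        twice = si.harmonize_markers(once, reference=ref_orig)
        np.testing.assert_allclose(twice["BETA"], df["BETA"])
        np.testing.assert_allclose(twice["EAF"], df["EAF"])

    def test_duplicate_kept_by_quality_then_row_order(self):
        df = small_study_table(n=3)
        df.loc[1, ["CHR", "POS"]] = df.loc[0, ["CHR", "POS"]]
        df.loc[2, ["CHR", "POS"]] = df.loc[0, ["CHR", "POS"]]
        df["INFO"] = [0.5, 0.9, 0.9]
        df["BETA"] = [1.0, 2.0, 3.0]
        out = si.harmonize_markers(df)
        assert len(out) == 1
        assert out.loc[0, "BETA"] == 2.0  # higher quality, earlier row

    def test_incompatible_alleles_excluded_and_counted(self):
        df = small_study_table(n=2)
        df.loc[0, ["EA", "OA"]] = ["A", "C"]
        ref = pd.DataFrame({"MARKER": df["MARKER"], "EA": "A", "OA": "G"})
        report = si.QCReport()
        out = si.harmonize_markers(df, reference=ref, report=report)
        assert len(out) == 1 and report.incompatible_alleles == 1


class TestQC:
    def test_removal_rules(self):
        df = small_study_table(n=6)
        df["EAF"] = [0.0, 0.0001, 0.3, 0.3, 0.3, 0.3]   # mono; MAF*N=1
        df["N"] = 10_000
        df["IMPUTED"] = [True, True, True, True, False, False]
        df["INFO"] = [0.9, 0.9, 0.2, 0.9, np.nan, np.nan]  # one below MACH 0.3
        df["CALLRATE"] = [1, 1, 1, 1, 0.90, 0.99]
        df["HWE_P"] = [1, 1, 1, 1, 0.5, 1e-6]
        out, rep = si.apply_qc(df, META)
        assert rep.monomorphic == 1 and rep.low_mac == 1
        assert rep.low_quality == 1 and rep.low_callrate == 1
        assert rep.hwe_failure == 1
        assert rep.removed + rep.retained == rep.input_count
        assert len(out) == 1

    def test_plink_quality_boundary_retained(self):
        df = small_study_table(n=1)
        df["INFO"], df["IMPUTED"] = 0.85, True
        meta = si.StudyMeta(study_id="S", stratum="M_le50",
                            imputation_software="PLINK")
        out, _ = si.apply_qc(df, meta)
        assert len(out) == 1  # 0.85 >= PLINK floor 0.8

    def test_unknown_imputation_software_raises(self):
        df = small_study_table(n=1)
        meta = si.StudyMeta(study_id="S", stratum="M_le50")
        with pytest.raises(SumstatsError, match="software"):
            si.apply_qc(df, meta)

    def test_idempotent(self):
        df = small_study_table(n=40, seed=5)
        df.loc[::3, "EAF"] = 0.0001
        once, _ = si.apply_qc(df, META)
        twice, rep = si.apply_qc(once, META)
        assert rep.removed == 0
        pd.testing.assert_frame_equal(once, twice)


class TestGenomicControl:
    def test_lambda_null_calibration(self, rng):
        n = 100_000
        df = small_study_table(n=10)
        df = pd.DataFrame({
            "MARKER": "x", "BETA": rng.standard_normal(n) * 0.01,
            "SE": 0.01})
        lam = si.estimate_lambda(df)
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_lambda_scale_equivariance(self, rng):
        z = rng.standard_normal(50_000)
        df = pd.DataFrame({"MARKER": "x", "BETA": z * 0.01, "SE": 0.01})
        df2 = df.assign(BETA=df["BETA"] * np.sqrt(1.21))
        assert si.estimate_lambda(df2) == pytest.approx(
            1.21 * si.estimate_lambda(df), rel=1e-12)

    def test_lambda_too_few_records_raises(self):
        with pytest.raises(SumstatsError):
            si.estimate_lambda(pd.DataFrame({"MARKER": [], "BETA": [],
                                             "SE": []}))

    def test_lambda_subset_restricts_markers(self):
        df = pd.DataFrame({
            "MARKER": [f"m{i}" for i in range(400)],
            "BETA": [0.01] * 200 + [0.03] * 200, "SE": 0.01})
        lam_all = si.estimate_lambda(df)
        lam_sub = si.estimate_lambda(df, subset=[f"m{i}" for i in range(200)])
        assert lam_sub < lam_all

    @pytest.mark.parametrize("lam", [1.0, 0.9])
    def test_gc_identity_and_clamp(self, lam):
        df = small_study_table(n=5, seed=2)
        out = si.gc_correct(df, lam)
        np.testing.assert_allclose(out["SE"], df["SE"])

    def test_gc_hand_value(self):
        df = pd.DataFrame({"MARKER": ["1:1"], "BETA": [0.05], "SE": [0.01]})
        out = si.gc_correct(df, 1.21)
        assert out.loc[0, "SE"] == pytest.approx(0.011)
        z = 0.05 / 0.011
        assert out.loc[0, "P"] == pytest.approx(2 * stats.norm.sf(z), rel=1e-12)

    def test_gc_never_decreases_p(self, rng):
        df = small_study_table(n=30, seed=9)
        df["P"] = 2 * stats.norm.sf(np.abs(df["BETA"] / df["SE"]))
        out = si.gc_correct(df, 1.4)
        assert (out["P"] >= df["P"] - 1e-15).all()

    def test_post_gc_lambda_is_one(self, rng):
        n = 100_000
        lam_true = 1.3
        df = pd.DataFrame({
            "MARKER": "x",
            "BETA": rng.standard_normal(n) * 0.01 * np.sqrt(lam_true),
            "SE": 0.01})
        lam = si.estimate_lambda(df)
        corrected = si.gc_correct(df, lam)
        assert si.estimate_lambda(corrected) == pytest.approx(1.0, abs=0.02)
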