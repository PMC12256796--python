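"""Sumstats I/O, phenotype adjustments, lead regions, rescaling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import xdosage as xd
from xdosage import sumstats as sc


def toy_table(rows):
    """rows: (snp, chr, bp, p_f) tuples -> minimal native table."""
    n = len(rows)
    return pd.DataFrame({
        "SNP": [r[0] for r in rows], "CHR": [r[1] for r in rows],
        "BP": [r[2] for r in rows], "A1": "A", "A2": "G", "A1FREQ": 0.2,
        "BETA_F": 0.01, "SE_F": 0.005, "P_F": [r[3] for r in rows], "N_F": 1000,
        "BETA_M": 0.01, "SE_M": 0.005, "P_M": 1.0, "N_M": 1000,
        "REGION": "autosome",
    })


class TestIO:
    def test_roundtrip_identity(self, fullxci_sumstats, tmp_path):
        _, ss = fullxci_sumstats
        path = tmp_path / "ss.tsv"
        sc.write_sumstats(ss, path)
        back = sc.read_sumstats(path)
        pd.testing.assert_frame_equal(
            back[sc.MANDATORY_COLUMNS], ss[sc.MANDATORY_COLUMNS],
            check_exact=False, rtol=1e-12)

    def test_missing_column_names_the_column(self, tmp_path):
        df = toy_table([("rs1", "1", 100, 0.5)]).drop(columns=["SE_F"])
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(sc.SumStatError, match="SE_F"):
            sc.read_sumstats(path)

    def test_zero_se_row_rejected_with_log(self, tmp_path, caplog):
        import logging
        df = toy_table([("rs1", "1", 100, 0.5), ("rs2", "1", 200, 0.5)])
        df.loc[1, "SE_F"] = 0.0
        path = tmp_path / "ss.tsv"
        df.to_csv(path, sep="\t", index=False)
        with caplog.at_level(logging.WARNING, logger="xdosage.sumstats"):
            out = sc.read_sumstats(path)
        assert list(out["SNP"]) == ["rs1"]
        assert any("rs2" in r.message for r in caplog.records)

    def test_frequency_folding_flips_sign_and_alleles(self, tmp_path):
        df = toy_table([("rs1", "1", 100, 0.5)])
        df["A1FREQ"] = 0.7
        df["BETA_F"] = 0.05
        df["BETA_M"] = -0.02
        path = tmp_path / "ss.tsv"
        df.to_csv(path, sep="\t", index=False)
        out = sc.read_sumstats(path)
        assert out.loc[0, "A1FREQ"] == pytest.approx(0.3)
        assert out.loc[0, "BETA_F"] == pytest.approx(-0.05)
        assert out.loc[0, "BETA_M"] == pytest.approx(0.02)
        assert (out.loc[0, "A1"], out.loc[0, "A2"]) == ("G", "A")
        # folding is idempotent through a second round trip
        sc.write_sumstats(out, path)
        again = sc.read_sumstats(path)
        pd.testing.assert_frame_equal(again, out)

    def test_single_sex_dialect_and_merge(self, tmp_path):
        df = pd.DataFrame({
            "SNP": ["rs1"], "CHR": ["X"], "BP": [50_000_000],
            "ALLELE1": ["A"], "ALLELE0": ["G"], "A1FREQ": [0.1],
            "BETA": [0.03], "SE": [0.01], "P_BOLT_LMM": [0.002], "N": [5000],
        })
        p = tmp_path / "bolt.tsv"
        df.to_csv(p, sep="\t", index=False)
        f = sc.read_sumstats(p, dialect="bolt-like", sex="F")
        m = sc.read_sumstats(p, dialect="bolt-like", sex="M")
        assert f.loc[0, "REGION"] == "chrX_nonPAR"
        merged = sc.merge_sex_tables(f, m)
        assert {"BETA_F", "BETA_M"} <= set(merged.columns)
        with pytest.raises(sc.SumStatError):
            sc.read_sumstats(p, dialect="bolt-like")


class TestPhenotypePrep:
    def test_int_removes_6sd_outliers_first(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        x[0] = x[1:].mean() + 7 * x[1:].std()
        out = sc.inverse_normal_transform(x)
        assert np.isnan(out[0])
        kept = out[1:]
        assert abs(np.nanmean(kept)) < 0.01
        assert np.nanstd(kept) == pytest.approx(1.0, rel=0.05)

    def test_int_preserves_rank_order(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(size=300)
        out = sc.inverse_normal_transform(x)
        ok = np.isfinite(out)          # extreme-tail points removed as outliers
        rho = stats.spearmanr(x[ok], out[ok]).statistic
        assert rho == pytest.approx(1.0)

    def test_int_output_is_normal(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(size=1000)   # heavily skewed input
        out = sc.inverse_normal_transform(x)
        assert stats.shapiro(out[np.isfinite(out)]).pvalue > 0.01

    def test_int_identical_values_error(self):
        with pytest.raises(ValueError):
            sc.inverse_normal_transform([1.0, 1.0, 1.0, 1.0])

    @pytest.mark.parametrize("trait,value,flag,expected", [
        ("systolic", 130.0, True, 145.0),
        ("diastolic", 80.0, False, 80.0),
        ("diastolic", 80.0, True, 90.0),
    ])
    def test_blood_pressure_offsets(self, trait, value, flag, expected):
        out = sc.adjust_blood_pressure([value], trait, [flag])
        assert out[0] == pytest.approx(expected)

    def test_blood_pressure_unknown_trait(self):
        with pytest.raises(ValueError):
            sc.adjust_blood_pressure([1.0], "pulse", [True])

    def test_statin_factor_arithmetic(self):
        res = sc.statin_adjust([1.0, 2.0], [1.2, 2.4], [2.4, 3.0],
                               [True, False])
        assert res.factor == pytest.approx(1.2)
        if res.applied:   # two pairs rarely reach p < 0.05
            assert res.values[0] == pytest.approx(2.0)
        else:
            assert res.values[0] == pytest.approx(2.4)

    def test_statin_identical_pairs_no_adjustment(self):
        res = sc.statin_adjust([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                               [5.0], [True])
        assert res.factor == pytest.approx(1.0)
        assert not res.applied
        assert res.values[0] == 5.0

    def test_statin_recovery_simulation(self):
        rng = np.random.default_rng(3)
        pre = rng.uniform(1, 3, 100)
        on = pre * 1.3 + rng.normal(0, 0.01, 100)
        pop = np.array([2.6, 1.0])
        res = sc.statin_adjust(pre, on, pop, [True, False])
        assert res.applied
        assert res.factor == pytest.approx(1.3, rel=0.02)
        assert res.values[0] == pytest.approx(2.6 / res.factor)
        assert res.values[1] == 1.0

    def test_statin_errors(self):
        with pytest.raises(ValueError):
            sc.statin_adjust([0.0, 1.0], [1.0, 1.0], [1.0], [True])
        with pytest.raises(ValueError):
            sc.statin_adjust([], [], [1.0], [True])


def brute_force_regions(bps, ps, threshold, span):
    """Independent O(n^2) interval-merge oracle on one chromosome."""
    half = span // 2
    sig = [(bp, p) for bp, p in zip(bps, ps) if p < threshold]
    intervals = [[bp - half, bp + half, [(bp, p)]] for bp, p in sorted(sig)]
    merged = []
    for iv in intervals:
        if merged and iv[0] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv[1])
            merged[-1][2].extend(iv[2])
        else:
            merged.append(iv)
    out = []
    for lo, hi, members in merged:
        lead = min(members, key=lambda t: (t[1], t[0]))
        out.append((lo, hi, lead[0]))
    return out


class TestLeadRegions:
    def test_worked_example_two_regions(self):
        df = toy_table([("a", "2", 1_000_000, 1e-9),
                        ("b", "2", 1_300_000, 1e-10),
                        ("c", "2", 5_000_000, 1e-9),
                        ("d", "2", 2_000_000, 0.5)])
        regions = sc.identify_lead_variants(df, sex="F")
        assert len(regions) == 2
        assert regions[0].lead_bp == 1_300_000
        assert regions[1].lead_bp == 5_000_000

    def test_no_significant_hits_empty(self):
        df = toy_table([("a", "1", 100, 0.5)])
        assert sc.identify_lead_variants(df, sex="F") == []

    def test_close_pair_merges(self):
        df = toy_table([("a", "1", 1_000_000, 1e-9), ("b", "1", 1_100_000, 1e-9)])
        assert len(sc.identify_lead_variants(df, sex="F")) == 1

    @given(st.lists(st.tuples(st.integers(1, 10_000_000),
                              st.sampled_from([1e-10, 1e-9, 1e-4, 0.5])),
                    min_size=0, max_size=30, unique_by=lambda t: t[0]))
    def test_matches_brute_force_oracle(self, items):
        rows = [(f"s{i}", "3", bp, p) for i, (bp, p) in enumerate(items)]
        df = toy_table(rows) if rows else toy_table([("x", "3", 1, 0.9)])
        got = sc.identify_lead_variants(df, sex="F")
        exp = brute_force_regions([r[2] for r in rows], [r[3] for r in rows],
                                  5e-8, 500_000)
        assert [(r.start, r.end, r.lead_bp) for r in got] == exp

    def test_order_independence(self):
        rng = np.random.default_rng(4)
        rows = [(f"s{i}", "1", int(bp), float(p))
                for i, (bp, p) in enumerate(zip(
                    rng.integers(1, 20_000_000, 40),
                    rng.choice([1e-9, 1e-12, 0.3], 40)))]
        df = toy_table(rows)
        a = sc.identify_lead_variants(df, sex="F")
        b = sc.identify_lead_variants(df.sample(frac=1, random_state=1), sex="F")
        assert a == b


class TestActiveAlleleScale:
    def test_nonpar_doubled_par_untouched(self):
        df = toy_table([("x1", "X", 50_000_000, 0.5), ("p1", "X", 1_000_000, 0.5),
                        ("a1", "1", 1000, 0.5)])
        df["REGION"] = ["chrX_nonPAR", "chrX_PAR", "autosome"]
        df.loc[0, "BETA_F"], df.loc[0, "SE_F"] = 0.05, 0.01
        out = sc.active_allele_scale(df)
        assert out.loc[0, "BETA_F"] == pytest.approx(0.10)
        assert out.loc[0, "SE_F"] == pytest.approx(0.02)
        assert out.loc[1, "BETA_F"] == pytest.approx(0.01)
        assert out.loc[2, "BETA_F"] == pytest.approx(0.01)
        # z-scores and p-values preserved exactly
        assert np.allclose(out["BETA_F"] / out["SE_F"], df["BETA_F"] / df["SE_F"])
        assert np.allclose(out["P_F"], df["P_F"])

    def test_double_application_guarded(self):
        df = toy_table([("x1", "X", 50_000_000, 0.5)])
        df["REGION"] = "chrX_nonPAR"
        once = sc.active_allele_scale(df)
        with pytest.raises(ValueError):
            sc.active_allele_scale(once)


class TestEqualizePower:
    def test_se_inflation_halves_male_ncp(self):
        df = toy_table([("x1", "X", 50_000_000, 0.5)])
        df["REGION"] = "chrX_nonPAR"
        out = sc.equalize_power_males(df, mode="se-inflate")
        assert out.loc[0, "SE_M"] == pytest.approx(df.loc[0, "SE_M"] * math.sqrt(2))
        z_old = df.loc[0, "BETA_M"] / df.loc[0, "SE_M"]
        z_new = out.loc[0, "BETA_M"] / out.loc[0, "SE_M"]
        assert z_new**2 == pytest.approx(z_old**2 / 2)
        # females untouched
        assert out.loc[0, "SE_F"] == df.loc[0, "SE_F"]

    def test_downsample_mode(self, small_cohort):
        _, cohort = small_cohort
        idx = sc.equalize_power_males(mode="individual-downsample",
                                      cohort=cohort, seed=5)
        assert idx.size == cohort.n_males // 2
        idx2 = sc.equalize_power_males(mode="individual-downsample",
                                       cohort=cohort, seed=5)
        assert np.array_equal(idx, idx2)
        with pytest.raises(ValueError):
            sc.equalize_power_males(mode="individual-downsample")


class TestBootstrapMedianCI:
    def test_constant_vector_collapses(self):
        med, lo, hi = sc.bootstrap_median_ci([3.0] * 10, n_boot=200, seed=0)
        assert med == lo == hi == 3.0

    def test_coverage_near_nominal(self):
        rng = np.random.default_rng(6)
        hits = 0
        reps = 200
        for i in range(reps):
            x = rng.standard_normal(60)
            _, lo, hi = sc.bootstrap_median_ci(x, n_boot=300, seed=i)
            hits += lo <= 0.0 <= hi
        assert hits / reps >= 0.88
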