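"""Heritability estimators, XI, zero-tests, BH, LD scores."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import xdosage as xd
from xdosage import heritability as herit


def direct(seed, m=1000, n=20_000, h2=0.05, pic=0.1):
    cfg = xd.SimConfig(seed=seed, m_x=m, n_males=n, n_females=n,
                       h2_x=h2, causal_fraction_x=pic)
    return cfg, xd.simulate_sumstats_direct(cfg)


class TestEffectMixture:
    def test_fixed_pic_reduces_to_method_of_moments(self):
        _, ss = direct(1, m=2000, h2=0.1, pic=1.0)
        est = herit.fit_effect_mixture(ss, "female", "chrX", fix_pi_c=1.0,
                                       se_method="none", n_restarts=2)
        u, s, _ = herit._standardized(ss, "female", "chrX")
        mom = est.M * float(np.mean(u**2 - s**2))
        assert est.h2 == pytest.approx(mom, rel=1e-4)
        assert est.pi_c == 1.0

    @pytest.mark.parametrize("h2,pic", [(0.0, 0.1), (0.05, 0.1),
                                        (0.2, 1.0), (0.05, 0.01)])
    def test_parameter_recovery_across_architectures(self, h2, pic):
        reps = 12
        ests = np.empty(reps)
        for i in range(reps):
            _, ss = direct(1000 * int(h2 * 100 + 1) + i, m=1000, h2=h2, pic=pic)
            ests[i] = herit.fit_effect_mixture(
                ss, "female", "chrX", se_method="none", n_restarts=3).h2
        se = ests.std(ddof=1) / math.sqrt(reps)
        slack = 0.003 if h2 == 0 else 0.0   # boundary bias allowance at h2=0
        assert abs(ests.mean() - h2) < 3 * se + slack

    def test_h2_decomposition_identity(self):
        _, ss = direct(3)
        est = herit.fit_effect_mixture(ss, "male", "chrX", se_method="none",
                                       n_restarts=3)
        assert est.h2 == pytest.approx(est.M * est.pi_c * est.sigma2)

    def test_bootstrap_and_info_ses_agree(self):
        _, ss = direct(4, m=800)
        kw = dict(n_restarts=2)
        boot = herit.fit_effect_mixture(ss, "female", "chrX",
                                        se_method="bootstrap", n_boot=60,
                                        seed=1, **kw)
        info = herit.fit_effect_mixture(ss, "female", "chrX",
                                        se_method="info", **kw)
        assert boot.se == pytest.approx(info.se, rel=0.5)
        assert boot.se > 0

    def test_small_m_warns(self):
        _, ss = direct(5, m=40, h2=0.01)
        with pytest.warns(UserWarning, match="fewer than 50"):
            herit.fit_effect_mixture(ss, "female", "chrX", se_method="none",
                                     n_restarts=2)


class TestChi2H2:
    def test_null_estimate_near_zero(self):
        _, ss = direct(6, h2=0.0)
        est = herit.chi2_h2(ss, "female", "chrX")
        assert est.h2 < 0.01

    def test_agrees_with_mixture_on_shared_simulations(self):
        diffs, ses = [], []
        for i in range(6):
            _, ss = direct(700 + i, m=1500, h2=0.08)
            a = herit.chi2_h2(ss, "female", "chrX")
            b = herit.fit_effect_mixture(ss, "female", "chrX",
                                         se_method="none", n_restarts=3)
            diffs.append(a.h2 - b.h2)
            ses.append(a.se)
        assert abs(np.mean(diffs)) < 3 * np.mean(ses)

    def test_invariant_to_sample_size_in_expectation(self):
        means = []
        for n in (10_000, 20_000):
            vals = [herit.chi2_h2(direct(900 + n + i, m=1000, n=n, h2=0.06)[1],
                                  "female", "chrX").h2 for i in range(8)]
            means.append(np.mean(vals))
        assert means[0] == pytest.approx(means[1], abs=0.01)

    def test_missing_n_errors(self):
        _, ss = direct(8, m=100)
        ss = ss.drop(columns=["N_F"])
        with pytest.raises(ValueError):
            herit.chi2_h2(ss, "female", "chrX")


class TestXI:
    def test_point_value_and_zero_se(self):
        ex = herit.H2Estimate("t", "male", "chrX", 0.02, 0.0)
        ea = herit.H2Estimate("t", "male", "autosomes", 0.40, 0.0)
        est = herit.xi(ex, ea)
        assert est.xi == pytest.approx(0.05)
        assert est.se == 0.0

    def test_equal_relative_ses(self):
        r = 0.1
        ex = herit.H2Estimate("t", "male", "chrX", 0.02, 0.02 * r)
        ea = herit.H2Estimate("t", "male", "autosomes", 0.40, 0.40 * r)
        est = herit.xi(ex, ea)
        assert est.se == pytest.approx(est.xi * r * math.sqrt(2))

    def test_delta_se_matches_monte_carlo(self):
        rng = np.random.default_rng(9)
        hx, sx = 0.20, 0.008
        ha, sa = 0.40, 0.012
        draws = rng.normal(hx, sx, 200_000) / rng.normal(ha, sa, 200_000)
        est = herit.xi(herit.H2Estimate("t", "male", "chrX", hx, sx),
                       herit.H2Estimate("t", "male", "autosomes", ha, sa))
        assert est.se == pytest.approx(draws.std(), rel=0.10)

    def test_errors(self):
        with pytest.raises(ValueError):
            herit.xi(herit.H2Estimate("t", "m", "chrX", 0.1, 0.1),
                     herit.H2Estimate("t", "m", "autosomes", 0.0, 0.1))
        with pytest.raises(ValueError):
            herit.xi(herit.H2Estimate("t", "m", "chrX", -0.1, 0.1),
                     herit.H2Estimate("t", "m", "autosomes", 0.2, 0.1))


class TestCombined:
    def test_mean_and_se(self):
        m = herit.H2Estimate("t", "male", "chrX", 0.02, 0.004)
        f = herit.H2Estimate("t", "female", "chrX", 0.01, 0.003)
        c = herit.combined_estimate(m, f)
        assert c.h2 == pytest.approx(0.015)
        assert c.se == pytest.approx(math.sqrt(0.004**2 + 0.003**2) / 2)
        e = herit.H2Estimate("t", "female", "chrX", 0.02, 0.004)
        assert herit.combined_estimate(m, e).se == pytest.approx(0.004 / math.sqrt(2))
        with pytest.raises(ValueError):
            herit.combined_estimate(m, herit.H2Estimate("s", "female", "chrX", 0.01, 0.1))

    def test_combined_xi_is_1p5x_female_under_full_xci(self):
        """Fig-1 algebra: male XI = 2x female XI, so combined = 1.5x female."""
        xis_c, xis_f = [], []
        for i in range(6):
            cfg = xd.SimConfig(seed=50 + i, m_auto=1500, m_x=750, h2_auto=0.2,
                               h2_x=None, n_males=20_000, n_females=20_000)
            ss = xd.simulate_sumstats_direct(cfg)
            ests = {}
            for stratum in ("male", "female"):
                ests[stratum] = {
                    r: herit.fit_effect_mixture(ss, stratum, r, se_method="none",
                                                n_restarts=3)
                    for r in ("chrX", "autosomes")}
            comb = {r: herit.combined_estimate(
                        herit.H2Estimate("t", "male", r, ests["male"][r].h2, 0.0),
                        herit.H2Estimate("t", "female", r, ests["female"][r].h2, 0.0))
                    for r in ("chrX", "autosomes")}
            xis_f.append(ests["female"]["chrX"].h2 / ests["female"]["autosomes"].h2)
            xis_c.append(comb["chrX"].h2 / comb["autosomes"].h2)
        assert np.mean(xis_c) / np.mean(xis_f) == pytest.approx(1.5, rel=0.12)


class TestZeroTestAndBH:
    def test_t_statistic_values(self):
        rows = [herit.H2Estimate("null", "male", "chrX", 0.0, 0.01),
                herit.H2Estimate("two", "male", "chrX", 0.02, 0.01)]
        out = herit.test_h2_zero(rows)
        assert out.loc[0, "T"] == 0.0
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert out.loc[1, "T"] == pytest.approx(4.0)
        assert out.loc[1, "p"] == pytest.approx(stats.chi2.sf(4, 1), rel=1e-9)
        assert out.loc[1, "p"] == pytest.approx(0.0455, abs=1e-3)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            herit.test_h2_zero([herit.H2Estimate("t", "male", "chrX", 0.1, 0.0)])

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=60))
    def test_bh_matches_statsmodels_exactly(self, pvals):
        from statsmodels.stats.multitest import multipletests
        mine = herit.bh_qvalues(np.array(pvals))
        ref = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(mine, ref, rtol=0, atol=0)

    def test_fdr_calibrated_under_global_null(self):
        rng_hits, total = 0, 0
        for rep in range(10):
            ests = []
            for t in range(40):
                _, ss = direct(10_000 + rep * 100 + t, m=400, n=5000, h2=0.0)
                e = herit.chi2_h2(ss, "female", "chrX", trait=f"t{t}")
                if e.se > 0:
                    ests.append(e)
            out = herit.test_h2_zero(ests)
            rng_hits += (out["q"] < 0.05).sum()
            total += len(out)
        assert rng_hits / total <= 0.05 + 0.02


class TestLDScores:
    def test_independent_variants_score_one(self):
        rng = np.random.default_rng(11)
        R = rng.binomial(2, 0.3, size=(2000, 30)).astype(float)
        pos = np.arange(30) * 10_000
        scores = herit.ld_scores(R, pos)
        assert np.allclose(scores, 1.0, atol=0.05)

    def test_duplicated_variant_scores_two(self):
        rng = np.random.default_rng(12)
        R = rng.binomial(2, 0.3, size=(500, 5)).astype(float)
        R[:, 1] = R[:, 0]
        scores = herit.ld_scores(R, np.arange(5) * 1000)
        assert scores[0] == pytest.approx(2.0, abs=0.05)
        assert scores[1] == pytest.approx(2.0, abs=0.05)

    def test_window_limits_tagging(self):
        rng = np.random.default_rng(13)
        R = rng.binomial(2, 0.3, size=(500, 2)).astype(float)
        R[:, 1] = R[:, 0]
        scores = herit.ld_scores(R, np.array([0, 2_000_000]))
        assert np.allclose(scores, 1.0, atol=0.05)

    def test_monomorphic_excluded(self, caplog):
        import logging
        rng = np.random.default_rng(14)
        R = rng.binomial(2, 0.3, size=(100, 3)).astype(float)
        R[:, 2] = 1.0
        with caplog.at_level(logging.WARNING, logger="xdosage.heritability"):
            scores = herit.ld_scores(R, np.arange(3))
        assert np.isnan(scores[2])
        assert any("monomorphic" in r.message for r in caplog.records)

    def test_small_sample_adjustment_removes_null_inflation(self):
        """With unlinked variants, raw scores inflate by ~(m-1)/n_ref while
        adjusted scores are unbiased for the true score of 1."""
        rng = np.random.default_rng(15)
        n_ref, m, reps = 40, 21, 60
        raw_means, adj_means = [], []
        for _ in range(reps):
            R = rng.binomial(2, 0.3, size=(n_ref, m)).astype(float)
            pos = np.arange(m) * 1000
            raw_means.append(np.nanmean(herit.ld_scores(R, pos, tag_r2=0.0,
                                                        adjust=False)))
            adj_means.append(np.nanmean(herit.ld_scores(R, pos, tag_r2=0.0)))
        raw, adj = np.mean(raw_means), np.mean(adj_means)
        assert raw > adj
        assert raw == pytest.approx(1 + (m - 1) / n_ref, abs=0.1)
        assert adj == pytest.approx(1.0, abs=0.05)
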