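import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rnamsnp.mr_suite import (
    _egger_zero_intercept,
    ivw,
    mr_egger,
    mr_presso,
    ratio_estimates,
    weighted_median,
)
from rnamsnp.synthetic import gen_instrument_stats


def _instr(bx, sx, by, sy):
    return pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(len(bx))],
            "beta_exposure": bx,
            "se_exposure": sx,
            "beta_outcome": by,
            "se_outcome": sy,
        }
    )


class TestIvw:
    def test_single_instrument_is_wald_ratio(self):
        t = _instr([0.5], [0.02], [0.1], [0.05])
        r = ivw(t)
        assert r.estimate == pytest.approx(0.2)
        assert r.se == pytest.approx(0.1)
        assert r.ci95 == (pytest.approx(0.2 - 1.96 * 0.1), pytest.approx(0.2 + 1.96 * 0.1))

    def test_three_instruments_match_direct_formula_oracle(self):
        bx = np.array([0.5, 0.3, -0.4])
        sy = np.array([0.05, 0.03, 0.06])
        by = np.array([0.11, 0.05, -0.09])
        t = _instr(bx, [0.02] * 3, by, sy)
        # independent oracle: weighted average of ratios, direct arithmetic
        theta = by / bx
        w = bx**2 / sy**2
        expected = (w * theta).sum() / w.sum()
        r = ivw(t)
        assert r.estimate == pytest.approx(expected, abs=1e-12)
        q = float((w * (theta - expected) ** 2).sum())
        assert r.q_stat == pytest.approx(q, abs=1e-12)

    def test_identical_ratios_give_zero_q_and_equal_ses(self):
        bx = np.array([0.5, 0.2, 0.8])
        by = 0.3 * bx
        t = _instr(bx, [0.02] * 3, by, [0.05, 0.04, 0.06])
        fixed = ivw(t, model="fixed")
        random = ivw(t, model="random")
        assert fixed.estimate == pytest.approx(0.3, abs=1e-12)
        assert fixed.q_stat == pytest.approx(0.0, abs=1e-12)
        assert fixed.se == pytest.approx(random.se)  # inflation floored at 1

    def test_zero_exposure_beta_names_snp(self):
        t = _instr([0.5, 0.0], [0.02] * 2, [0.1, 0.1], [0.05] * 2)
        with pytest.raises(ValueError, match="rs1"):
            ivw(t)

    def test_parameter_recovery_and_coverage(self):
        """beta = 0.1, 50 instruments, n = 50,000: the IVW mean over 200
        replicates recovers the causal effect; CI coverage is nominal."""
        ests, cover, cover_null = [], 0, 0
        for s in range(200):
            tab = gen_instrument_stats(50, 0.1, seed=[101, s])
            r = ivw(tab)
            ests.append(r.estimate)
            cover += r.ci95[0] <= 0.1 <= r.ci95[1]
            null = gen_instrument_stats(50, 0.0, seed=[102, s])
            rn = ivw(null)
            cover_null += rn.ci95[0] <= 0.0 <= rn.ci95[1]
        assert np.mean(ests) == pytest.approx(0.1, abs=0.01)
        assert 0.90 <= cover / 200 <= 0.98
        assert 0.90 <= cover_null / 200 <= 0.98


class TestEgger:
    def test_exact_fit_recovers_slope_and_intercept(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        by = 0.02 + 0.3 * bx
        t = _instr(bx, [0.01] * 4, by, [0.05] * 4)
        r = mr_egger(t)
        assert r.estimate == pytest.approx(0.3, abs=1e-12)
        assert r.egger_intercept == pytest.approx(0.02, abs=1e-12)
        assert r.q_stat == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels_wls_oracle(self, rng):
        bx = rng.uniform(0.1, 0.9, 10)
        by = rng.normal(0.01 + 0.25 * bx, 0.05)
        sy = rng.uniform(0.02, 0.08, 10)
        t = _instr(bx, [0.01] * 10, by, sy)
        r = mr_egger(t)
        import statsmodels.api as sm

        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
        assert r.estimate == pytest.approx(fit.params[1], abs=1e-10)
        assert r.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)

    def test_orientation_invariance(self, rng):
        bx = rng.uniform(0.1, 0.9, 8)
        by = rng.normal(0.3 * bx, 0.05)
        t = _instr(bx, [0.01] * 8, by, [0.05] * 8)
        sign = np.where(np.arange(8) % 2 == 0, 1.0, -1.0)
        t_flipped = _instr(bx * sign, [0.01] * 8, by * sign, [0.05] * 8)
        assert mr_egger(t).estimate == pytest.approx(mr_egger(t_flipped).estimate, abs=1e-12)

    def test_zero_intercept_mode_reproduces_ivw(self, rng):
        tab = gen_instrument_stats(15, 0.1, seed=55)
        assert _egger_zero_intercept(tab).estimate == pytest.approx(ivw(tab).estimate, abs=1e-12)

    def test_requires_three_instruments(self):
        t = _instr([0.5, 0.3], [0.02] * 2, [0.1, 0.05], [0.05] * 2)
        with pytest.raises(ValueError, match="at least 3"):
            mr_egger(t)

    def test_intercept_type_one_error_calibrated(self):
        """No pleiotropy: the intercept test rejects at ~5% over 500 seeds."""
        rej = 0
        for s in range(500):
            tab = gen_instrument_stats(50, 0.1, seed=[103, s])
            rej += mr_egger(tab).egger_intercept_p < 0.05
        assert rej / 500 == pytest.approx(0.05, abs=0.025)


class TestWeightedMedian:
    def test_identical_ratios(self):
        bx = np.array([0.5, 0.2, 0.8])
        t = _instr(bx, [0.02] * 3, 0.25 * bx, [0.05] * 3)
        assert weighted_median(t, n_boot=50, seed=1).estimate == pytest.approx(0.25, abs=1e-10)

    def test_equal_weight_median(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.2, 0.9])
        t = _instr(bx, [0.01] * 3, by, [0.05] * 3)
        assert weighted_median(t, n_boot=50, seed=2).estimate == pytest.approx(0.2, abs=1e-10)

    def test_bootstrap_se_stable_across_seeds(self):
        tab = gen_instrument_stats(30, 0.1, seed=77)
        se1 = weighted_median(tab, n_boot=5000, seed=1).se
        se2 = weighted_median(tab, n_boot=5000, seed=2).se
        assert abs(se1 - se2) / se1 < 0.05


class TestPresso:
    def test_clean_fit_boundary_global_p_one(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        t = _instr(bx, [1e-8] * 5, 0.3 * bx, [0.05] * 5)
        r = mr_presso(t, n_sim=200, seed=3)
        # observed RSS is essentially zero: no simulated RSS can be smaller
        assert r.global_p == 1.0
        assert r.outliers == []

    def test_no_outliers_corrected_equals_all(self):
        tab = gen_instrument_stats(20, 0.1, seed=88)
        r = mr_presso(tab, n_sim=500, seed=4)
        assert r.outliers == []
        assert r.estimate_outlier_corrected.estimate == r.estimate_all.estimate
        assert np.isnan(r.distortion_p)

    def test_planted_outlier_detected(self):
        """One instrument with its ratio shifted by 10 ratio-SEs is flagged
        in nearly every replicate."""
        detected = 0
        for s in range(100):
            tab = gen_instrument_stats(21, 0.1, seed=[104, s])
            j = 20
            se_ratio = tab.loc[j, "se_outcome"] / abs(tab.loc[j, "beta_exposure"])
            tab.loc[j, "beta_outcome"] += 10 * se_ratio * tab.loc[j, "beta_exposure"]
            r = mr_presso(tab, n_sim=1000, seed=[105, s])
            detected += tab.loc[j, "rsid"] in r.outliers
        assert detected >= 95

    def test_global_p_uniform_under_null(self):
        ps = []
        for s in range(200):
            tab = gen_instrument_stats(20, 0.1, seed=[106, s])
            ps.append(mr_presso(tab, n_sim=1000, seed=[107, s]).global_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_requires_four_instruments(self):
        t = _instr([0.5, 0.3, 0.2], [0.02] * 3, [0.1, 0.05, 0.04], [0.05] * 3)
        with pytest.raises(ValueError, match="at least 4"):
            mr_presso(t, seed=5)


class TestCrossMethodProperties:
    def test_consistency_as_ses_vanish(self):
        bx = np.linspace(0.2, 1.0, 10)
        theta = 0.25
        t = _instr(bx, [1e-6] * 10, theta * bx, [1e-6] * 10)
        assert ivw(t).estimate == pytest.approx(theta, abs=1e-4)
        assert mr_egger(t).estimate == pytest.approx(theta, abs=1e-4)
        assert weighted_median(t, n_boot=50, seed=6).estimate == pytest.approx(theta, abs=1e-4)
        assert mr_presso(t, n_sim=100, seed=7).estimate_all.estimate == pytest.approx(theta, abs=1e-4)

    def test_scale_equivariance_in_outcome(self):
        tab = gen_instrument_stats(12, 0.1, seed=99)
        c = 3.7
        scaled = tab.copy()
        scaled["beta_outcome"] *= c
        scaled["se_outcome"] *= c
        for fn in (ivw, mr_egger):
            assert fn(scaled).estimate == pytest.approx(c * fn(tab).estimate, rel=1e-10)
            assert fn(scaled).se == pytest.approx(c * fn(tab).se, rel=1e-10)
        wm1 = weighted_median(tab, n_boot=200, seed=8)
        wm2 = weighted_median(scaled, n_boot=200, seed=8)
        assert wm2.estimate == pytest.approx(c * wm1.estimate, rel=1e-10)

    def test_ratio_estimates_table(self):
        t = _instr([0.5, -0.4], [0.02] * 2, [0.1, 0.2], [0.05, 0.08])
        r = ratio_estimates(t)
        assert r.loc[0, "theta"] == pytest.approx(0.2)
        assert r.loc[1, "se_theta"] == pytest.approx(0.08 / 0.4)

    def test_individual_level_recovery(self):
        """End-to-end: individual-level two-sample simulation, instrument
        selection by p-value, IVW recovers the causal effect within 3 SE."""
        from rnamsnp.instruments import select_instruments
        from rnamsnp.synthetic import SimulationConfig, gen_ld_panel, gen_summary_stats

        hits = 0
        n_seeds = 25
        for s in range(n_seeds):
            cfg = SimulationConfig(
                n_individuals=20_000,
                n_blocks=100,
                snps_per_block=1,
                rho=0.0,
                n_causal=50,
                heritability_x=0.3,
                beta_causal=0.1,
                seed=1000 + s,
            )
            panel = gen_ld_panel(cfg)
            out = gen_summary_stats(panel, cfg)
            exp = select_instruments(out["exposure"], 5e-4)
            merged = exp.merge(
                out["outcome"][["rsid", "beta", "se"]], on="rsid", suffixes=("", "_out")
            ).rename(
                columns={
                    "beta": "beta_exposure",
                    "se": "se_exposure",
                    "beta_out": "beta_outcome",
                    "se_out": "se_outcome",
                }
            )
            r = ivw(merged)
            hits += abs(r.estimate - 0.1) <= 3 * r.se
        assert hits >= n_seeds - 1
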