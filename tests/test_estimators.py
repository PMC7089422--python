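"""Causal estimators against closed-form oracles, plus the algebraic
invariants every summary-data MR estimator must satisfy."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

import lipidmr as lm
from lipidmr.harmonise import HarmonisedData


def make_h(bx, by, s, sx=None, names=("X",)) -> HarmonisedData:
    bx = np.atleast_2d(np.asarray(bx, float))
    if bx.shape[0] == 1 and len(names) == 1:
        bx = bx.T
    J, K = bx.shape
    sx = np.full((J, K), 0.01) if sx is None else np.atleast_2d(np.asarray(sx, float)).reshape(J, K)
    return HarmonisedData([f"rs{i}" for i in range(J)], list(names), bx, sx,
                          np.asarray(by, float), np.asarray(s, float),
                          ["A"] * J, ["G"] * J)


class TestRatioEstimates:
    def test_examples(self):
        H = make_h([0.2], [0.1], [0.05])
        ratio, se = lm.ratio_estimates(H)
        assert ratio[0] == pytest.approx(0.5)
        assert se[0] == pytest.approx(0.25)

    def test_sign_flip(self):
        H = make_h([-0.2], [0.1], [0.05])
        ratio, _ = lm.ratio_estimates(H)
        assert ratio[0] == pytest.approx(-0.5)

    def test_zero_exposure_beta_raises(self):
        H = make_h([0.0, 0.1], [0.1, 0.1], [0.05, 0.05])
        with pytest.raises(lm.EstimationError, match="rs0"):
            lm.ratio_estimates(H)


class TestIVW:
    def test_single_snp_reduces_to_wald_ratio(self):
        H = make_h([0.2], [0.1], [0.05])
        res = lm.ivw(H)
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.25)

    def test_exact_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3])
        H = make_h(bx, 0.4 * bx, [0.01, 0.02, 0.03])
        res = lm.ivw(H)
        assert res.beta == pytest.approx(0.4, abs=1e-12)
        assert res.residual_scale == 1.0   # dispersion clipped at the fixed-effect floor

    def test_three_snp_closed_form_oracle(self):
        bx = np.array([0.10, 0.20, 0.15])
        by = np.array([0.06, 0.11, 0.09])
        s = np.array([0.01, 0.02, 0.015])
        H = make_h(bx, by, s)
        res = lm.ivw(H)
        w = s**-2
        beta_o = (w * bx * by).sum() / (w * bx * bx).sum()
        sig2 = (w * (by - beta_o * bx) ** 2).sum() / 2
        se_o = np.sqrt(max(1.0, sig2) / (w * bx * bx).sum())
        assert res.beta == pytest.approx(beta_o, abs=1e-10)
        assert res.se == pytest.approx(se_o, abs=1e-10)

    def test_equals_weighted_mean_of_ratios(self):
        rng = np.random.default_rng(0)
        bx = rng.normal(0.2, 0.05, 15)
        by = rng.normal(0.1, 0.05, 15)
        s = rng.uniform(0.01, 0.05, 15)
        res = lm.ivw(make_h(bx, by, s))
        ratios = by / bx
        w = bx**2 / s**2
        assert res.beta == pytest.approx((w * ratios).sum() / w.sum(), abs=1e-10)

    def test_permutation_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(1)
        bx = rng.normal(0.2, 0.05, 12)
        by = rng.normal(0.1, 0.05, 12)
        s = rng.uniform(0.01, 0.05, 12)
        res = lm.ivw(make_h(bx, by, s))
        perm = rng.permutation(12)
        res_p = lm.ivw(make_h(bx[perm], by[perm], s[perm]))
        assert res_p.beta == pytest.approx(res.beta, abs=1e-12)
        res_c = lm.ivw(make_h(3.0 * bx, by, s))
        assert res_c.beta == pytest.approx(res.beta / 3.0, abs=1e-12)

    def test_empty_input_raises(self):
        H = make_h(np.zeros((0, 1)), [], [])
        with pytest.raises(lm.EstimationError):
            lm.ivw(H)


class TestMREgger:
    def test_exact_affine_relation(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        H = make_h(bx, 0.02 + 0.5 * bx, np.full(4, 0.02))
        res = lm.mr_egger(H)
        assert res.beta == pytest.approx(0.5, abs=1e-10)
        assert res.intercept == pytest.approx(0.02, abs=1e-10)

    def test_orientation_canonicalises_sign_flips(self):
        rng = np.random.default_rng(2)
        bx = rng.normal(0.2, 0.05, 8)
        by = rng.normal(0.1, 0.05, 8)
        s = rng.uniform(0.01, 0.05, 8)
        res = lm.mr_egger(make_h(bx, by, s))
        bx2, by2 = bx.copy(), by.copy()
        bx2[3] *= -1
        by2[3] *= -1
        res2 = lm.mr_egger(make_h(bx2, by2, s))
        assert res2.beta == pytest.approx(res.beta, abs=1e-12)
        assert res2.intercept == pytest.approx(res.intercept, abs=1e-12)

    def test_too_few_snps_raises(self):
        H = make_h([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        with pytest.raises(lm.EstimationError):
            lm.mr_egger(H)

    def test_matches_statsmodels_wls(self):
        rng = np.random.default_rng(3)
        bx = np.abs(rng.normal(0.2, 0.05, 10))
        by = rng.normal(0.1, 0.05, 10)
        s = rng.uniform(0.01, 0.05, 10)
        res = lm.mr_egger(make_h(bx, by, s))
        fit = sm.WLS(by, sm.add_constant(bx), weights=s**-2).fit()
        assert res.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.5, 0.9])
        H = make_h(bx, by, np.ones(3))
        res = lm.weighted_median(H, n_boot=50, seed=0)
        assert res.beta == pytest.approx(0.5)

    def test_dominant_weight_snp_wins(self):
        bx = np.array([1.0, 0.02, 0.02])
        by = np.array([0.30, 0.032, 0.036])    # ratios: 0.3, 1.6, 1.8
        s = np.array([0.002, 0.2, 0.2])        # weight 1 carries ~all the mass
        res = lm.weighted_median(make_h(bx, by, s), n_boot=50, seed=0)
        assert res.beta == pytest.approx(0.3, abs=1e-6)

    def test_five_snp_interpolation_oracle(self):
        bx = np.array([0.12, 0.25, 0.18, 0.30, 0.22])
        by = np.array([0.05, 0.14, 0.07, 0.20, 0.10])
        s = np.array([0.02, 0.03, 0.025, 0.04, 0.03])
        res = lm.weighted_median(make_h(bx, by, s), n_boot=10, seed=0)
        # independent step-by-step oracle
        ratios = by / bx
        w = bx**2 / s**2
        order = np.argsort(ratios)
        r_s, w_s = ratios[order], w[order] / w.sum()
        p = np.cumsum(w_s) - w_s / 2
        below = np.where(p < 0.5)[0][-1]
        expect = r_s[below] + (0.5 - p[below]) * (r_s[below + 1] - r_s[below]) \
            / (p[below + 1] - p[below])
        assert res.beta == pytest.approx(expect, abs=1e-12)

    def test_bootstrap_reproducible_under_seed(self):
        rng = np.random.default_rng(4)
        H = make_h(rng.normal(0.2, 0.05, 8), rng.normal(0.1, 0.05, 8),
                   rng.uniform(0.01, 0.05, 8))
        r1 = lm.weighted_median(H, n_boot=200, seed=7)
        r2 = lm.weighted_median(H, n_boot=200, seed=7)
        assert r1.se == r2.se

    def test_within_ratio_range(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            bx = rng.normal(0.2, 0.1, 9)
            bx[bx == 0] = 0.01
            by = rng.normal(0.0, 0.1, 9)
            s = rng.uniform(0.01, 0.05, 9)
            res = lm.weighted_median(make_h(bx, by, s), n_boot=2, seed=0)
            ratios = by / bx
            assert ratios.min() - 1e-12 <= res.beta <= ratios.max() + 1e-12


class TestWeightedMode:
    def test_identical_ratios_degenerate(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = 0.3 * bx
        res = lm.weighted_mode(make_h(bx, by, np.full(3, 0.02)), n_boot=10, seed=0)
        assert res.beta == pytest.approx(0.3) and res.se == 0.0

    def test_dominant_weight_snp_wins(self):
        bx = np.array([1.0, 0.05, 0.05, 0.05])
        by = np.array([0.30, 0.08, 0.09, 0.07])
        s = np.array([0.005, 0.1, 0.1, 0.1])
        res = lm.weighted_mode(make_h(bx, by, s), n_boot=10, seed=0)
        assert res.beta == pytest.approx(0.3, abs=0.05)

    def test_bimodal_grid_argmax_oracle(self):
        # 7 tight high-weight ratios near 0.5, 3 low-weight near 1.5
        bx = np.concatenate([np.full(7, 0.5), np.full(3, 0.1)])
        by = np.concatenate([0.5 * np.full(7, 0.5) + [0, .001, -.001, .002, -.002, .0015, -.0015],
                             1.5 * np.full(3, 0.1)])
        s = np.concatenate([np.full(7, 0.01), np.full(3, 0.05)])
        H = make_h(bx, by, s)
        res = lm.weighted_mode(H, n_boot=5, seed=0)
        assert 0.4 < res.beta < 0.6
        # independent grid-argmax oracle
        ratios = by / bx
        w = bx**2 / s**2
        w = w / w.sum()
        J = len(ratios)
        sd = np.std(ratios, ddof=1)
        iqr = np.subtract(*np.percentile(ratios, [75, 25]))
        h = 0.9 * min(sd, iqr / 1.349) * J ** (-0.2)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
        dens = (np.exp(-0.5 * ((grid[:, None] - ratios) / h) ** 2) * w).sum(axis=1)
        assert res.beta == pytest.approx(grid[np.argmax(dens)], abs=1e-12)


class TestMultivariable:
    def test_exact_linear_combination(self):
        rng = np.random.default_rng(6)
        B = rng.normal(0.1, 0.05, size=(10, 2))
        b = 0.5 * B[:, 0]
        H = make_h(B, b, np.full(10, 0.02), names=("X1", "X2"))
        res = lm.mvmr_ivw(H)
        assert res[0].beta == pytest.approx(0.5, abs=1e-10)
        assert res[1].beta == pytest.approx(0.0, abs=1e-10)

    def test_k1_reduces_to_ivw(self):
        rng = np.random.default_rng(7)
        bx = rng.normal(0.2, 0.05, 8)
        by = rng.normal(0.1, 0.05, 8)
        s = rng.uniform(0.01, 0.05, 8)
        H = make_h(bx, by, s)
        uni = lm.ivw(H)
        multi = lm.mvmr_ivw(H)[0]
        assert multi.beta == pytest.approx(uni.beta, abs=1e-12)
        assert multi.se == pytest.approx(uni.se, abs=1e-12)

    def test_rank_deficiency_names_collinear_pair(self):
        B = np.column_stack([np.linspace(0.1, 0.5, 6), 2 * np.linspace(0.1, 0.5, 6)])
        H = make_h(B, np.full(6, 0.1), np.full(6, 0.02), names=("A", "B"))
        with pytest.raises(lm.EstimationError, match="A~B"):
            lm.mvmr_ivw(H)

    def test_mvmr_egger_exact_affine(self):
        rng = np.random.default_rng(8)
        B = np.abs(rng.normal(0.2, 0.05, size=(12, 2)))
        b = 0.02 + 0.6 * B[:, 0] - 0.1 * B[:, 1]
        H = make_h(B, b, np.full(12, 0.02), names=("X1", "X2"))
        results, inter = lm.mvmr_egger(H)
        assert inter.beta == pytest.approx(0.02, abs=1e-10)
        assert results[0].beta == pytest.approx(0.6, abs=1e-10)
        assert results[1].beta == pytest.approx(-0.1, abs=1e-10)

    def test_mvmr_egger_row_negation_invariance(self):
        rng = np.random.default_rng(9)
        B = rng.normal(0.15, 0.08, size=(10, 2))
        b = rng.normal(0.05, 0.03, 10)
        s = np.full(10, 0.02)
        H1 = make_h(B, b, s, names=("X1", "X2"))
        flip = rng.random(10) < 0.5
        sign = np.where(flip, -1.0, 1.0)
        H2 = make_h(B * sign[:, None], b * sign, s, names=("X1", "X2"))
        r1, i1 = lm.mvmr_egger(H1)
        r2, i2 = lm.mvmr_egger(H2)
        assert r1[0].beta == pytest.approx(r2[0].beta, abs=1e-12)
        assert i1.beta == pytest.approx(i2.beta, abs=1e-12)

    def test_mvmr_agrees_with_statsmodels_wls(self):
        rng = np.random.default_rng(10)
        B = rng.normal(0.1, 0.05, size=(15, 3))
        b = rng.normal(0.05, 0.05, 15)
        s = rng.uniform(0.01, 0.05, 15)
        H = make_h(B, b, s, names=("X1", "X2", "X3"))
        res = lm.mvmr_ivw(H)
        fit = sm.WLS(b, B, weights=s**-2).fit()
        for k in range(3):
            assert res[k].beta == pytest.approx(fit.params[k], abs=1e-10)


class TestFStatistics:
    def test_mean_f_examples(self):
        import pandas as pd
        from lipidmr.summary import SummaryStats

        def stats(zs):
            df = pd.DataFrame({
                "snp": [f"rs{i}" for i in range(len(zs))], "chrom": 1,
                "pos": np.arange(1, len(zs) + 1), "ea": "A", "oa": "G",
                "eaf": 0.4, "beta": np.asarray(zs) * 0.01, "se": 0.01,
                "pvalue": 0.5, "n": 100, "info": 1.0})
            return SummaryStats(df)

        assert lm.mean_f(stats([10.0])) == pytest.approx(100.0)
        assert lm.mean_f(stats([10.0, 20.0])) == pytest.approx(250.0)

    def test_conditional_f_orthogonal_oracle(self):
        # other exposures' betas all zero: CF = mean F * L / (L - K + 1)
        rng = np.random.default_rng(11)
        L = 10
        B = np.zeros((L, 2))
        B[:, 0] = rng.normal(0.2, 0.05, L)
        S = np.full((L, 2), 0.02)
        H = make_h(B, np.full(L, 0.1), np.full(L, 0.02), sx=S, names=("X1", "X2"))
        fs = lm.conditional_f(H)
        mf = np.mean((B[:, 0] / 0.02) ** 2)
        assert fs.conditional_f[0] == pytest.approx(mf * L / (L - 2 + 1), rel=1e-10)

    def test_exact_collinearity_gives_zero(self):
        L = 8
        x = np.linspace(0.1, 0.5, L)
        B = np.column_stack([x, 2 * x])
        H = make_h(B, np.full(L, 0.1), np.full(L, 0.02), names=("X1", "X2"))
        fs = lm.conditional_f(H)
        assert fs.conditional_f[0] == pytest.approx(0.0, abs=1e-18)

    def test_requires_enough_snps(self):
        H = make_h(np.zeros((2, 2)) + 0.1, [0.1, 0.1], [0.02, 0.02],
                   names=("X1", "X2"))
        with pytest.raises(lm.EstimationError):
            lm.conditional_f(H)

    def test_near_collinear_conditional_f_below_mean_f(self, lipid_study):
        """On the lipid preset the apoB/LDL analogues are nearly collinear,
        so each conditional F sits well below its univariable mean F."""
        from lipidmr import AnalysisConfig
        from lipidmr.validation import _harmonised_for

        ana = AnalysisConfig(traits=["apoB", "LDL", "TG"],
                             models=[["apoB", "LDL", "TG"]])
        H = _harmonised_for(lipid_study, ["apoB", "LDL", "TG"], ana)
        fs = lm.conditional_f(H)
        assert (fs.conditional_f[:2] < 0.5 * fs.mean_f[:2]).all()


class TestOddsRatioScale:
    def test_examples(self):
        res = lm.MRResult("ivw", "X", 0.0, 0.1, 5)
        assert lm.to_odds_ratio(res).or_scale["or"] == pytest.approx(1.0)
        res = lm.MRResult("ivw", "X", np.log(1.66), 0.05, 5)
        assert res.or_scale["or"] == pytest.approx(1.66)
        res = lm.MRResult("ivw", "X", 0.3, 0.0, 5)
        assert res.or_scale["or_lo"] == res.or_scale["or_hi"] == pytest.approx(np.exp(0.3))

    def test_ci_is_symmetric_on_log_scale(self):
        res = lm.MRResult("ivw", "X", 0.2, 0.07, 3)
        lo, hi = res.ci95
        assert lo == pytest.approx(0.2 - 1.959964 * 0.07)
        assert hi == pytest.approx(0.2 + 1.959964 * 0.07)
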