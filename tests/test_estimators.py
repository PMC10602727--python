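"""The five causal estimators against closed-form and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from mrkit import (
    HarmonizedSet,
    all_estimates,
    egger,
    ivw,
    mode_estimate,
    or_from_beta,
    ratio_estimates,
    weighted_median,
)

from conftest import random_hset


def hset(gamma, Gamma, sy, sx=None):
    gamma = np.asarray(gamma, float)
    if sx is None:
        sx = np.full_like(gamma, 0.01)
    return HarmonizedSet.from_arrays(gamma, sx, Gamma, sy)


class TestRatioEstimates:
    def test_direct_arithmetic(self):
        beta, se, _ = ratio_estimates(hset([2.0], [1.0], [0.2]))
        assert beta[0] == pytest.approx(0.5) and se[0] == pytest.approx(0.1)

    def test_sign(self):
        beta, _, _ = ratio_estimates(hset([-1.0], [0.3], [0.1]))
        assert beta[0] == pytest.approx(-0.3)

    def test_elementwise_division_oracle(self, rng):
        g = rng.uniform(0.5, 2, 10) * rng.choice([-1, 1], 10)
        G = rng.normal(size=10)
        sy = rng.uniform(0.05, 0.2, 10)
        beta, se, _ = ratio_estimates(hset(g, G, sy))
        np.testing.assert_allclose(beta, G / g)
        np.testing.assert_allclose(se, sy / np.abs(g))

    def test_zero_gamma_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero exposure effect"):
            beta, _, keep = ratio_estimates(hset([1.0, 0.0], [0.5, 0.5], [0.1, 0.1]))
        assert len(beta) == 1 and keep.tolist() == [True, False]


class TestIVW:
    def test_exact_fit_returns_common_ratio(self):
        est = ivw(hset([1.0, 2.0], [0.5, 1.0], [0.1, 0.1]))
        assert est.beta == pytest.approx(0.5)

    def test_hand_computed_weighted_sums(self, three_snp_set):
        # w = (100, 25, 100/9); sum(w*g*G) = 140, sum(w*g^2) = 300
        est = ivw(three_snp_set)
        assert est.beta == pytest.approx(140 / 300)

    def test_linearity_in_outcome(self, rng):
        h = random_hset(rng)
        scaled = HarmonizedSet.from_arrays(
            h.gamma_hat, h.sigma_x, 3.0 * h.Gamma_hat, h.sigma_y
        )
        assert ivw(scaled).beta == pytest.approx(3.0 * ivw(h).beta)

    def test_oracle_equivalence_origin_constrained_wls(self, rng):
        """IVW equals the normal-equations solution of weighted regression
        through the origin, written out independently."""
        for _ in range(20):
            h = random_hset(rng, L=int(rng.integers(3, 30)))
            w = 1.0 / h.sigma_y**2
            oracle = np.sum(w * h.gamma_hat * h.Gamma_hat) / np.sum(
                w * h.gamma_hat**2
            )
            assert abs(ivw(h).beta - oracle) <= 1e-10 * max(1.0, abs(oracle))

    def test_fe_vs_re_share_point_estimate(self, rng):
        h = random_hset(rng)
        assert ivw(h, model="fe").beta == ivw(h, model="re").beta
        assert ivw(h, model="re").se >= ivw(h, model="fe").se

    def test_too_few_instruments_raise(self):
        with pytest.raises(ValueError):
            ivw(hset([1.0], [0.5], [0.1]))


class TestEgger:
    def test_exact_line_recovers_slope_and_intercept(self):
        g = np.array([1.0, 2.0, 3.0])
        est = egger(hset(g, 0.1 + 0.5 * g, [0.1, 0.2, 0.15]))
        assert est.beta == pytest.approx(0.5)
        assert est.egger_intercept == pytest.approx(0.1)

    def test_degrees_of_freedom_match_three_snp_inference(self):
        """A 3-instrument fit uses t with 1 df: beta/se = 1.93/0.864
        gives the two-sided p 0.268."""
        p = 2 * stats.t.sf(1.93 / 0.864, df=1)
        assert p == pytest.approx(0.268, abs=5e-4)

    def test_balanced_pleiotropy_gives_near_zero_intercept(self, rng):
        L = 50
        g = rng.uniform(0.5, 2, L)
        sy = np.full(L, 0.1)
        intercepts = []
        for _ in range(200):
            G = 0.4 * g + rng.choice([-1, 1], L) * 0.05 + rng.normal(0, sy)
            intercepts.append(egger(hset(g, G, sy)).egger_intercept)
        mcse = np.std(intercepts, ddof=1) / np.sqrt(len(intercepts))
        assert abs(np.mean(intercepts)) < 3 * mcse

    def test_orientation_invariance(self, rng):
        h = random_hset(rng)
        flip = np.ones(h.n_snp)
        flip[::2] = -1
        flipped = HarmonizedSet.from_arrays(
            h.gamma_hat * flip, h.sigma_x, h.Gamma_hat * flip, h.sigma_y
        )
        assert egger(flipped).beta == pytest.approx(egger(h).beta)
        assert egger(flipped).egger_intercept == pytest.approx(
            egger(h).egger_intercept
        )


class TestWeightedMedian:
    def test_equal_weights_middle_element(self):
        est = weighted_median(
            hset([1.0, 1.0, 1.0], [0.2, 0.5, 0.9], [0.1, 0.1, 0.1]),
            n_boot=50,
            seed=1,
        )
        assert est.beta == pytest.approx(0.5)

    def test_brute_force_cumulative_weight_walk(self, rng):
        """Five unequal weights against an independent interpolation oracle."""
        g = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        G = np.array([0.1, 0.25, 0.4, 0.7, 1.1])
        sy = np.array([0.05, 0.1, 0.2, 0.08, 0.3])
        est = weighted_median(hset(g, G, sy), n_boot=50, seed=1)

        ratios = G / g
        w = (1.0 / (sy / np.abs(g)) ** 2)
        w = w / w.sum()
        order = np.argsort(ratios)
        b, wt = ratios[order], w[order]
        s = np.cumsum(wt) - wt / 2
        k = np.searchsorted(s, 0.5)
        oracle = b[k - 1] + (b[k] - b[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1])
        assert est.beta == pytest.approx(oracle)

    def test_symmetric_interpolation_midpoint(self):
        # two of three ratios at the extremes with tiny third weight:
        # equal-weight pair (0, 1) interpolates to 0.5
        g = np.array([1.0, 1.0, 1e-6])
        G = np.array([0.0, 1.0, 0.5e-6])
        sy = np.array([0.1, 0.1, 1e3])
        est = weighted_median(hset(g, G, sy), n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-6)

    def test_bootstrap_reproducible(self, three_snp_set):
        a = weighted_median(three_snp_set, n_boot=100, seed=7)
        b = weighted_median(three_snp_set, n_boot=100, seed=7)
        assert a == b


class TestModes:
    def test_degenerate_distribution_returns_common_ratio(self):
        g = np.array([1.0, 2.0, 4.0])
        est = mode_estimate(
            hset(g, 0.7 * g, [0.1, 0.1, 0.1]), weighted=False, n_boot=50, seed=1
        )
        assert est.beta == pytest.approx(0.7)

    def test_robust_to_single_outlier(self):
        g = np.ones(4)
        G = np.array([0.5, 0.5, 0.5, 5.0])
        est = mode_estimate(
            hset(g, G, np.full(4, 0.1)), weighted=False, n_boot=50, seed=1
        )
        assert abs(est.beta - 0.5) < abs(est.beta - np.mean(G))

    @pytest.mark.parametrize("weighted", [False, True])
    def test_argmax_matches_direct_kernel_sum(self, weighted, rng):
        """Seven hand-set ratios against a direct density evaluation on the
        same grid."""
        g = np.ones(7)
        G = np.array([0.2, 0.35, 0.4, 0.42, 0.55, 0.9, 1.4])
        sy = np.array([0.1, 0.05, 0.08, 0.06, 0.2, 0.3, 0.4])
        est = mode_estimate(hset(g, G, sy), weighted=weighted, n_boot=50, seed=1)

        ratios, se = G / g, sy / np.abs(g)
        w = 1.0 / se**2 if weighted else np.ones(7)
        w = w / w.sum()
        sd = np.std(ratios, ddof=1)
        iqr = np.percentile(ratios, 75) - np.percentile(ratios, 25)
        h = 0.9 * min(sd, iqr / 1.349) * 7 ** (-1 / 5)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
        dens = [float(np.sum(w * np.exp(-0.5 * ((x - ratios) / h) ** 2))) for x in grid]
        assert est.beta == pytest.approx(grid[int(np.argmax(dens))])


class TestORScale:
    def test_headline_risk_estimate(self):
        """beta 0.778 (SE 0.265) exponentiates to OR 2.18, CI 1.295-3.661."""
        r = or_from_beta(0.778, 0.265)
        assert r.or_point == pytest.approx(2.18, abs=5e-3)
        assert r.ci_low == pytest.approx(1.295, abs=2e-3)
        assert r.ci_high == pytest.approx(3.661, abs=2e-3)

    def test_protective_estimate(self):
        """beta −0.657 (SE 0.183) gives OR 0.52, CI 0.362-0.742."""
        r = or_from_beta(-0.657, 0.183)
        assert r.or_point == pytest.approx(0.52, abs=5e-3)
        assert r.ci_low == pytest.approx(0.362, abs=2e-3)
        assert r.ci_high == pytest.approx(0.742, abs=2e-3)

    def test_null_effect(self):
        r = or_from_beta(0.0, 0.2)
        assert r.or_point == 1.0
        assert r.ci_low == pytest.approx(np.exp(-1.96 * 0.2))
        assert r.ci_high == pytest.approx(np.exp(1.96 * 0.2))

    def test_ci_ordering_invariant(self, rng):
        for _ in range(20):
            r = or_from_beta(float(rng.normal()), float(rng.uniform(0.01, 1)))
            assert 0 < r.ci_low <= r.or_point <= r.ci_high


class TestSharedProperties:
    def test_exact_fit_collapse_all_estimators(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        h = hset(g, 0.37 * g, np.full(4, 0.1))
        for est in all_estimates(h, n_boot=50, seed=3):
            assert est.beta == pytest.approx(0.37), est.method

    def test_sign_equivariance(self, rng):
        h = random_hset(rng, L=8)
        neg = HarmonizedSet.from_arrays(
            h.gamma_hat, h.sigma_x, -h.Gamma_hat, h.sigma_y
        )
        for a, b in zip(
            all_estimates(h, n_boot=400, seed=5), all_estimates(neg, n_boot=400, seed=5)
        ):
            assert a.beta == pytest.approx(-b.beta, abs=1e-9), a.method
            if a.method in ("ivw", "egger"):
                # analytic SEs are exactly sign-symmetric; bootstrap SEs only
                # up to Monte-Carlo noise
                assert a.se == pytest.approx(b.se, rel=1e-9), a.method
            else:
                assert a.se == pytest.approx(b.se, rel=0.3), a.method
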