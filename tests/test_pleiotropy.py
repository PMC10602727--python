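"""Heterogeneity and horizontal-pleiotropy diagnostics."""

import numpy as np
import pytest
from scipy import stats

from mrkit import (
    HarmonizedSet,
    SyntheticTruth,
    cochran_q,
    egger_intercept_test,
    harmonize,
    leave_one_out,
    plant_outliers,
    presso_global,
    presso_outlier_test,
    sequential_outlier_removal,
    simulate_pair,
)

from conftest import random_hset


def clean_hset(seed, L=20, theta=0.3, **kw):
    e, o, _ = simulate_pair(SyntheticTruth(theta=theta, L=L, **kw), seed=seed)
    return harmonize(e, o)


class TestCochranQ:
    def test_perfect_homogeneity(self):
        g = np.array([1.0, 2.0, 3.0])
        h = HarmonizedSet.from_arrays(g, g * 0 + 0.01, 0.5 * g, [0.1, 0.1, 0.1])
        rep = cochran_q(h)
        assert rep.Q == pytest.approx(0.0, abs=1e-12)
        assert rep.p == pytest.approx(1.0)
        assert not rep.flag

    def test_hand_computed_residual_sum(self, three_snp_set):
        # slope 7/15; residuals (-1/15, 1/15, 0.1); weighted sum = 2/3
        rep = cochran_q(three_snp_set)
        assert rep.Q == pytest.approx(2 / 3, abs=5e-4)
        assert rep.df == 2

    def test_sign_flip_invariance(self, rng):
        h = random_hset(rng, L=8)
        flip = np.ones(h.n_snp)
        flip[1::2] = -1
        flipped = HarmonizedSet.from_arrays(
            h.gamma_hat * flip, h.sigma_x, h.Gamma_hat * flip, h.sigma_y
        )
        assert cochran_q(flipped).Q == pytest.approx(cochran_q(h).Q)

    def test_null_pvalues_uniform(self):
        """Under theta = 0 with valid instruments the statistic is exactly
        chi-square(L-1), so its p-values are uniform."""
        ps = [
            cochran_q(clean_hset(seed, theta=0.0)).p
            for seed in np.random.SeedSequence(101).spawn(1000)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestEggerIntercept:
    def test_exact_line_intercept(self):
        g = np.array([1.0, 2.0, 3.0])
        h = HarmonizedSet.from_arrays(g, g * 0 + 0.01, 0.1 + 0.5 * g, [0.1] * 3)
        intercept, _, _ = egger_intercept_test(h)
        assert intercept == pytest.approx(0.1)

    def test_translation_equivariance(self, rng):
        h = random_hset(rng)  # gamma all positive: orientation is identity
        shifted = HarmonizedSet.from_arrays(
            h.gamma_hat, h.sigma_x, h.Gamma_hat + 0.25, h.sigma_y
        )
        a = egger_intercept_test(h)[0]
        b = egger_intercept_test(shifted)[0]
        assert b - a == pytest.approx(0.25)

    def test_type_i_error_calibrated(self):
        """Zero pleiotropy, 500 replicates: rejection rate near nominal 0.05."""
        rej = 0
        for seed in np.random.SeedSequence(11).spawn(500):
            _, _, p = egger_intercept_test(clean_hset(seed, L=50, theta=0.0))
            rej += p < 0.05
        assert 0.03 <= rej / 500 <= 0.08


class TestPressoGlobal:
    def test_clean_data_rarely_flagged(self):
        flagged = 0
        for seed in np.random.SeedSequence(31).spawn(20):
            h = clean_hset(seed)
            _, p = presso_global(h, n_distribution=500, seed=seed.spawn(1)[0])
            flagged += p <= 0.05
        assert flagged <= 2

    def test_planted_outlier_detected(self):
        h = clean_hset(np.random.SeedSequence(32), L=20)
        planted = plant_outliers(h, [4], size=10.0)
        _, p = presso_global(planted, n_distribution=500, seed=1)
        assert p <= 0.05

    def test_monotone_in_planted_residual(self):
        """Once the planted offset dominates the SNP's own sampling noise,
        growing it never increases the global p (a small offset can cancel
        an existing residual, so monotonicity starts past ~2 sigma)."""
        h = clean_hset(np.random.SeedSequence(33), L=20)
        ps = []
        for size in (0.0, 2.0, 4.0, 8.0, 16.0):
            _, p = presso_global(
                plant_outliers(h, [3], size=size), n_distribution=500, seed=9
            )
            ps.append(p)
        assert all(a >= b for a, b in zip(ps[1:], ps[2:]))
        assert all(0 < p <= 1 for p in ps)

    def test_too_few_instruments(self):
        h = clean_hset(np.random.SeedSequence(34), L=3)
        with pytest.raises(ValueError, match="insufficient instruments"):
            presso_global(h, n_distribution=100, seed=1)


class TestPressoOutlier:
    def test_planted_snp_has_smallest_p(self):
        h = clean_hset(np.random.SeedSequence(41), L=20)
        planted = plant_outliers(h, [7], size=10.0)
        ps = presso_outlier_test(planted, n_distribution=500, seed=2)
        assert min(ps, key=ps.get) == str(planted.snp_ids[7])

    def test_clean_snps_mostly_unflagged(self):
        ok = 0
        for seed in np.random.SeedSequence(42).spawn(20):
            h = clean_hset(seed)
            ps = presso_outlier_test(h, n_distribution=500, seed=seed.spawn(1)[0])
            ok += all(p > 0.05 for p in ps.values())
        assert ok >= 18

    def test_order_equivariance(self):
        h = clean_hset(np.random.SeedSequence(43), L=12)
        perm = np.random.default_rng(0).permutation(h.n_snp)
        ps_a = presso_outlier_test(h, n_distribution=300, seed=5)
        ps_b = presso_outlier_test(h.subset(perm), n_distribution=300, seed=5)
        assert set(ps_a) == set(ps_b)


class TestSequentialRemoval:
    def test_clean_data_zero_iterations(self):
        h = clean_hset(np.random.SeedSequence(51))
        rep = sequential_outlier_removal(h, n_distribution=500, seed=1)
        if rep.global_p > 0.05:
            assert rep.removed == [] and rep.audit == []
            assert rep.distortion_p is None
            assert rep.final_global_p == rep.global_p

    def test_planted_set_recovered(self):
        """Three gross outliers among 25 SNPs are exactly the SNPs the loop
        removes, in at least 16 of 20 seeded runs."""
        exact = 0
        for seed in np.random.SeedSequence(52).spawn(20):
            h = clean_hset(seed, L=25)
            idx = [i for i in (1, 7, 13) if i < h.n_snp]
            planted = plant_outliers(h, idx, size=10.0)
            ids = sorted(str(planted.snp_ids[i]) for i in idx)
            rep = sequential_outlier_removal(
                planted, n_distribution=500, seed=seed.spawn(1)[0]
            )
            exact += sorted(rep.removed) == ids
        assert exact >= 16

    def test_termination_bound(self):
        # every SNP wildly heterogeneous: loop must stop before L-3 removals
        rng = np.random.default_rng(8)
        L = 10
        g = rng.uniform(0.5, 1.5, L)
        G = rng.normal(0, 1.0, L)  # no common slope at tiny sigma_y
        h = HarmonizedSet.from_arrays(g, np.full(L, 0.01), G, np.full(L, 0.01))
        rep = sequential_outlier_removal(h, n_distribution=200, seed=3)
        assert len(rep.removed) < L - 3
        assert rep.truncated

    def test_removals_audited_in_order(self):
        h = clean_hset(np.random.SeedSequence(53), L=25)
        planted = plant_outliers(h, [2, 9], size=10.0)
        rep = sequential_outlier_removal(planted, n_distribution=500, seed=4)
        assert [sid for _, sid, _, _ in rep.audit] == rep.removed
        assert [it for it, *_ in rep.audit] == list(range(1, len(rep.removed) + 1))
        if rep.removed:
            assert rep.distortion_p is not None and 0 < rep.distortion_p <= 1

    def test_seed_stability_of_global_p(self):
        """At 10000 null draws the empirical global p moves by < 0.02
        across seeds."""
        h = clean_hset(np.random.SeedSequence(54))
        ps = [
            presso_global(h, n_distribution=10_000, seed=s)[1] for s in range(10)
        ]
        assert max(ps) - min(ps) < 0.02


class TestLeaveOneOut:
    def test_exchangeable_snps_give_identical_estimates(self):
        L = 6
        h = HarmonizedSet.from_arrays(
            np.ones(L), np.full(L, 0.01), np.full(L, 0.4), np.full(L, 0.1)
        )
        res = leave_one_out(h)
        assert len(res.estimates) == L
        for beta, _ in res.estimates.values():
            assert beta == pytest.approx(res.full[0])
        assert not res.driver

    def test_dominant_outlier_has_largest_influence(self):
        h = clean_hset(np.random.SeedSequence(61), L=15)
        planted = plant_outliers(h, [5], size=10.0)
        res = leave_one_out(planted)
        deltas = {
            s: abs(beta - res.full[0]) for s, (beta, _) in res.estimates.items()
        }
        assert max(deltas, key=deltas.get) == str(planted.snp_ids[5])

    def test_output_cardinality_and_minimum(self):
        h = clean_hset(np.random.SeedSequence(62), L=10)
        assert len(leave_one_out(h).estimates) == h.n_snp
        with pytest.raises(ValueError):
            leave_one_out(h.subset(np.arange(3)))
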