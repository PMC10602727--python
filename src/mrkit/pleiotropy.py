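"""Horizontal-pleiotropy and heterogeneity diagnostics.

Instruments that affect the outcome through pathways other than the exposure
(horizontal pleiotropy) bias the IVW estimate.  This module implements the
standard diagnostic battery:

- Cochran's Q about the fixed-effect IVW slope (chi-square, L−1 df);
- the MR-Egger intercept test for average directional pleiotropy;
- MR-PRESSO: a residual-sum-of-squares global test against a parametric
  null simulation, per-SNP outlier tests, a sequential removal loop that
  eliminates the worst outlier and re-tests until the global p exceeds 0.05,
  and a distortion test comparing the causal estimate before and after
  removal;
- leave-one-out IVW to flag single SNPs that drive a result.

Empirical p-values use the (1+k)/(1+N) estimator and are therefore never
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import _ivw_core, egger, ivw
from .sumstats_io import HarmonizedSet

__all__ = [
    "HeterogeneityReport",
    "PressoReport",
    "LeaveOneOutResult",
    "cochran_q",
    "egger_intercept_test",
    "presso_global",
    "presso_outlier_test",
    "sequential_outlier_removal",
    "leave_one_out",
]

#: minimum instruments for the PRESSO machinery (leave-one-out IVW needs >=3 left)
_PRESSO_MIN_SNPS = 4


@dataclass(frozen=True)
class HeterogeneityReport:
    """Cochran's Q heterogeneity diagnostic (flag: p < 0.05)."""

    Q: float
    df: int
    p: float
    flag: bool


@dataclass
class PressoReport:
    """MR-PRESSO global/outlier/distortion results and the removal loop audit.

    ``global_rss``/``global_p``/``outlier_p`` refer to the initial full set;
    ``removed`` lists eliminated SNPs in removal order; ``audit`` holds one
    ``(iteration, snp_id, outlier_p, global_p_after)`` row per removal;
    ``final_global_p`` is the global p on the surviving set (equals
    ``global_p`` when nothing was removed).  ``distortion_p`` is None when
    the loop removed nothing.
    """

    global_rss: float
    global_p: float
    outlier_p: dict[str, float]
    removed: list[str]
    distortion_p: float | None
    n_distribution: int
    seed: int | None
    final_global_p: float
    audit: list[tuple[int, str, float, float]] = field(default_factory=list)
    truncated: bool = False


@dataclass(frozen=True)
class LeaveOneOutResult:
    """Full-set IVW plus one IVW estimate per excluded SNP."""

    full: tuple[float, float]
    estimates: dict[str, tuple[float, float]]
    driver: bool


def cochran_q(hset: HarmonizedSet) -> HeterogeneityReport:
    """Cochran's Q about the fixed-effect IVW slope.

    Q = Σⱼ (Γ̂ⱼ − β̂γ̂ⱼ)²/σ_yj², upper-tail chi-square p with L−1 df;
    p < 0.05 flags heterogeneity (a symptom of invalid instruments).
    """
    L = hset.n_snp
    if L < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments")
    _, _, q = _ivw_core(hset.gamma_hat, hset.Gamma_hat, hset.sigma_y)
    df = L - 1
    p = float(stats.chi2.sf(q, df))
    return HeterogeneityReport(Q=q, df=df, p=p, flag=p < 0.05)


def egger_intercept_test(hset: HarmonizedSet) -> tuple[float, float, float]:
    """(intercept, se, p) from the MR-Egger fit — directional-pleiotropy test."""
    fit = egger(hset)
    assert fit.egger_intercept is not None
    return fit.egger_intercept, fit.egger_intercept_se, fit.egger_intercept_p  # type: ignore[return-value]


def _loo_slopes(
    gamma: np.ndarray, Gamma: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes, vectorized over the left-out SNP.

    Supports batched input of shape (..., L); the slope excluding SNP j is
    computed from the weighted sums minus SNP j's contribution.
    """
    s1 = np.sum(w * gamma * Gamma, axis=-1, keepdims=True)
    s2 = np.sum(w * gamma**2, axis=-1, keepdims=True)
    return (s1 - w * gamma * Gamma) / (s2 - w * gamma**2)


def _presso_machinery(
    hset: HarmonizedSet, n_distribution: int, rng: np.random.Generator
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Shared core of the global and outlier tests.

    Returns (rss_obs, global_p, obs_residuals, sim_residuals) where
    ``sim_residuals`` has shape (n_distribution, L).
    """
    L = hset.n_snp
    if L < _PRESSO_MIN_SNPS:
        raise ValueError("insufficient instruments for PRESSO (need >= 4)")
    gamma, Gamma = hset.gamma_hat, hset.Gamma_hat
    sx, sy = hset.sigma_x, hset.sigma_y
    w = 1.0 / sy**2

    beta_loo = _loo_slopes(gamma, Gamma, w)
    obs_resid = w * (Gamma - beta_loo * gamma) ** 2
    rss_obs = float(np.sum(obs_resid))

    # parametric null: effects re-drawn about the observed exposure effects
    # and the leave-one-out expectations of the outcome effects
    g_star = rng.normal(gamma, sx, size=(n_distribution, L))
    G_star = rng.normal(beta_loo * gamma, sy, size=(n_distribution, L))
    beta_loo_star = _loo_slopes(g_star, G_star, w[None, :])
    sim_resid = w[None, :] * (G_star - beta_loo_star * g_star) ** 2

    rss_sim = np.sum(sim_resid, axis=1)
    global_p = (1.0 + float(np.sum(rss_sim >= rss_obs))) / (n_distribution + 1.0)
    return rss_obs, global_p, obs_resid, sim_resid


def presso_global(
    hset: HarmonizedSet,
    n_distribution: int = 10_000,
    seed: int | np.random.Generator | np.random.SeedSequence = None,  # type: ignore[assignment]
) -> tuple[float, float]:
    """MR-PRESSO global test: (observed RSS, empirical p).

    The observed statistic sums each SNP's weighted squared residual about
    the IVW slope fitted *without* that SNP; the null distribution re-draws
    both effect vectors parametrically ``n_distribution`` times.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    rss_obs, global_p, _, _ = _presso_machinery(hset, n_distribution, rng)
    return rss_obs, global_p


def presso_outlier_test(
    hset: HarmonizedSet,
    n_distribution: int = 10_000,
    seed: int | np.random.Generator | np.random.SeedSequence = None,  # type: ignore[assignment]
) -> dict[str, float]:
    """Per-SNP MR-PRESSO outlier p-values, Bonferroni-adjusted by L.

    Each SNP's observed weighted squared residual is ranked within its own
    simulated residual distribution.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    _, _, obs_resid, sim_resid = _presso_machinery(hset, n_distribution, rng)
    return _outlier_pvalues(hset, obs_resid, sim_resid, n_distribution)


def _outlier_pvalues(
    hset: HarmonizedSet,
    obs_resid: np.ndarray,
    sim_resid: np.ndarray,
    n_distribution: int,
) -> dict[str, float]:
    L = hset.n_snp
    counts = np.sum(sim_resid >= obs_resid[None, :], axis=0)
    raw = (1.0 + counts) / (n_distribution + 1.0)
    adjusted = np.minimum(1.0, raw * L)
    return {str(s): float(p) for s, p in zip(hset.snp_ids, adjusted)}


def sequential_outlier_removal(
    hset: HarmonizedSet,
    n_distribution: int = 10_000,
    seed: int | np.random.SeedSequence = None,  # type: ignore[assignment]
    alpha: float = 0.05,
    n_boot_distortion: int = 500,
    refresh_ranking: bool = True,
) -> PressoReport:
    """The iterative MR-PRESSO cleanup loop.

    Run the global test; while its p <= ``alpha``, eliminate the single SNP
    with the smallest outlier-test p and re-run the global test on the
    remainder.  Empirical p-values floor at 1/(n_distribution+1), so ties at
    the floor are common; they are broken by the larger observed weighted
    squared residual, then lexicographically on snp_id — deterministic, and
    it keeps a gross outlier ahead of a merely slope-contaminated SNP.  The loop hard-stops
    (``truncated=True``) when fewer than 4 SNPs would remain.  With
    ``refresh_ranking=False`` the initial full-set outlier ranking is frozen
    instead of being recomputed each iteration.

    The distortion test compares the IVW estimate before vs after removal:
    the observed difference is scaled by the bootstrap SE of the difference
    (``n_boot_distortion`` parametric resamples) and referred to the normal.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    seed_int = ss.entropy if isinstance(ss.entropy, int) else None

    current = hset
    removed: list[str] = []
    audit: list[tuple[int, str, float, float]] = []
    truncated = False

    initial_stats: tuple[float, float, dict[str, float]] | None = None
    frozen_ranking: dict[str, tuple[float, float]] | None = None
    iteration = 0
    final_global_p = np.nan
    while True:
        rng = np.random.default_rng(ss.spawn(1)[0])
        rss_obs, global_p, obs_resid, sim_resid = _presso_machinery(
            current, n_distribution, rng
        )
        outlier_p = _outlier_pvalues(current, obs_resid, sim_resid, n_distribution)
        # ranking key: (p, -observed residual, snp_id)
        keys = {
            str(s): (outlier_p[str(s)], -float(r))
            for s, r in zip(current.snp_ids, obs_resid)
        }
        if initial_stats is None:
            initial_stats = (rss_obs, global_p, outlier_p)
            frozen_ranking = keys
        final_global_p = global_p
        if iteration > 0 and audit:
            # back-fill the global p observed after the previous removal
            it, sid, op, _ = audit[-1]
            audit[-1] = (it, sid, op, global_p)
        if global_p > alpha:
            break
        if current.n_snp <= _PRESSO_MIN_SNPS:
            truncated = True
            break
        ranking = keys if refresh_ranking else {
            s: frozen_ranking[s]  # type: ignore[index]
            for s in map(str, current.snp_ids)
        }
        worst = min(ranking.items(), key=lambda kv: (kv[1], kv[0]))
        iteration += 1
        audit.append((iteration, worst[0], worst[1][0], np.nan))
        removed.append(worst[0])
        current = current.without([worst[0]])

    assert initial_stats is not None
    rss0, p0, outlier0 = initial_stats

    distortion_p: float | None = None
    if removed:
        distortion_p = _distortion_test(
            hset, removed, n_boot_distortion, np.random.default_rng(ss.spawn(1)[0])
        )

    return PressoReport(
        global_rss=rss0,
        global_p=p0,
        outlier_p=outlier0,
        removed=removed,
        distortion_p=distortion_p,
        n_distribution=n_distribution,
        seed=seed_int,
        final_global_p=final_global_p,
        audit=audit,
        truncated=truncated,
    )


def _distortion_test(
    hset: HarmonizedSet,
    removed: list[str],
    n_boot: int,
    rng: np.random.Generator,
) -> float:
    """Bootstrap z-test on the pre- vs post-removal IVW difference."""
    reduced = hset.without(removed)
    beta_full = ivw(hset, model="fe").beta
    beta_reduced = ivw(reduced, model="fe").beta

    keep_mask = np.array([s not in set(removed) for s in hset.snp_ids], dtype=bool)
    w = 1.0 / hset.sigma_y**2
    L = hset.n_snp
    g = rng.normal(hset.gamma_hat, hset.sigma_x, size=(n_boot, L))
    G = rng.normal(hset.Gamma_hat, hset.sigma_y, size=(n_boot, L))

    def slopes(mask: np.ndarray) -> np.ndarray:
        wm = w[mask]
        return np.sum(wm * g[:, mask] * G[:, mask], axis=1) / np.sum(
            wm * g[:, mask] ** 2, axis=1
        )

    diff = slopes(np.ones(L, dtype=bool)) - slopes(keep_mask)
    se = float(np.std(diff, ddof=1))
    if se == 0.0:
        return 1.0
    z = (beta_full - beta_reduced) / se
    return float(2.0 * stats.norm.sf(abs(z)))


def leave_one_out(hset: HarmonizedSet, model: str = "re") -> LeaveOneOutResult:
    """IVW re-estimated with each SNP excluded in turn.

    The ``driver`` flag is raised when any single exclusion flips the sign
    of the estimate, or moves the 95% CI across zero relative to the
    full-set estimate (in either direction).
    """
    L = hset.n_snp
    if L < 4:
        raise ValueError("leave-one-out needs at least 4 instruments")
    full = ivw(hset, model=model)
    estimates: dict[str, tuple[float, float]] = {}
    driver = False

    def excludes_zero(beta: float, se: float) -> bool:
        return abs(beta) - 1.96 * se > 0

    full_excl = excludes_zero(full.beta, full.se)
    for j, snp in enumerate(hset.snp_ids):
        keep = np.ones(L, dtype=bool)
        keep[j] = False
        est = ivw(hset.subset(keep), model=model)
        estimates[str(snp)] = (est.beta, est.se)
        if np.sign(est.beta) != np.sign(full.beta) and est.beta != 0.0:
            driver = True
        if excludes_zero(est.beta, est.se) != full_excl:
            driver = True
    return LeaveOneOutResult(
        full=(full.beta, full.se), estimates=estimates, driver=driver
    )
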