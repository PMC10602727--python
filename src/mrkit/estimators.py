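"""Causal-effect estimators for two-sample Mendelian randomization.

Given a harmonized set of L instruments with exposure effects γ̂ⱼ (SE σ_xj)
and outcome effects Γ̂ⱼ (SE σ_yj), each estimator summarises the per-SNP
Wald ratios β̂ⱼ = Γ̂ⱼ/γ̂ⱼ into one causal effect on the outcome (log-odds per
SD-unit exposure for a binary outcome):

- IVW: inverse-variance weighted regression of Γ̂ on γ̂ through the origin,
  efficient when every instrument is valid; multiplicative random-effects
  scaling of the SE by default.
- MR-Egger: the same regression with an intercept; the intercept estimates
  average directional pleiotropy and the slope a pleiotropy-adjusted effect.
  Inference is t-based with L−2 degrees of freedom.
- Weighted median: consistent when instruments carrying >= 50% of the weight
  are valid; SE by parametric bootstrap.
- Simple/weighted mode: kernel-density argmax of the ratio estimates,
  consistent when the largest cluster of instruments is valid.

Ratio-estimate SEs use the first-order delta method ignoring exposure-side
error (the NOME simplification); a second-order option is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats_io import HarmonizedSet

__all__ = [
    "MREstimate",
    "ORResult",
    "METHODS",
    "ratio_estimates",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimate",
    "or_from_beta",
    "all_estimates",
]

METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")

_MODE_GRID_SIZE = 512


@dataclass(frozen=True)
class MREstimate:
    """One estimator's causal-effect estimate."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None

    def odds_ratio(self, z: float = 1.96) -> "ORResult":
        return or_from_beta(self.beta, self.se, z=z)


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with a two-sided normal confidence interval."""

    or_point: float
    ci_low: float
    ci_high: float


def or_from_beta(beta: float, se: float, z: float = 1.96) -> ORResult:
    """Exponentiate a log-odds effect: OR = exp(β), CI = exp(β ± z·se)."""
    if se <= 0:
        raise ValueError("se must be positive")
    return ORResult(
        or_point=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
    )


def ratio_estimates(
    hset: HarmonizedSet, second_order: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with delta-method SEs.

    First order (default): se_j = σ_yj/|γ̂ⱼ|.  The second-order form adds the
    exposure-error term: se_j = sqrt(σ_yj²/γ̂ⱼ² + Γ̂ⱼ²σ_xj²/γ̂ⱼ⁴).  SNPs with
    γ̂ⱼ = 0 are excluded with a warning.

    Returns (beta, se, kept_mask) where ``kept_mask`` indexes the input SNPs.
    """
    gamma = hset.gamma_hat
    keep = gamma != 0.0
    if not np.all(keep):
        warnings.warn(
            f"{int((~keep).sum())} SNP(s) with zero exposure effect excluded "
            "from ratio estimates",
            stacklevel=2,
        )
    g = gamma[keep]
    G = hset.Gamma_hat[keep]
    sy = hset.sigma_y[keep]
    beta = G / g
    if second_order:
        sx = hset.sigma_x[keep]
        se = np.sqrt(sy**2 / g**2 + G**2 * sx**2 / g**4)
    else:
        se = sy / np.abs(g)
    return beta, se, keep


def _ivw_core(
    gamma: np.ndarray, Gamma: np.ndarray, sigma_y: np.ndarray
) -> tuple[float, float, float]:
    """Fixed-effect IVW slope, Σwγ², and Cochran's Q about that slope."""
    w = 1.0 / sigma_y**2
    denom = float(np.sum(w * gamma**2))
    if denom == 0.0:
        raise ValueError("all exposure effects are zero")
    beta = float(np.sum(w * gamma * Gamma)) / denom
    q = float(np.sum(w * (Gamma - beta * gamma) ** 2))
    return beta, denom, q


def ivw(hset: HarmonizedSet, model: str = "re") -> MREstimate:
    """Inverse-variance weighted estimate (regression through the origin).

    β̂ = Σ wⱼγ̂ⱼΓ̂ⱼ / Σ wⱼγ̂ⱼ² with wⱼ = 1/σ_yj².  ``model='re'`` applies the
    multiplicative random-effects SE inflation φ̂ = max(1, Q/(L−1));
    ``model='fe'`` keeps φ̂ = 1.  p-value from the standard normal.
    """
    if model not in ("re", "fe"):
        raise ValueError("model must be 're' or 'fe'")
    L = hset.n_snp
    if L < 2:
        raise ValueError("IVW needs at least 2 instruments")
    beta, denom, q = _ivw_core(hset.gamma_hat, hset.Gamma_hat, hset.sigma_y)
    phi = max(1.0, q / (L - 1)) if model == "re" else 1.0
    se = float(np.sqrt(phi / denom))
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return MREstimate(method="ivw", beta=beta, se=se, pval=float(p), n_snp=L)


def egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger weighted regression with intercept.

    Instruments are oriented so every γ̂ⱼ >= 0 (flipping both effect signs
    where needed), then Γ̂ is regressed on γ̂ with weights 1/σ_yj².  The
    slope is the pleiotropy-adjusted causal effect; the intercept the
    average directional pleiotropy.  SEs are the unit-dispersion WLS SEs
    inflated by max(1, sqrt(RSS/(L−2))); two-sided p-values from t(L−2).
    """
    L = hset.n_snp
    if L < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    sign = np.where(hset.gamma_hat < 0, -1.0, 1.0)
    g = hset.gamma_hat * sign
    G = hset.Gamma_hat * sign
    w = 1.0 / hset.sigma_y**2

    X = np.column_stack([np.ones_like(g), g])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * G)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = G - X @ coef
    rss = float(np.sum(w * resid**2))
    df = L - 2
    scale = max(1.0, np.sqrt(rss / df))
    cov0 = np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov0)) * scale
    tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return MREstimate(
        method="egger",
        beta=float(coef[1]),
        se=float(se[1]),
        pval=float(pvals[1]),
        n_snp=L,
        egger_intercept=float(coef[0]),
        egger_intercept_se=float(se[0]),
        egger_intercept_p=float(pvals[0]),
    )


def _weighted_median_core(beta: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ``beta`` under normalized weights."""
    order = np.argsort(beta, kind="stable")
    b = beta[order]
    w = weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, b))


def _parametric_resamples(
    hset: HarmonizedSet, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (n_boot, L) resamples of γ̂* and Γ̂* and their ratio β*, se*."""
    L = hset.n_snp
    g = rng.normal(hset.gamma_hat, hset.sigma_x, size=(n_boot, L))
    G = rng.normal(hset.Gamma_hat, hset.sigma_y, size=(n_boot, L))
    # guard the vanishing-denominator pathology in resamples
    g = np.where(g == 0.0, np.finfo(float).tiny, g)
    beta = G / g
    se = hset.sigma_y[None, :] / np.abs(g)
    return beta, se, g


def weighted_median(
    hset: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | np.random.Generator | np.random.SeedSequence = None,  # type: ignore[assignment]
) -> MREstimate:
    """Weighted-median estimate over the per-SNP ratio estimates.

    Ratios are ordered ascending with normalized inverse-variance weights
    wⱼ' and cumulative midpoints sⱼ = Σ_{k<=j} w_k' − wⱼ'/2; the estimate
    linearly interpolates the ratio across s at s = 0.5.  The SE is the
    standard deviation of ``n_boot`` parametric resamples of both effect
    vectors; p is two-sided normal.  A seed (or Generator) is required for
    reproducibility.
    """
    L = hset.n_snp
    if L < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    beta_j, se_j, _ = ratio_estimates(hset)
    est = _weighted_median_core(beta_j, 1.0 / se_j**2)

    boot_beta, boot_se, _ = _parametric_resamples(hset, n_boot, rng)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _weighted_median_core(boot_beta[b], 1.0 / boot_se[b] ** 2)
    se = float(np.std(boots, ddof=1))
    p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else float(est == 0.0)
    return MREstimate(
        method="weighted_median", beta=est, se=se, pval=float(p), n_snp=L
    )


def _mode_bandwidth(beta: np.ndarray, phi: float) -> float:
    sd = float(np.std(beta, ddof=1)) if len(beta) > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(beta, [75, 25])))
    candidates = [s for s in (sd, iqr / 1.349) if s > 0]
    if not candidates:
        return 0.0
    return phi * 0.9 * min(candidates) * len(beta) ** (-1 / 5)


def _mode_core(beta: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Gaussian-kernel density argmax over a fixed 512-point grid."""
    h = _mode_bandwidth(beta, phi)
    if h <= 0.0:
        return float(beta[0])
    grid = np.linspace(beta.min() - 3 * h, beta.max() + 3 * h, _MODE_GRID_SIZE)
    dens = np.sum(
        weights[None, :] * np.exp(-0.5 * ((grid[:, None] - beta[None, :]) / h) ** 2),
        axis=1,
    )
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    hset: HarmonizedSet,
    weighted: bool,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | np.random.Generator | np.random.SeedSequence = None,  # type: ignore[assignment]
) -> MREstimate:
    """Mode-based estimate (simple or inverse-variance weighted).

    The causal effect is the argmax of a Gaussian kernel density over the
    ratio estimates (Silverman-type bandwidth, scaled by
    ``bandwidth_factor``), evaluated on a fixed 512-point grid spanning the
    ratio range ± 3 bandwidths.  SE by the same parametric bootstrap as the
    weighted median; p two-sided from t(L−1).
    """
    L = hset.n_snp
    if L < 3:
        raise ValueError("mode estimators need at least 3 instruments")
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    beta_j, se_j, _ = ratio_estimates(hset)

    def weights_for(se_vec: np.ndarray) -> np.ndarray:
        if weighted:
            w = 1.0 / se_vec**2
        else:
            w = np.ones_like(se_vec)
        return w / w.sum()

    est = _mode_core(beta_j, weights_for(se_j), bandwidth_factor)

    boot_beta, boot_se, _ = _parametric_resamples(hset, n_boot, rng)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _mode_core(boot_beta[b], weights_for(boot_se[b]), bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    p = 2.0 * stats.t.sf(abs(est) / se, L - 1) if se > 0 else float(est == 0.0)
    return MREstimate(
        method="weighted_mode" if weighted else "simple_mode",
        beta=est,
        se=se,
        pval=float(p),
        n_snp=L,
    )


def all_estimates(
    hset: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence = None,  # type: ignore[assignment]
    ivw_model: str = "re",
) -> list[MREstimate]:
    """Run all five estimators with bootstrap seeds derived from ``seed``."""
    if hset.n_snp < 3:
        raise ValueError("estimator battery needs at least 3 instruments")
    if seed is None:
        raise ValueError("an explicit seed is required")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    s_wm, s_sm, s_wmod = ss.spawn(3)
    return [
        ivw(hset, model=ivw_model),
        egger(hset),
        weighted_median(hset, n_boot=n_boot, seed=s_wm),
        mode_estimate(hset, weighted=False, n_boot=n_boot, seed=s_sm),
        mode_estimate(hset, weighted=True, n_boot=n_boot, seed=s_wmod),
    ]
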