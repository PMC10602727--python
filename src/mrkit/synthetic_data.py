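"""Synthetic two-sample GWAS summary statistics with known ground truth.

Effects are simulated directly on the summary-statistic level (no
individual-level genotypes): per SNP j, a true exposure effect γⱼ is drawn
from a truncated-positive normal (mimicking the convention that effects are
reported for the trait-increasing allele), its sampling SE follows the
standard GWAS scaling σ_xj = 1/sqrt(2·n·mafⱼ(1−mafⱼ)), and the outcome
effect obeys a linear causal model Γⱼ = θ·γⱼ + αⱼ with optional horizontal
pleiotropy αⱼ (balanced or directional, optionally correlated with
instrument strength to violate the InSIDE assumption).  Observed effects add
Gaussian sampling noise; p-values are two-sided normal Wald tests; allele
pairs include a configurable fraction of palindromic (A/T, C/G) variants.

Default sample sizes emulate a microbiome-consortium exposure GWAS
(n=18,340) and a case/control liver-disease outcome GWAS (n=24,510).
LD structure is not simulated: SNPs are placed on distinct, distant loci so
clumping leaves them untouched; clumping behaviour is exercised against
hand-built LD matrices instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import COMPLEMENT, HarmonizedSet, SummaryStatRecord

__all__ = [
    "SyntheticTruth",
    "simulate_pair",
    "simulate_multitaxon",
    "make_flipped_copy",
    "plant_outliers",
    "harmonized_from_tables",
]

#: gamma prior: Normal(0.08, 0.03^2) truncated to positive values
_GAMMA_MEAN = 0.08
_GAMMA_SD = 0.03

_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters of one simulated exposure→outcome dataset.

    theta is the true causal effect (log-odds per SD exposure);
    ``prop_invalid`` the fraction of instruments given horizontal pleiotropy
    of scale ``alpha_sd`` (mean 0 when balanced, mean ``alpha_sd`` when
    directional); ``inside_violated`` correlates pleiotropy with instrument
    strength (r = 0.5).  ``n_exp``/``n_out`` control the SE scales.
    """

    theta: float = 0.0
    L: int = 20
    prop_invalid: float = 0.0
    pleiotropy_mode: str = "balanced"
    alpha_sd: float = 0.01
    inside_violated: bool = False
    n_exp: int = 18_340
    n_out: int = 24_510
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_palindromic: float = 0.15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not (0.0 <= self.prop_invalid <= 1.0):
            raise ValueError("prop_invalid must be in [0, 1]")
        if self.pleiotropy_mode not in ("balanced", "directional"):
            raise ValueError("pleiotropy_mode must be 'balanced' or 'directional'")
        if self.alpha_sd < 0:
            raise ValueError("alpha_sd must be >= 0")
        if self.n_exp <= 0 or self.n_out <= 0:
            raise ValueError("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if not (0.0 <= self.frac_palindromic <= 1.0):
            raise ValueError("frac_palindromic must be in [0, 1]")


def _rng_from(truth_seed, seed_or_rng) -> np.random.Generator:
    if seed_or_rng is not None:
        return np.random.default_rng(seed_or_rng)
    if truth_seed is None:
        raise ValueError("a seed is required (truth.seed or the seed argument)")
    return np.random.default_rng(truth_seed)


def _draw_alleles(
    rng: np.random.Generator, L: int, frac_palindromic: float
) -> tuple[list[str], list[str]]:
    effect, other = [], []
    palindromic = rng.random(L) < frac_palindromic
    for j in range(L):
        pool = _PALINDROMIC_PAIRS if palindromic[j] else _NONPALINDROMIC_PAIRS
        a, b = pool[rng.integers(len(pool))]
        if rng.random() < 0.5:
            a, b = b, a
        effect.append(a)
        other.append(b)
    return effect, other


def simulate_pair(
    truth: SyntheticTruth,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
    snp_offset: int = 0,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], pd.DataFrame]:
    """Simulate one exposure table, one outcome table and a truth sidecar.

    The two tables share SNP ids (``rs{snp_offset+j+1}``), alleles and
    frequencies; the truth sidecar records each SNP's true effect, its
    pleiotropic effect and a validity label.  ``seed`` overrides
    ``truth.seed`` (useful for replicate studies of one configuration).
    """
    rng = _rng_from(truth.seed, seed)
    L = truth.L

    maf = rng.uniform(*truth.maf_range, size=L)
    a = (0.0 - _GAMMA_MEAN) / _GAMMA_SD
    gamma_true = stats.truncnorm.rvs(
        a, np.inf, loc=_GAMMA_MEAN, scale=_GAMMA_SD, size=L, random_state=rng
    )
    sigma_x = 1.0 / np.sqrt(2.0 * truth.n_exp * maf * (1.0 - maf))
    sigma_y = 1.0 / np.sqrt(2.0 * truth.n_out * maf * (1.0 - maf))

    n_invalid = int(round(truth.prop_invalid * L))
    invalid = np.zeros(L, dtype=bool)
    if n_invalid:
        invalid[rng.choice(L, size=n_invalid, replace=False)] = True
    alpha = np.zeros(L)
    if n_invalid:
        m = truth.alpha_sd if truth.pleiotropy_mode == "directional" else 0.0
        eps = rng.normal(size=n_invalid)
        if truth.inside_violated:
            z_gamma = (gamma_true[invalid] - _GAMMA_MEAN) / _GAMMA_SD
            alpha[invalid] = m + truth.alpha_sd * (
                0.5 * z_gamma + np.sqrt(1 - 0.25) * eps
            )
        else:
            alpha[invalid] = m + truth.alpha_sd * eps

    Gamma_true = truth.theta * gamma_true + alpha
    gamma_hat = rng.normal(gamma_true, sigma_x)
    Gamma_hat = rng.normal(Gamma_true, sigma_y)

    p_exp = 2.0 * stats.norm.sf(np.abs(gamma_hat / sigma_x))
    p_out = 2.0 * stats.norm.sf(np.abs(Gamma_hat / sigma_y))
    # Wald p-values of exactly 0 underflow only at |z|>~38; clamp into (0,1]
    tiny = np.finfo(float).tiny
    p_exp = np.clip(p_exp, tiny, 1.0)
    p_out = np.clip(p_out, tiny, 1.0)

    effect_allele, other_allele = _draw_alleles(rng, L, truth.frac_palindromic)
    snp_ids = [f"rs{snp_offset + j + 1}" for j in range(L)]
    chroms = [str(1 + (j % 22)) for j in range(L)]
    positions = [1_000_000 + 30_000_000 * (j // 22) for j in range(L)]

    exposure, outcome = [], []
    for j in range(L):
        common = dict(
            snp_id=snp_ids[j],
            effect_allele=effect_allele[j],
            other_allele=other_allele[j],
            eaf=float(maf[j]),
            chrom=chroms[j],
            pos=positions[j],
        )
        exposure.append(
            SummaryStatRecord(
                beta=float(gamma_hat[j]),
                se=float(sigma_x[j]),
                pval=float(p_exp[j]),
                n=truth.n_exp,
                **common,
            )
        )
        outcome.append(
            SummaryStatRecord(
                beta=float(Gamma_hat[j]),
                se=float(sigma_y[j]),
                pval=float(p_out[j]),
                n=truth.n_out,
                **common,
            )
        )

    sidecar = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "gamma_true": gamma_true,
            "alpha": alpha,
            "valid": ~invalid,
        }
    )
    return exposure, outcome, sidecar


@dataclass
class ExposureBundle:
    """Multi-taxon simulation output: per-taxon exposures, shared outcome."""

    exposures: list[tuple[str, str, list[SummaryStatRecord]]]
    outcome: list[SummaryStatRecord]
    truth: dict[str, dict] = field(default_factory=dict)


RANKS = ("phylum", "class", "order", "family", "genus")


def simulate_multitaxon(
    n_per_rank: Mapping[str, int],
    signal_spec: Mapping[str, float] | None = None,
    defaults: SyntheticTruth | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> ExposureBundle:
    """Simulate a panel of taxa across taxonomic ranks with a shared outcome.

    ``n_per_rank`` maps rank name to taxon count; taxa are labelled
    ``{rank}.taxon{i}``.  ``signal_spec`` assigns a nonzero causal effect to
    selected taxa (all others get theta = 0); unknown names are an error.
    Each taxon receives its own block of SNP ids; the shared outcome table is
    the concatenation of the per-taxon outcome rows.
    """
    if defaults is None:
        defaults = SyntheticTruth()
    signal_spec = dict(signal_spec or {})
    for rank in n_per_rank:
        if rank not in RANKS:
            raise ValueError(f"unknown taxonomic rank {rank!r}")

    names = [
        f"{rank}.taxon{i + 1}"
        for rank in RANKS
        if rank in n_per_rank
        for i in range(n_per_rank[rank])
    ]
    unknown = set(signal_spec) - set(names)
    if unknown:
        raise ValueError(f"signal_spec references unknown taxa: {sorted(unknown)}")

    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(len(names))

    exposures: list[tuple[str, str, list[SummaryStatRecord]]] = []
    outcome_rows: list[SummaryStatRecord] = []
    truth_manifest: dict[str, dict] = {}
    offset = 0
    for name, child in zip(names, children):
        rank = name.split(".", 1)[0]
        theta = signal_spec.get(name, 0.0)
        truth = replace(defaults, theta=theta, seed=None)
        exp_rows, out_rows, sidecar = simulate_pair(
            truth, seed=child, snp_offset=offset
        )
        offset += truth.L
        exposures.append((name, rank, exp_rows))
        outcome_rows.extend(out_rows)
        truth_manifest[name] = {
            "rank": rank,
            "theta": theta,
            "L": truth.L,
            "snp_ids": list(sidecar["snp_id"]),
        }
    return ExposureBundle(
        exposures=exposures, outcome=outcome_rows, truth=truth_manifest
    )


def make_flipped_copy(
    records: Sequence[SummaryStatRecord], mode: str = "swap"
) -> list[SummaryStatRecord]:
    """Emit an allele-transformed copy of a table to exercise harmonization.

    ``swap``: exchange the alleles and negate beta (mirror eaf) — a valid
    re-description of the same associations; ``strand``: complement both
    alleles (opposite-strand report, effects unchanged); ``both``: apply
    both transforms.
    """
    if mode not in ("swap", "strand", "both"):
        raise ValueError("mode must be 'swap', 'strand' or 'both'")
    out = []
    for r in records:
        ea, oa, beta, eaf = r.effect_allele, r.other_allele, r.beta, r.eaf
        if mode in ("swap", "both"):
            ea, oa = oa, ea
            beta = -beta
            eaf = None if eaf is None else 1.0 - eaf
        if mode in ("strand", "both"):
            ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
        out.append(
            SummaryStatRecord(
                snp_id=r.snp_id,
                effect_allele=ea,
                other_allele=oa,
                beta=beta,
                se=r.se,
                pval=r.pval,
                eaf=eaf,
                n=r.n,
                chrom=r.chrom,
                pos=r.pos,
            )
        )
    return out


def plant_outliers(
    hset: HarmonizedSet,
    indices: Sequence[int],
    size: float = 10.0,
) -> HarmonizedSet:
    """Add a pleiotropic offset of ``size``·σ_yj to selected outcome effects.

    Returns a modified copy; used by planted-truth diagnostics tests.
    """
    out = hset.subset(np.arange(hset.n_snp))
    Gamma = out.Gamma_hat.copy()
    for j in indices:
        Gamma[j] = Gamma[j] + size * out.sigma_y[j]
    out.Gamma_hat = Gamma
    return out


def harmonized_from_tables(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    pair_label: str = "",
) -> HarmonizedSet:
    """Harmonize simulated tables (convenience: they share alleles already)."""
    from .sumstats_io import harmonize

    return harmonize(exposure, outcome, pair_label=pair_label)
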