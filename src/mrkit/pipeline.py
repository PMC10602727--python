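"""Orchestration of the full bidirectional MR analysis across many exposures.

Forward direction: each bacterial taxon (phylum/class/order/family/genus) is
an exposure and the disease the outcome.  Per taxon the stages run in the
quality-control order: p-value selection → LD clumping → confounder-SNP
exclusion → weak-instrument (F) filtering → harmonization → iterative
MR-PRESSO outlier removal → (if at least three instruments survive) the five
estimators plus diagnostics.  Taxa with fewer than three shared SNPs are
excluded with that reason; other per-taxon failures are quarantined, never
fatal to the run.

Multiple testing is controlled per taxonomic rank: the significance
threshold is alpha divided by the number of taxa with a reported result at
that rank, so a rank with n reported taxa uses P < 0.05/n on the IVW
p-value.  Reverse direction: the disease becomes the exposure (instrument
p-value ceiling 5e-8, genome-wide) and each previously identified taxon the
outcome; an IVW p >= 0.05 flags absence of reverse causation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .estimators import METHODS, MREstimate, all_estimates, ivw
from .iv_selection import (
    ClumpingParams,
    LDMatrix,
    clump,
    exclude_confounder_snps,
    filter_weak_instruments,
    select_candidates,
)
from .pleiotropy import (
    HeterogeneityReport,
    LeaveOneOutResult,
    PressoReport,
    cochran_q,
    leave_one_out,
    sequential_outlier_removal,
)
from .sumstats_io import HarmonizedSet, SummaryStatRecord, harmonize

__all__ = [
    "AnalysisConfig",
    "ExposureTable",
    "TaxonResult",
    "ForwardResult",
    "rank_threshold",
    "run_forward",
    "run_reverse",
    "write_report",
]

RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class AnalysisConfig:
    """Every threshold and seed of the analysis, in one place.

    Defaults are the conventional microbiome-MR values: instrument p-value
    ceiling 1e-5 forward / 5e-8 reverse, clumping r² < 0.001 within
    10,000 kb, F >= 10, PRESSO null distribution of 10,000 draws, 1,000
    bootstrap resamples, significance alpha 0.05.  The seed is mandatory.
    """

    seed: int
    p_select: float = 1e-5
    p_select_reverse: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0
    f_min: float = 10.0
    f_method: str = "wald"
    ivw_model: str = "re"
    n_distribution: int = 10_000
    n_boot: int = 1000
    alpha: float = 0.05
    presso_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_select", "p_select_reverse", "alpha", "presso_alpha"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.f_min < 0:
            raise ValueError("f_min must be >= 0")
        if self.n_distribution < 1 or self.n_boot < 1:
            raise ValueError("simulation counts must be positive")
        if self.f_method not in ("wald", "r2"):
            raise ValueError("f_method must be 'wald' or 'r2'")
        if self.ivw_model not in ("re", "fe"):
            raise ValueError("ivw_model must be 're' or 'fe'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config file; missing fields take the defaults above."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "seed" not in raw:
            raise ValueError("config file must set an integer seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def clumping_params(self, reverse: bool = False) -> ClumpingParams:
        return ClumpingParams(
            r2_threshold=self.r2_threshold,
            window_kb=self.window_kb,
            p_select=self.p_select_reverse if reverse else self.p_select,
        )


@dataclass
class ExposureTable:
    """One exposure's summary statistics with its taxon name and rank."""

    name: str
    rank: str
    records: list[SummaryStatRecord]

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown taxonomic rank {self.rank!r}")


@dataclass
class TaxonResult:
    """All estimates and diagnostics for one exposure–outcome pair."""

    taxon: str
    rank: str
    estimates: dict[str, MREstimate]
    heterogeneity: HeterogeneityReport | None
    presso: PressoReport | None
    egger_intercept: tuple[float, float, float] | None
    loo: LeaveOneOutResult | None
    n_snp_final: int
    stage_counts: dict[str, int]
    significant: bool = False
    nominal: bool = False
    threshold: float | None = None

    @property
    def ivw_p(self) -> float:
        return self.estimates["ivw"].pval


@dataclass
class ForwardResult:
    """Per-taxon results, exclusions and the config echo of one run."""

    results: list[TaxonResult]
    excluded: list[tuple[str, str]]
    config: AnalysisConfig
    reverse: bool = False


def rank_threshold(n_taxa_at_rank: int, alpha: float = 0.05) -> float:
    """Bonferroni-style per-rank threshold alpha/n over the taxa at a rank."""
    if n_taxa_at_rank < 1:
        raise ValueError("n_taxa_at_rank must be >= 1")
    return alpha / n_taxa_at_rank


def _analyze_pair(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    config: AnalysisConfig,
    seed: np.random.SeedSequence,
    ld: LDMatrix | None,
    exclusion: Mapping[str, str] | None,
    p_select: float,
    label: str,
) -> tuple[TaxonResult | None, str | None]:
    """Run the per-pair stage sequence; (result, None) or (None, reason)."""
    params = ClumpingParams(
        r2_threshold=config.r2_threshold,
        window_kb=config.window_kb,
        p_select=p_select,
    )
    counts: dict[str, int] = {"input": len(exposure)}
    candidates = select_candidates(exposure, p_select)
    counts["p_selected"] = len(candidates)
    clumped = clump(candidates, ld, params) if candidates else []
    counts["clumped"] = len(clumped)
    kept, _removed_conf = exclude_confounder_snps(clumped, exclusion or {})
    counts["confounder_filtered"] = len(kept)
    strong = filter_weak_instruments(kept, f_min=config.f_min, method=config.f_method)
    counts["f_filtered"] = len(strong)
    if not strong:
        return None, "no instruments after quality control"
    hset = harmonize(strong, outcome, pair_label=label)
    counts["harmonized"] = hset.n_snp

    presso_seed, est_seed = seed.spawn(2)
    presso: PressoReport | None = None
    if hset.n_snp >= 4:
        presso = sequential_outlier_removal(
            hset,
            n_distribution=config.n_distribution,
            seed=presso_seed,
            alpha=config.presso_alpha,
        )
        if presso.removed:
            hset = hset.without(presso.removed)
    counts["post_presso"] = hset.n_snp

    if hset.n_snp < 3:
        return None, "fewer than three shared SNPs"

    estimates = {
        e.method: e
        for e in all_estimates(
            hset, n_boot=config.n_boot, seed=est_seed, ivw_model=config.ivw_model
        )
    }
    het = cochran_q(hset)
    egger_fit = estimates["egger"]
    intercept = (
        egger_fit.egger_intercept,
        egger_fit.egger_intercept_se,
        egger_fit.egger_intercept_p,
    )
    loo = leave_one_out(hset, model=config.ivw_model) if hset.n_snp >= 4 else None
    return (
        TaxonResult(
            taxon=label,
            rank="",
            estimates=estimates,
            heterogeneity=het,
            presso=presso,
            egger_intercept=intercept,  # type: ignore[arg-type]
            loo=loo,
            n_snp_final=hset.n_snp,
            stage_counts=counts,
        ),
        None,
    )


def run_forward(
    exposures: Sequence[ExposureTable],
    outcome: Sequence[SummaryStatRecord],
    config: AnalysisConfig,
    ld: LDMatrix | None = None,
    exclusion: Mapping[str, str] | None = None,
) -> ForwardResult:
    """Forward MR: every taxon as exposure against one outcome table.

    Per-taxon failures are quarantined with a reason.  After all taxa run,
    the per-rank thresholds alpha/n (n = taxa with a reported result at that
    rank) set the ``significant`` flags on the IVW p-value; ``nominal``
    means IVW p < 0.05.
    """
    if not outcome:
        raise ValueError("outcome table is empty")
    results: list[TaxonResult] = []
    excluded: list[tuple[str, str]] = []
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(exposures))
    for table, child in zip(exposures, children):
        try:
            result, reason = _analyze_pair(
                table.records,
                outcome,
                config,
                child,
                ld,
                exclusion,
                config.p_select,
                table.name,
            )
        except Exception as exc:  # quarantine, never abort the panel
            excluded.append((table.name, f"failed: {exc}"))
            continue
        if result is None:
            excluded.append((table.name, reason or "excluded"))
            continue
        result.rank = table.rank
        results.append(result)

    n_by_rank: dict[str, int] = {}
    for r in results:
        n_by_rank[r.rank] = n_by_rank.get(r.rank, 0) + 1
    for r in results:
        thr = rank_threshold(n_by_rank[r.rank], config.alpha)
        r.threshold = thr
        r.nominal = r.ivw_p < 0.05
        r.significant = r.ivw_p < thr
    return ForwardResult(results=results, excluded=excluded, config=config)


def run_reverse(
    outcome_as_exposure: Sequence[SummaryStatRecord],
    identified_taxa: Sequence[ExposureTable],
    config: AnalysisConfig,
    ld: LDMatrix | None = None,
    exclusion: Mapping[str, str] | None = None,
) -> ForwardResult:
    """Reverse MR: the disease as exposure, each identified taxon as outcome.

    Instruments are selected at the genome-wide ceiling
    ``config.p_select_reverse``; a taxon's ``nominal`` flag False (IVW
    p >= 0.05) indicates no evidence of reverse causation.
    """
    if not identified_taxa:
        raise ValueError("identified_taxa must be nonempty")
    results: list[TaxonResult] = []
    excluded: list[tuple[str, str]] = []
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(identified_taxa))
    for table, child in zip(identified_taxa, children):
        try:
            result, reason = _analyze_pair(
                outcome_as_exposure,
                table.records,
                config,
                child,
                ld,
                exclusion,
                config.p_select_reverse,
                table.name,
            )
        except Exception as exc:
            excluded.append((table.name, f"failed: {exc}"))
            continue
        if result is None:
            excluded.append((table.name, reason or "excluded"))
            continue
        result.rank = table.rank
        results.append(result)

    for r in results:
        r.threshold = config.alpha
        r.nominal = r.ivw_p < 0.05
        r.significant = r.nominal
    return ForwardResult(
        results=results, excluded=excluded, config=config, reverse=True
    )


def _estimates_frame(run: ForwardResult) -> pd.DataFrame:
    rows = []
    for r in run.results:
        for method in METHODS:
            e = r.estimates[method]
            orr = e.odds_ratio()
            rows.append(
                {
                    "taxon": r.taxon,
                    "rank": r.rank,
                    "method": method,
                    "n_snp": e.n_snp,
                    "beta": e.beta,
                    "se": e.se,
                    "pval": e.pval,
                    "or": orr.or_point,
                    "ci_low": orr.ci_low,
                    "ci_high": orr.ci_high,
                }
            )
    columns = [
        "taxon", "rank", "method", "n_snp", "beta", "se", "pval",
        "or", "ci_low", "ci_high",
    ]
    return pd.DataFrame(rows, columns=columns)


def _diagnostics_frame(run: ForwardResult) -> pd.DataFrame:
    rows = []
    for r in run.results:
        if r.heterogeneity is not None:
            rows.append(
                {
                    "taxon": r.taxon,
                    "test": "cochran_q",
                    "statistic": r.heterogeneity.Q,
                    "p": r.heterogeneity.p,
                    "flag": r.heterogeneity.flag,
                }
            )
        if r.egger_intercept is not None:
            rows.append(
                {
                    "taxon": r.taxon,
                    "test": "egger_intercept",
                    "statistic": r.egger_intercept[0],
                    "p": r.egger_intercept[2],
                    "flag": r.egger_intercept[2] < 0.05,
                }
            )
        if r.presso is not None:
            rows.append(
                {
                    "taxon": r.taxon,
                    "test": "presso_global",
                    "statistic": r.presso.global_rss,
                    "p": r.presso.global_p,
                    "flag": r.presso.global_p <= 0.05,
                }
            )
        if r.loo is not None:
            rows.append(
                {
                    "taxon": r.taxon,
                    "test": "leave_one_out_driver",
                    "statistic": float(len(r.loo.estimates)),
                    "p": float("nan"),
                    "flag": r.loo.driver,
                }
            )
    return pd.DataFrame(
        rows, columns=["taxon", "test", "statistic", "p", "flag"]
    )


def write_report(run: ForwardResult, outdir: str | Path) -> dict[str, Path]:
    """Write the run's tabular reports and manifest.

    Emits ``estimates.tsv`` (taxa × methods, odds-ratio scale included),
    ``diagnostics.tsv``, ``excluded.tsv``, ``presso_removals.tsv`` and a
    ``manifest.json`` echoing the config, seeds, per-rank thresholds and
    per-stage SNP accounting.  Output is deterministic: identical inputs,
    config and seed give byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    est = _estimates_frame(run)
    paths["estimates"] = outdir / "estimates.tsv"
    est.to_csv(paths["estimates"], sep="\t", index=False, float_format="%.10g")

    diag = _diagnostics_frame(run)
    paths["diagnostics"] = outdir / "diagnostics.tsv"
    diag.to_csv(paths["diagnostics"], sep="\t", index=False, float_format="%.10g")

    excl = pd.DataFrame(run.excluded, columns=["taxon", "reason"])
    paths["excluded"] = outdir / "excluded.tsv"
    excl.to_csv(paths["excluded"], sep="\t", index=False)

    removal_rows = []
    for r in run.results:
        if r.presso is None:
            continue
        for iteration, snp_id, outlier_p, global_p_after in r.presso.audit:
            removal_rows.append(
                {
                    "taxon": r.taxon,
                    "iteration": iteration,
                    "snp_id": snp_id,
                    "outlier_p": outlier_p,
                    "global_p_after": global_p_after,
                }
            )
    removals = pd.DataFrame(
        removal_rows,
        columns=["taxon", "iteration", "snp_id", "outlier_p", "global_p_after"],
    )
    paths["presso_removals"] = outdir / "presso_removals.tsv"
    removals.to_csv(
        paths["presso_removals"], sep="\t", index=False, float_format="%.10g"
    )

    n_by_rank: dict[str, int] = {}
    for r in run.results:
        n_by_rank[r.rank] = n_by_rank.get(r.rank, 0) + 1
    manifest = {
        "direction": "reverse" if run.reverse else "forward",
        "config": run.config.to_dict(),
        "n_reported": len(run.results),
        "n_excluded": len(run.excluded),
        "taxa_per_rank": dict(sorted(n_by_rank.items())),
        "rank_thresholds": {
            rank: rank_threshold(n, run.config.alpha)
            for rank, n in sorted(n_by_rank.items())
        },
        "stage_counts": {r.taxon: r.stage_counts for r in run.results},
        "significant": sorted(r.taxon for r in run.results if r.significant),
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
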