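"""Instrumental-variable selection from exposure summary statistics.

The filter stack mirrors the standard two-sample MR quality-control recipe:
a p-value ceiling on the exposure association (1e-5 for under-powered
exposures such as microbiome taxa, 5e-8 genome-wide for the reverse
direction), greedy LD clumping to approximately independent index SNPs
(r² < 0.001 within a 10,000 kb window), removal of SNPs associated with
known confounders of the exposure–outcome relationship, and elimination of
weak instruments by the per-SNP F-statistic (F >= 10).

LD is consumed as a precomputed pairwise r² matrix (long or square TSV);
no reference panel is downloaded or read.  When no LD information is given,
clumping degrades to distance-only filtering with a warning.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sumstats_io import SummaryStatRecord

__all__ = [
    "ClumpingParams",
    "LDMatrix",
    "select_candidates",
    "clump",
    "exclude_confounder_snps",
    "f_statistic",
    "f_statistic_r2",
    "filter_weak_instruments",
    "read_ld_matrix",
    "read_exclusion_list",
]


@dataclass(frozen=True)
class ClumpingParams:
    """LD-clumping and instrument-selection thresholds.

    Defaults follow the usual microbiome-MR choices: r² ceiling 0.001,
    10,000 kb window, instrument p-value ceiling 1e-5 (use 5e-8 for a
    well-powered exposure, e.g. a disease GWAS in reverse MR).
    """

    r2_threshold: float = 0.001
    window_kb: float = 10_000.0
    p_select: float = 1e-5

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not (0.0 < self.p_select <= 1.0):
            raise ValueError("p_select must be in (0, 1]")


@dataclass
class LDMatrix:
    """Symmetric pairwise LD r² matrix over an ordered set of SNP ids."""

    snp_ids: Sequence[str]
    r2: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if np.any(self.r2 < -1e-12) or np.any(self.r2 > 1 + 1e-12):
            raise ValueError("r2 values must lie in [0, 1]")
        if not np.allclose(self.r2, self.r2.T, atol=1e-9):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-9):
            raise ValueError("r2 matrix must have unit diagonal")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        """Pairwise r²; SNPs absent from the matrix are treated as unlinked."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])


def select_candidates(
    records: Sequence[SummaryStatRecord], p_select: float
) -> list[SummaryStatRecord]:
    """Keep records with ``pval < p_select`` (strict), preserving order."""
    return [r for r in records if r.pval < p_select]


def _within_window(
    a: SummaryStatRecord, b: SummaryStatRecord, window_kb: float
) -> bool:
    # without coordinates the window condition is treated as satisfied,
    # so LD alone decides
    if a.chrom is None or b.chrom is None or a.pos is None or b.pos is None:
        return True
    if a.chrom != b.chrom:
        return False
    return abs(a.pos - b.pos) <= window_kb * 1000.0


def clump(
    records: Sequence[SummaryStatRecord],
    ld: LDMatrix | None,
    params: ClumpingParams,
) -> list[SummaryStatRecord]:
    """Greedy LD clumping to independent index SNPs.

    SNPs are ranked by ascending p-value (ties broken lexicographically on
    snp_id); the best remaining SNP becomes an index SNP and every remaining
    SNP with r² >= ``params.r2_threshold`` with it *and* within the window is
    discarded.  Index SNPs are returned in rank order.  SNPs missing from the
    LD matrix are treated as unlinked (logged); with no LD matrix at all,
    clumping is distance-only (warned).
    """
    if ld is None:
        warnings.warn(
            "no LD matrix supplied: clumping degrades to distance-only "
            "window filtering",
            stacklevel=2,
        )
    else:
        missing = [r.snp_id for r in records if r.snp_id not in ld]
        if missing:
            warnings.warn(
                f"{len(missing)} SNP(s) absent from the LD matrix are "
                "treated as unlinked",
                stacklevel=2,
            )

    ranked = sorted(records, key=lambda r: (r.pval, r.snp_id))
    kept: list[SummaryStatRecord] = []
    discarded: set[str] = set()
    for i, index_snp in enumerate(ranked):
        if index_snp.snp_id in discarded:
            continue
        kept.append(index_snp)
        for other in ranked[i + 1 :]:
            if other.snp_id in discarded:
                continue
            r2 = 1.0 if ld is None else ld.r2_between(index_snp.snp_id, other.snp_id)
            if r2 >= params.r2_threshold and _within_window(
                index_snp, other, params.window_kb
            ):
                discarded.add(other.snp_id)
    return kept


def exclude_confounder_snps(
    records: Sequence[SummaryStatRecord],
    exclusion_list: Mapping[str, str],
) -> tuple[list[SummaryStatRecord], list[tuple[str, str]]]:
    """Remove SNPs associated with known confounders of the outcome.

    ``exclusion_list`` maps snp_id to the annotated confounding trait (the
    role a PhenoScanner-style lookup plays in practice).  Returns the
    retained records and an audit list of ``(snp_id, trait)`` removals.
    """
    kept: list[SummaryStatRecord] = []
    removed: list[tuple[str, str]] = []
    for r in records:
        if r.snp_id in exclusion_list:
            removed.append((r.snp_id, exclusion_list[r.snp_id]))
        else:
            kept.append(r)
    return kept, removed


def f_statistic(beta: float, se: float) -> float:
    """Single-instrument Wald F-statistic, F = (beta/se)²."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def f_statistic_r2(beta: float, eaf: float, n: int) -> float:
    """Variance-explained form: F = R²(N−2)/(1−R²), R² = 2·maf(1−maf)·β².

    Assumes a standardized (unit-variance) exposure.  Agrees closely with
    the Wald form at GWAS effect scales.
    """
    if not (0.0 < eaf < 1.0):
        raise ValueError("eaf must be in (0, 1)")
    if n is None or n <= 2:
        raise ValueError("n must exceed 2")
    r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
    if r2 >= 1.0:
        raise ValueError("implied R² is >= 1")
    return r2 * (n - 2) / (1.0 - r2)


def filter_weak_instruments(
    records: Sequence[SummaryStatRecord],
    f_min: float = 10.0,
    method: str = "wald",
) -> list[SummaryStatRecord]:
    """Retain records with F >= ``f_min`` (boundary inclusive).

    ``method`` selects the F formula: ``wald`` = (beta/se)², ``r2`` = the
    variance-explained form (requires eaf and n on every record).
    """
    if method not in ("wald", "r2"):
        raise ValueError("method must be 'wald' or 'r2'")
    kept = []
    for r in records:
        if method == "wald":
            f = f_statistic(r.beta, r.se)
        else:
            if r.eaf is None or r.n is None:
                raise ValueError(
                    f"record {r.snp_id}: eaf and samplesize required for r2 F"
                )
            f = f_statistic_r2(r.beta, r.eaf, r.n)
        if f >= f_min:
            kept.append(r)
    return kept


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read an LD r² matrix from TSV.

    Accepts either long form with columns ``snp_a, snp_b, r2`` or a square
    matrix with SNP ids as header row and first column.  Long form fills
    unlisted pairs with 0.
    """
    path = Path(path)
    head = pd.read_csv(path, sep="\t", nrows=0)
    if {"snp_a", "snp_b", "r2"}.issubset(head.columns):
        long = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
        ids = sorted(set(long["snp_a"]) | set(long["snp_b"]))
        index = {s: i for i, s in enumerate(ids)}
        mat = np.eye(len(ids))
        for a, b, r2 in zip(long["snp_a"], long["snp_b"], long["r2"]):
            mat[index[a], index[b]] = r2
            mat[index[b], index[a]] = r2
        return LDMatrix(snp_ids=ids, r2=mat)
    square = pd.read_csv(path, sep="\t", index_col=0)
    return LDMatrix(snp_ids=[str(c) for c in square.columns], r2=square.to_numpy())


def read_exclusion_list(path: str | Path) -> dict[str, str]:
    """Read a confounder-SNP exclusion TSV with columns ``snp_id, trait``."""
    out: dict[str, str] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "snp_id" not in reader.fieldnames:
            raise ValueError("exclusion list needs columns snp_id, trait")
        for row in reader:
            out[row["snp_id"]] = row.get("trait", "") or ""
    return out
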