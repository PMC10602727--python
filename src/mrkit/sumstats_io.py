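"""Read, validate and write GWAS summary-statistics tables, and harmonize
exposure/outcome pairs onto a shared effect-allele frame.

Two-sample Mendelian randomization consumes one association table per trait,
one row per SNP: identifier, effect allele, other allele, effect size (beta,
log-odds for binary traits), its standard error, p-value, and optionally
effect-allele frequency, sample size and genomic coordinates.  Tables are
tab-separated text with a canonical header; a column map adapts foreign
headers.  Missing optional fields are written as ``.``.

Harmonization aligns the outcome table onto the exposure's effect alleles:
swapped alleles flip the outcome beta's sign (and mirror the frequency),
strand flips (complement bases) are reconciled for non-palindromic SNPs, and
palindromic (A/T, C/G) SNPs — whose strand cannot be resolved from alleles
alone — are always dropped, never rescued by allele-frequency inference.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SummaryStatRecord",
    "HarmonizedSet",
    "SumstatsError",
    "ColumnError",
    "CANONICAL_COLUMNS",
    "read_sumstats",
    "write_sumstats",
    "is_palindromic",
    "harmonize",
    "write_audit",
]

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical TSV header, in file order
CANONICAL_COLUMNS = (
    "SNP",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
    "eaf",
    "samplesize",
    "chr",
    "pos",
)

MANDATORY_COLUMNS = ("SNP", "effect_allele", "other_allele", "beta", "se", "pval")


class SumstatsError(ValueError):
    """Invalid summary-statistics content."""


class ColumnError(SumstatsError):
    """A mandatory column is absent from the table (configuration error)."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association summary for one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (log-odds for case/control traits); ``se`` its standard error; ``pval``
    the association p-value; ``eaf`` the effect-allele frequency; ``n`` the
    sample size; ``chrom``/``pos`` optional 1-based coordinates used only for
    window-based clumping.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None
    chrom: str | None = None
    pos: int | None = None

    def validation_error(self) -> str | None:
        """Return a human-readable reason this record is invalid, or None."""
        if self.effect_allele not in VALID_BASES:
            return f"invalid effect allele {self.effect_allele!r}"
        if self.other_allele not in VALID_BASES:
            return f"invalid other allele {self.other_allele!r}"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if not np.isfinite(self.beta):
            return "non-finite beta"
        if not np.isfinite(self.se) or self.se <= 0:
            return "nonpositive SE"
        if not (0.0 < self.pval <= 1.0):
            return "p-value outside (0,1]"
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            return "EAF outside (0,1)"
        if self.n is not None and self.n <= 0:
            return "nonpositive sample size"
        return None


def _parse_optional_str(text: str | None) -> str | None:
    text = (text or "").strip()
    return None if text in ("", ".") else text


def _parse_optional_float(text: str | None) -> float | None:
    if text is None or text == "" or text == ".":
        return None
    return float(text)


def _parse_optional_int(text: str | None) -> int | None:
    if text is None or text == "" or text == ".":
        return None
    return int(float(text))


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[SummaryStatRecord], list[tuple[int, str]]]:
    """Read a summary-statistics TSV.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    column_map
        Optional ``{canonical_name: header_in_file}`` mapping adapting a
        foreign header; canonical names are those in :data:`CANONICAL_COLUMNS`.

    Returns
    -------
    (records, rejected)
        ``records`` in file order, one per valid row; ``rejected`` holds
        ``(data_row_number, reason)`` for every malformed row (1-based,
        header excluded).

    Raises
    ------
    ColumnError
        If a mandatory column is missing after applying the map.
    """
    path = Path(path)
    column_map = dict(column_map or {})
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        resolved: dict[str, str] = {}
        for canonical in CANONICAL_COLUMNS:
            source = column_map.get(canonical, canonical)
            if source in header:
                resolved[canonical] = source
        missing = [c for c in MANDATORY_COLUMNS if c not in resolved]
        if missing:
            raise ColumnError(
                f"{path.name}: missing mandatory column(s) {', '.join(missing)}"
            )

        records: list[SummaryStatRecord] = []
        rejected: list[tuple[int, str]] = []
        for row_number, row in enumerate(reader, start=1):
            def get(canonical: str) -> str | None:
                src = resolved.get(canonical)
                return row.get(src) if src is not None else None

            try:
                record = SummaryStatRecord(
                    snp_id=(get("SNP") or "").strip(),
                    effect_allele=(get("effect_allele") or "").strip().upper(),
                    other_allele=(get("other_allele") or "").strip().upper(),
                    beta=float(get("beta")),  # type: ignore[arg-type]
                    se=float(get("se")),  # type: ignore[arg-type]
                    pval=float(get("pval")),  # type: ignore[arg-type]
                    eaf=_parse_optional_float(get("eaf")),
                    n=_parse_optional_int(get("samplesize")),
                    chrom=_parse_optional_str(get("chr")),
                    pos=_parse_optional_int(get("pos")),
                )
            except (TypeError, ValueError):
                rejected.append((row_number, "non-numeric or missing field"))
                continue
            if not record.snp_id:
                rejected.append((row_number, "empty SNP identifier"))
                continue
            reason = record.validation_error()
            if reason is not None:
                rejected.append((row_number, reason))
                continue
            records.append(record)
    return records, rejected


def write_sumstats(records: Iterable[SummaryStatRecord], path: str | Path) -> None:
    """Write records as a canonical-header TSV (``.`` for missing optionals)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.snp_id,
                    r.effect_allele,
                    r.other_allele,
                    repr(float(r.beta)),
                    repr(float(r.se)),
                    repr(float(r.pval)),
                    "." if r.eaf is None else repr(float(r.eaf)),
                    "." if r.n is None else str(int(r.n)),
                    "." if r.chrom is None else r.chrom,
                    "." if r.pos is None else str(int(r.pos)),
                ]
            )


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (strand-ambiguous SNP)."""
    if effect_allele not in VALID_BASES or other_allele not in VALID_BASES:
        raise SumstatsError(
            f"invalid allele pair ({effect_allele!r}, {other_allele!r})"
        )
    if effect_allele == other_allele:
        raise SumstatsError("alleles must differ")
    return COMPLEMENT[effect_allele] == other_allele


@dataclass
class HarmonizedSet:
    """Aligned per-SNP exposure/outcome effects for one trait pair, post QC.

    Parallel vectors: ``gamma_hat``/``sigma_x`` are the exposure effect and SE
    of SNP j, ``Gamma_hat``/``sigma_y`` the outcome effect and SE, all on the
    exposure's effect allele.  ``dropped`` audits every input SNP not
    retained; ``actions`` records how each retained SNP was reconciled.
    """

    pair_label: str
    snp_ids: np.ndarray
    gamma_hat: np.ndarray
    sigma_x: np.ndarray
    Gamma_hat: np.ndarray
    sigma_y: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)
    actions: list[tuple[str, str]] = field(default_factory=list)
    eaf_exposure: np.ndarray | None = None
    eaf_outcome: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.gamma_hat = np.asarray(self.gamma_hat, dtype=float)
        self.sigma_x = np.asarray(self.sigma_x, dtype=float)
        self.Gamma_hat = np.asarray(self.Gamma_hat, dtype=float)
        self.sigma_y = np.asarray(self.sigma_y, dtype=float)
        lengths = {
            len(self.snp_ids),
            len(self.gamma_hat),
            len(self.sigma_x),
            len(self.Gamma_hat),
            len(self.sigma_y),
        }
        if len(lengths) != 1:
            raise ValueError("harmonized vectors must share one length")

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    @classmethod
    def from_arrays(
        cls,
        gamma_hat: Sequence[float],
        sigma_x: Sequence[float],
        Gamma_hat: Sequence[float],
        sigma_y: Sequence[float],
        snp_ids: Sequence[str] | None = None,
        pair_label: str = "",
    ) -> "HarmonizedSet":
        """Build a set directly from effect vectors (testing/simulation aid)."""
        if snp_ids is None:
            snp_ids = [f"snp{i}" for i in range(len(list(gamma_hat)))]
        return cls(
            pair_label=pair_label,
            snp_ids=np.asarray(snp_ids, dtype=object),
            gamma_hat=np.asarray(gamma_hat, dtype=float),
            sigma_x=np.asarray(sigma_x, dtype=float),
            Gamma_hat=np.asarray(Gamma_hat, dtype=float),
            sigma_y=np.asarray(sigma_y, dtype=float),
        )

    def subset(self, keep: np.ndarray) -> "HarmonizedSet":
        """Return a copy restricted to boolean mask / index array ``keep``."""
        keep = np.asarray(keep)
        return HarmonizedSet(
            pair_label=self.pair_label,
            snp_ids=self.snp_ids[keep],
            gamma_hat=self.gamma_hat[keep],
            sigma_x=self.sigma_x[keep],
            Gamma_hat=self.Gamma_hat[keep],
            sigma_y=self.sigma_y[keep],
            dropped=list(self.dropped),
            actions=list(self.actions),
            eaf_exposure=None if self.eaf_exposure is None else self.eaf_exposure[keep],
            eaf_outcome=None if self.eaf_outcome is None else self.eaf_outcome[keep],
        )

    def without(self, snp_ids: Iterable[str]) -> "HarmonizedSet":
        """Return a copy excluding the given SNP identifiers."""
        exclude = set(snp_ids)
        keep = np.array([s not in exclude for s in self.snp_ids], dtype=bool)
        return self.subset(keep)


def _check_unique(records: Sequence[SummaryStatRecord], label: str) -> dict:
    by_id: dict[str, SummaryStatRecord] = {}
    for r in records:
        if r.snp_id in by_id:
            raise SumstatsError(
                f"duplicate snp_id {r.snp_id!r} in {label} table (ambiguous join)"
            )
        by_id[r.snp_id] = r
    return by_id


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    pair_label: str = "",
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect alleles.

    Reconciliation order per shared SNP: palindromic pairs are dropped
    unconditionally; identical alleles are kept as-is; swapped alleles flip
    the outcome beta's sign and mirror its frequency; strand complements
    (with or without a swap) are reconciled the same way; anything else is
    dropped as ``incompatible alleles``.  SNPs present in only one table are
    dropped as ``unmatched``.  Duplicated identifiers within one table are a
    hard error.
    """
    exp_by_id = _check_unique(exposure, "exposure")
    out_by_id = _check_unique(outcome, "outcome")

    dropped: list[tuple[str, str]] = []
    actions: list[tuple[str, str]] = []
    ids: list[str] = []
    gamma, sx, Gamma, sy = [], [], [], []
    eaf_x: list[float] = []
    eaf_y: list[float] = []
    any_eaf_x = any_eaf_y = False

    for e in exposure:
        o = out_by_id.get(e.snp_id)
        if o is None:
            dropped.append((e.snp_id, "unmatched"))
            continue
        if is_palindromic(e.effect_allele, e.other_allele):
            dropped.append((e.snp_id, "palindromic"))
            continue
        if is_palindromic(o.effect_allele, o.other_allele):
            # exposure pair is unambiguous, outcome pair is A/T or C/G:
            # the two cannot describe the same variant
            dropped.append((e.snp_id, "incompatible alleles"))
            continue

        ea, oa = e.effect_allele, e.other_allele
        pair = (o.effect_allele, o.other_allele)
        comp = (COMPLEMENT[o.effect_allele], COMPLEMENT[o.other_allele])
        if pair == (ea, oa):
            flip, action = False, "kept"
        elif pair == (oa, ea):
            flip, action = True, "flipped"
        elif comp == (ea, oa):
            flip, action = False, "strand_flipped"
        elif comp == (oa, ea):
            flip, action = True, "strand_flipped,flipped"
        else:
            dropped.append((e.snp_id, "incompatible alleles"))
            continue

        ids.append(e.snp_id)
        gamma.append(e.beta)
        sx.append(e.se)
        Gamma.append(-o.beta if flip else o.beta)
        sy.append(o.se)
        actions.append((e.snp_id, action))
        if e.eaf is not None:
            any_eaf_x = True
        eaf_x.append(np.nan if e.eaf is None else e.eaf)
        if o.eaf is not None:
            any_eaf_y = True
        eaf_y.append(
            np.nan if o.eaf is None else (1.0 - o.eaf if flip else o.eaf)
        )

    for o in outcome:
        if o.snp_id not in exp_by_id:
            dropped.append((o.snp_id, "unmatched"))

    return HarmonizedSet(
        pair_label=pair_label,
        snp_ids=np.asarray(ids, dtype=object),
        gamma_hat=np.asarray(gamma, dtype=float),
        sigma_x=np.asarray(sx, dtype=float),
        Gamma_hat=np.asarray(Gamma, dtype=float),
        sigma_y=np.asarray(sy, dtype=float),
        dropped=dropped,
        actions=actions,
        eaf_exposure=np.asarray(eaf_x, dtype=float) if any_eaf_x else None,
        eaf_outcome=np.asarray(eaf_y, dtype=float) if any_eaf_y else None,
    )


def write_audit(hset: HarmonizedSet, path: str | Path) -> None:
    """Write the harmonization audit trail as TSV (snp_id, action, reason)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["snp_id", "action", "reason"])
        for snp_id, action in hset.actions:
            writer.writerow([snp_id, "retained", action])
        for snp_id, reason in hset.dropped:
            writer.writerow([snp_id, "dropped", reason])
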