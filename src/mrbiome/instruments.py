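"""Instrument selection for summary-level Mendelian randomization.

Selection proceeds through significance and minor-allele-frequency filters,
greedy LD clumping against a pairwise r² reference, an instrument-strength
filter (F > 10), and finally Steiger directionality filtering on the
harmonized exposure–outcome table.

The per-SNP variance explained is computed from allele frequency, effect
size, its standard error, and the sample size as

    R² = (2·EAF·(1−EAF)·β²) / [2·EAF·(1−EAF)·β² + 2·EAF·(1−EAF)·N·SE(β)²]

which simplifies algebraically to β² / (β² + N·SE²), and the instrument
strength as F = R²·(N−2)/(1−R²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, MRBiomeError
from .gwas_io import HarmonizedTable, LDReference, SummaryStatSet

__all__ = [
    "InstrumentSet",
    "SteigerVerdict",
    "filter_by_pvalue",
    "filter_by_maf",
    "ld_clump",
    "variance_explained",
    "f_statistic",
    "steiger_filter",
    "select_instruments",
]


@dataclass
class InstrumentSet:
    """Selected instruments with strength statistics and a selection audit.

    ``records`` carries the retained summary rows plus ``r2_trait`` (variance
    explained) and ``f_stat`` columns.  ``audit`` counts removals per filter
    stage; the counts plus the retained total equal the pre-filter count.
    """

    trait_name: str
    records: pd.DataFrame
    audit: dict = field(default_factory=dict)
    pvalue_threshold_used: float | None = None

    def __len__(self) -> int:
        return len(self.records)

    def to_summary_set(self, template: SummaryStatSet) -> SummaryStatSet:
        from .gwas_io import SUMMARY_COLUMNS

        return template.replace_records(self.records[SUMMARY_COLUMNS])


@dataclass
class SteigerVerdict:
    snp_id: str
    r2_exposure: float
    r2_outcome: float
    verdict: str  # "TRUE" | "FALSE" | "untestable"


# ---------------------------------------------------------------------------
# marginal filters
# ---------------------------------------------------------------------------

def filter_by_pvalue(sset: SummaryStatSet, threshold: float) -> SummaryStatSet:
    """Retain records with p-value strictly below ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise DomainError(f"p-value threshold must be in (0, 1], got {threshold}")
    keep = sset.records["pvalue"] < threshold
    return sset.replace_records(sset.records.loc[keep])


def filter_by_maf(sset: SummaryStatSet, maf_min: float) -> SummaryStatSet:
    """Retain records whose minor-allele frequency is at least ``maf_min``.

    Records with missing EAF cannot be assessed and are dropped with a
    warning.
    """
    if not 0.0 <= maf_min < 0.5:
        raise DomainError(f"maf_min must be in [0, 0.5), got {maf_min}")
    eaf = sset.records["eaf"]
    no_eaf = eaf.isna()
    if no_eaf.any():
        warnings.warn(
            f"{sset.trait_name}: {int(no_eaf.sum())} record(s) lack eaf; "
            "dropped by the MAF filter (reason no_eaf)",
            stacklevel=2,
        )
    maf = np.minimum(eaf, 1.0 - eaf)
    keep = (maf >= maf_min) & ~no_eaf
    return sset.replace_records(sset.records.loc[keep])


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def ld_clump(
    sset: SummaryStatSet,
    ld: LDReference,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> SummaryStatSet:
    """Greedy LD clumping: retain index SNPs, prune their LD partners.

    Repeatedly the most significant unclaimed SNP becomes an index SNP (ties
    broken by chromosome, position, then snp_id); every unclaimed SNP on the
    same chromosome within ``window_kb`` of it with r² >= ``r2_max`` is
    pruned.  Pairs absent from the LD reference count as r² = 0.
    """
    recs = sset.records
    missing = [s for s in recs["snp_id"] if not ld.has_position(s)]
    if missing:
        raise MRBiomeError(
            f"SNP(s) missing from the LD reference position map: {missing[:5]}"
        )
    entries = []
    for snp, p in zip(recs["snp_id"], recs["pvalue"]):
        chrom, pos = ld.position(snp)
        entries.append((float(p), chrom, pos, snp))
    entries.sort()

    window_bp = window_kb * 1000.0
    claimed: set[str] = set()
    index_snps: list[str] = []
    for p, chrom, pos, snp in entries:
        if snp in claimed:
            continue
        index_snps.append(snp)
        claimed.add(snp)
        for p2, chrom2, pos2, snp2 in entries:
            if snp2 in claimed or chrom2 != chrom:
                continue
            if abs(pos2 - pos) <= window_bp and ld.r2(snp, snp2) >= r2_max:
                claimed.add(snp2)

    keep = recs["snp_id"].isin(index_snps)
    return sset.replace_records(recs.loc[keep])


# ---------------------------------------------------------------------------
# instrument strength
# ---------------------------------------------------------------------------

def variance_explained(eaf, beta, se, n):
    """Per-SNP variance in the trait explained by the variant (R²).

    Accepts scalars or arrays.  EAF enters numerator and denominator through
    the same 2·EAF·(1−EAF) factor, so the value reduces to
    β² / (β² + N·SE²) and is independent of EAF whenever EAF is interior.
    """
    eaf = np.asarray(eaf, float)
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    n = np.asarray(n, float)
    if np.any((eaf <= 0.0) | (eaf >= 1.0)):
        raise DomainError("eaf must lie strictly inside (0, 1)")
    if np.any(se <= 0.0):
        raise DomainError("se must be > 0")
    if np.any(n < 3):
        raise DomainError("n must be >= 3")
    het = 2.0 * eaf * (1.0 - eaf)
    num = het * beta**2
    den = num + het * n * se**2
    out = num / den
    return float(out) if out.ndim == 0 else out


def f_statistic(r2, n):
    """Instrument-strength F statistic, F = R²·(N−2)/(1−R²)."""
    r2 = np.asarray(r2, float)
    n = np.asarray(n, float)
    if np.any((r2 < 0.0) | (r2 >= 1.0)):
        raise DomainError("r2 must lie in [0, 1)")
    if np.any(n < 3):
        raise DomainError("n must be >= 3")
    out = r2 * (n - 2.0) / (1.0 - r2)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Steiger directionality filtering
# ---------------------------------------------------------------------------

def steiger_filter(
    table: HarmonizedTable,
) -> tuple[HarmonizedTable, list[SteigerVerdict]]:
    """Remove SNPs whose variance explained favours the reverse direction.

    Each SNP's R² with the exposure and with the outcome are compared; the
    verdict is TRUE when r2_exposure > r2_outcome (the assumed direction) and
    such SNPs are retained.  FALSE SNPs are removed.  Rows lacking EAF or N
    on either side cannot be tested: they are retained with verdict
    ``untestable`` and a warning.
    """
    t = table.table
    verdicts: list[SteigerVerdict] = []
    keep = np.ones(len(t), dtype=bool)
    n_untestable = 0
    for i, row in t.iterrows():
        testable = (
            pd.notna(row["eaf_exp"])
            and pd.notna(row["eaf_out"])
            and pd.notna(row["n_exp"])
            and pd.notna(row["n_out"])
            and 0.0 < row["eaf_exp"] < 1.0
            and 0.0 < row["eaf_out"] < 1.0
        )
        if not testable:
            n_untestable += 1
            verdicts.append(SteigerVerdict(row["snp_id"], np.nan, np.nan, "untestable"))
            continue
        r2_exp = variance_explained(row["eaf_exp"], row["beta_exp"], row["se_exp"], row["n_exp"])
        r2_out = variance_explained(row["eaf_out"], row["beta_out"], row["se_out"], row["n_out"])
        verdict = "TRUE" if r2_exp > r2_out else "FALSE"
        verdicts.append(SteigerVerdict(row["snp_id"], r2_exp, r2_out, verdict))
        if verdict == "FALSE":
            keep[i] = False
    if n_untestable:
        warnings.warn(
            f"steiger_filter: {n_untestable} row(s) untestable (missing eaf/n); retained",
            stacklevel=2,
        )
    return table.subset(keep), verdicts


# ---------------------------------------------------------------------------
# full selection pipeline
# ---------------------------------------------------------------------------

def select_instruments(
    exposure: SummaryStatSet,
    ld: LDReference,
    pvalue: float = 5e-6,
    genome_wide_pvalue: float = 5e-8,
    two_stage: bool = True,
    min_instruments: int = 3,
    maf_min: float = 0.01,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
    min_f: float = 10.0,
) -> InstrumentSet:
    """Run the full marginal selection: p-value, MAF, LD clump, F filter.

    With ``two_stage`` the genome-wide threshold (5e-8) is tried first and
    relaxed to ``pvalue`` (5e-6) when fewer than ``min_instruments`` SNPs
    survive clumping — mirroring the common practice for traits with few
    genome-wide-significant hits.
    """
    def _run(threshold: float):
        audit = {"initial": len(exposure)}
        s1 = filter_by_pvalue(exposure, threshold)
        audit["removed_pvalue"] = len(exposure) - len(s1)
        s2 = filter_by_maf(s1, maf_min)
        audit["removed_maf"] = len(s1) - len(s2)
        s3 = ld_clump(s2, ld, r2_max=r2_max, window_kb=window_kb) if len(s2) else s2
        audit["removed_clump"] = len(s2) - len(s3)
        return s3, audit

    threshold = genome_wide_pvalue if two_stage else pvalue
    selected, audit = _run(threshold)
    if two_stage and len(selected) < min_instruments and pvalue > genome_wide_pvalue:
        threshold = pvalue
        selected, audit = _run(threshold)

    recs = selected.records.copy()
    if len(recs):
        interior = (recs["eaf"] > 0) & (recs["eaf"] < 1) & recs["eaf"].notna()
        r2 = np.full(len(recs), np.nan)
        r2[interior.to_numpy()] = variance_explained(
            recs.loc[interior, "eaf"],
            recs.loc[interior, "beta"],
            recs.loc[interior, "se"],
            recs.loc[interior, "n"],
        )
        recs["r2_trait"] = r2
        recs["f_stat"] = np.where(
            np.isnan(r2), np.nan, f_statistic(np.nan_to_num(r2), recs["n"])
        )
        weak = recs["f_stat"] <= min_f
        audit["removed_weak_f"] = int(weak.sum())
        recs = recs.loc[~weak]
    else:
        recs["r2_trait"] = []
        recs["f_stat"] = []
        audit["removed_weak_f"] = 0
    audit["retained"] = len(recs)

    total = (
        audit["removed_pvalue"]
        + audit["removed_maf"]
        + audit["removed_clump"]
        + audit["removed_weak_f"]
        + audit["retained"]
    )
    if total != audit["initial"]:
        raise ConfigurationError("selection audit does not balance")  # pragma: no cover

    return InstrumentSet(
        trait_name=exposure.trait_name,
        records=recs.reset_index(drop=True),
        audit=audit,
        pvalue_threshold_used=threshold,
    )
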