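"""Bidirectional, many-taxa screening with per-level multiplicity control.

Runs the full univariable workflow (instrument selection → harmonization →
Steiger filtering → five estimators → sensitivity suite, with MR-PRESSO
outlier correction) for every exposure–outcome pair in a direction, and
classifies each pair's headline IVW p-value against a per-taxonomic-level
Bonferroni threshold 0.05/n, where n is the number of taxa actually
analyzed at that level in the run.  P-values between the level threshold
and 0.05 are classed potentially significant.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, MRBiomeError
from .estimators import EstimateBatch, MREstimate, run_all_methods
from .gwas_io import HarmonizedTable, LDReference, SummaryStatSet, harmonize
from .instruments import select_instruments, steiger_filter
from .sensitivity import SensitivityReport, sensitivity_report
from .synthetic import taxon_seed

__all__ = [
    "PipelineConfig",
    "PairResult",
    "ScreenResult",
    "bonferroni_threshold",
    "classify_significance",
    "run_direction",
    "export_results",
]

SIGNIFICANCE_CLASSES = (
    "significant",
    "potentially_significant",
    "not_significant",
    "not_estimable",
)


@dataclass
class PipelineConfig:
    """All thresholds of the screening protocol, with the study defaults."""

    pvalue_genome_wide: float = 5e-8
    pvalue_relaxed: float = 5e-6
    two_stage: bool = True
    min_instruments: int = 3
    maf_min: float = 0.01
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    min_f: float = 10.0
    alpha: float = 0.05
    palindrome_policy: str = "drop_ambiguous"
    steiger: bool = True
    presso_n_sim: int = 1000
    presso_outlier_sig: float = 0.05
    n_boot: int = 1000
    or_scale: bool = False
    seed: int = 42

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise MRBiomeError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def bonferroni_threshold(n_taxa_at_level: int) -> float:
    """Per-level multiple-testing threshold 0.05/n."""
    if n_taxa_at_level < 1:
        raise DomainError(f"taxa count must be >= 1, got {n_taxa_at_level}")
    return 0.05 / n_taxa_at_level


def classify_significance(p: float, level_threshold: float) -> str:
    """significant / potentially_significant / not_significant.

    ``significant`` below the level's Bonferroni threshold; p-values between
    the threshold and the nominal 0.05 are ``potentially_significant``.
    """
    if not 0.0 < p <= 1.0:
        raise DomainError(f"p must be in (0, 1], got {p}")
    if level_threshold > 0.05:
        raise DomainError("level threshold cannot exceed the nominal 0.05")
    if p < level_threshold:
        return "significant"
    if p < 0.05:
        return "potentially_significant"
    return "not_significant"


@dataclass
class PairResult:
    taxon: str
    level: str
    direction: str
    status: str  # "estimable" | "not_estimable"
    reason: str = ""
    n_snp: int = 0
    estimates: EstimateBatch | None = None
    sensitivity: SensitivityReport | None = None
    uncorrected_estimates: EstimateBatch | None = None
    outliers_removed: list[str] = field(default_factory=list)
    steiger_removed: list[str] = field(default_factory=list)
    headline_p: float = float("nan")
    significance_class: str = "not_estimable"
    selection_audit: dict = field(default_factory=dict)


@dataclass
class ScreenResult:
    direction: str
    pairs: list[PairResult]
    level_thresholds: dict[str, float]

    @property
    def n_estimable(self) -> int:
        return sum(p.status == "estimable" for p in self.pairs)

    @property
    def n_not_estimable(self) -> int:
        return sum(p.status != "estimable" for p in self.pairs)


def _analyze_pair(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    ld: LDReference,
    config: PipelineConfig,
    seed: int,
) -> PairResult:
    taxon = outcome.trait_name if exposure.taxon_level == "none" else exposure.trait_name
    level = outcome.taxon_level if exposure.taxon_level == "none" else exposure.taxon_level
    result = PairResult(taxon=taxon, level=level, direction="", status="not_estimable")

    instruments = select_instruments(
        exposure,
        ld,
        pvalue=config.pvalue_relaxed,
        genome_wide_pvalue=config.pvalue_genome_wide,
        two_stage=config.two_stage,
        min_instruments=config.min_instruments,
        maf_min=config.maf_min,
        r2_max=config.clump_r2,
        window_kb=config.clump_kb,
        min_f=config.min_f,
    )
    result.selection_audit = dict(instruments.audit)
    if len(instruments) == 0:
        result.reason = "no suitable instrumental variables"
        return result

    table = harmonize(
        instruments.to_summary_set(exposure),
        outcome,
        palindrome_policy=config.palindrome_policy,
    )
    if config.steiger and len(table):
        before = set(table.snp_ids)
        table, _ = steiger_filter(table)
        result.steiger_removed = sorted(before - set(table.snp_ids))
    if len(table) == 0:
        result.reason = "no instruments after harmonization"
        return result

    batch = run_all_methods(
        table, n_boot=config.n_boot, seed=seed, or_scale=config.or_scale
    )
    sens = (
        sensitivity_report(
            table,
            n_sim=config.presso_n_sim,
            outlier_sig=config.presso_outlier_sig,
            seed=seed,
        )
        if len(table) >= 2
        else None
    )

    # MR-PRESSO outlier correction: headline estimates are refit without
    # detected outliers; the uncorrected batch is kept for the record.
    if sens is not None and sens.presso is not None and sens.presso.outlier_snps:
        reduced = table.drop_snps(sens.presso.outlier_snps)
        if len(reduced) >= 1:
            result.uncorrected_estimates = batch
            result.outliers_removed = list(sens.presso.outlier_snps)
            batch = run_all_methods(
                reduced, n_boot=config.n_boot, seed=seed, or_scale=config.or_scale
            )
            table = reduced

    result.status = "estimable"
    result.n_snp = len(table)
    result.estimates = batch
    result.sensitivity = sens
    result.headline_p = batch.ivw.pvalue
    return result


def run_direction(
    trait: SummaryStatSet,
    taxa: dict[str, SummaryStatSet],
    manifest: pd.DataFrame,
    ld: LDReference,
    config: PipelineConfig,
    direction: str = "forward",
) -> ScreenResult:
    """Screen every taxon against the host trait in one causal direction.

    ``forward`` treats the trait as exposure and each taxon as outcome;
    ``reverse`` treats each taxon as exposure.  Per-pair failures (no
    instruments, missing data, estimator floors) are isolated: the batch
    always completes, recording such pairs as ``not_estimable``.  Level
    thresholds are computed from the number of estimable taxa per level.
    """
    if direction not in ("forward", "reverse"):
        raise MRBiomeError(f"direction must be forward or reverse, got {direction!r}")
    pairs: list[PairResult] = []
    for row in manifest.itertuples(index=False):
        name, level = row.taxon_name, row.level
        seed = taxon_seed(config.seed, f"{direction}:{name}")
        taxon_set = taxa.get(name)
        if taxon_set is None:
            pairs.append(
                PairResult(
                    taxon=name, level=level, direction=direction,
                    status="not_estimable", reason="summary data not available",
                )
            )
            continue
        exposure, outcome = (
            (trait, taxon_set) if direction == "forward" else (taxon_set, trait)
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = _analyze_pair(exposure, outcome, ld, config, seed)
        except Exception as exc:  # per-pair isolation: batch must complete
            result = PairResult(
                taxon=name, level=level, direction=direction,
                status="not_estimable", reason=f"{type(exc).__name__}: {exc}",
            )
        result.taxon, result.level, result.direction = name, level, direction
        pairs.append(result)

    level_counts: dict[str, int] = {}
    for p in pairs:
        if p.status == "estimable":
            level_counts[p.level] = level_counts.get(p.level, 0) + 1
    thresholds = {lvl: bonferroni_threshold(n) for lvl, n in level_counts.items()}
    for p in pairs:
        if p.status != "estimable":
            p.significance_class = "not_estimable"
        else:
            p.significance_class = classify_significance(
                min(max(p.headline_p, np.finfo(float).tiny), 1.0),
                thresholds[p.level],
            )
    return ScreenResult(direction=direction, pairs=pairs, level_thresholds=thresholds)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_ESTIMATE_COLS = [
    "taxon", "level", "direction", "method", "nsnp", "beta", "se",
    "ci_low", "ci_high", "pval", "or", "or_ci_low", "or_ci_high",
    "significance_class",
]


def _estimate_rows(result: ScreenResult):
    for p in result.pairs:
        if p.estimates is None:
            continue
        for e in p.estimates.estimates:
            if not e.estimable:
                continue
            orr = e.or_scale or (np.nan, np.nan, np.nan)
            yield {
                "taxon": p.taxon, "level": p.level, "direction": p.direction,
                "method": e.method, "nsnp": e.n_snp, "beta": e.beta, "se": e.se,
                "ci_low": e.ci_low, "ci_high": e.ci_high, "pval": e.pvalue,
                "or": orr[0], "or_ci_low": orr[1], "or_ci_high": orr[2],
                "significance_class": p.significance_class,
            }


def _sensitivity_dict(p: PairResult) -> dict:
    s = p.sensitivity
    if s is None:
        return {}
    out = {
        "q_ivw": {"Q": s.q_ivw[0], "df": s.q_ivw[1], "p": s.q_ivw[2]},
        "steiger_removed": p.steiger_removed,
        "outliers_removed": p.outliers_removed,
        "funnel": [
            {"snp_id": sid, "ratio": r, "precision": prec} for sid, r, prec in s.funnel
        ],
    }
    if s.q_egger is not None:
        out["q_egger"] = {"Q": s.q_egger[0], "df": s.q_egger[1], "p": s.q_egger[2]}
    if s.egger_intercept is not None:
        v, se, pv = s.egger_intercept
        out["egger_intercept"] = {"value": v, "se": se, "p": pv}
    if s.leave_one_out:
        out["leave_one_out"] = [
            {
                "snp_id": e.snp_id, "beta": e.estimate.beta, "se": e.estimate.se,
                "p": e.estimate.pvalue, "flagged": e.flagged,
            }
            for e in s.leave_one_out
        ]
    if s.presso is not None and s.presso.estimable:
        out["presso"] = {
            "global_rss_obs": s.presso.global_rss_obs,
            "global_p": s.presso.global_p,
            "outlier_snps": s.presso.outlier_snps,
            "distortion_p": s.presso.distortion_p,
            "n_sim": s.presso.n_sim,
            "seed": s.presso.seed,
        }
    if p.uncorrected_estimates is not None:
        out["uncorrected_ivw"] = {
            "beta": p.uncorrected_estimates.ivw.beta,
            "p": p.uncorrected_estimates.ivw.pvalue,
        }
    return out


def export_results(result: ScreenResult, out_dir) -> dict[str, Path]:
    """Write estimates TSV, sensitivity JSON and a forest-ready long table.

    An empty result yields header-only files with a warning.  Output is
    deterministic given the input (sorted, fixed float format).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d = result.direction
    est_path = out_dir / f"estimates_{d}.tsv"
    forest_path = out_dir / f"forest_{d}.tsv"
    sens_path = out_dir / f"sensitivity_{d}.json"
    status_path = out_dir / f"status_{d}.tsv"

    rows = list(_estimate_rows(result))
    est = pd.DataFrame(rows, columns=_ESTIMATE_COLS)
    if est.empty:
        warnings.warn(f"export_results: no estimable pairs in direction {d}", stacklevel=2)
    est = est.sort_values(["level", "taxon", "method"], kind="mergesort")
    est.to_csv(est_path, sep="\t", index=False, float_format="%.10g")
    # forest-ready long table: one row per taxon x method, point + interval
    forest = est[
        ["taxon", "level", "direction", "method", "nsnp", "beta", "ci_low",
         "ci_high", "pval", "significance_class"]
    ]
    forest.to_csv(forest_path, sep="\t", index=False, float_format="%.10g")

    sens = {
        "direction": d,
        "level_thresholds": result.level_thresholds,
        "pairs": {p.taxon: _sensitivity_dict(p) for p in result.pairs},
    }
    with open(sens_path, "w") as fh:
        json.dump(sens, fh, indent=1, sort_keys=True, default=float)

    status_cols = [
        "taxon", "level", "status", "reason", "n_snp",
        "significance_class", "headline_p",
    ]
    status = pd.DataFrame(
        [
            {
                "taxon": p.taxon, "level": p.level, "status": p.status,
                "reason": p.reason, "n_snp": p.n_snp,
                "significance_class": p.significance_class,
                "headline_p": p.headline_p,
            }
            for p in result.pairs
        ],
        columns=status_cols,
    ).sort_values(["level", "taxon"], kind="mergesort")
    status.to_csv(status_path, sep="\t", index=False, float_format="%.10g")
    return {
        "estimates": est_path,
        "forest": forest_path,
        "sensitivity": sens_path,
        "status": status_path,
    }
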