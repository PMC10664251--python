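"""Multivariable Mendelian randomization (MVMR).

Jointly regresses per-SNP outcome effects on the effects for several
exposures, estimating each exposure's direct causal effect conditional on
the others.  Used here to adjust a primary exposure (nicotine dependence)
for correlated smoking phenotypes (age of smoking initiation, smoking
initiation, cigarettes per day, smoking cessation).

Instrument strength in the joint model is summarized by a conditional
F statistic per exposure: the exposure's instrument effects are residualized
on the other exposures' effects and the residual signal is scaled by the
exposure's own measurement error,

    F_cond(i) = sum_j r_ij² / se_x,ij² / (k − m + 1)

with k instruments and m exposures.  Perfectly collinear exposures get
F_cond ≈ 0; an exposure orthogonal to the others recovers roughly its mean
univariable per-SNP F.  The conventional adequacy cutoff is F > 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CollinearityError,
    ConfigurationError,
    InsufficientInstrumentsError,
)
from .gwas_io import LDReference, SummaryStatSet, harmonize
from .instruments import filter_by_pvalue, ld_clump

__all__ = [
    "MVMRInput",
    "MVMREstimate",
    "mvmr_select_instruments",
    "mvmr_ivw",
    "mvmr_egger",
    "conditional_f",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MVMRInput:
    """Aligned instrument effects for several exposures and one outcome.

    ``exposure_betas``/``exposure_ses`` are (k SNPs × m exposures) matrices
    aligned to ``snp_ids`` row-wise and ``exposure_names`` column-wise; all
    effects refer to the same per-SNP effect allele.
    """

    snp_ids: list[str]
    exposure_names: list[str]
    exposure_betas: np.ndarray
    exposure_ses: np.ndarray
    outcome_beta: np.ndarray
    outcome_se: np.ndarray

    def __post_init__(self):
        self.exposure_betas = np.asarray(self.exposure_betas, float)
        self.exposure_ses = np.asarray(self.exposure_ses, float)
        self.outcome_beta = np.asarray(self.outcome_beta, float)
        self.outcome_se = np.asarray(self.outcome_se, float)
        k, m = self.exposure_betas.shape
        if (
            self.exposure_ses.shape != (k, m)
            or self.outcome_beta.shape != (k,)
            or self.outcome_se.shape != (k,)
            or len(self.snp_ids) != k
            or len(self.exposure_names) != m
        ):
            raise ConfigurationError("MVMR matrices are not rectangular/aligned")
        if k < m + 1:
            raise InsufficientInstrumentsError(
                f"MVMR needs >= {m + 1} instruments for {m} exposures, got {k}"
            )

    @property
    def n_snp(self) -> int:
        return self.exposure_betas.shape[0]

    @property
    def n_exposure(self) -> int:
        return self.exposure_betas.shape[1]

    def reorder_exposures(self, names: list[str]) -> "MVMRInput":
        idx = [self.exposure_names.index(n) for n in names]
        return MVMRInput(
            snp_ids=list(self.snp_ids),
            exposure_names=list(names),
            exposure_betas=self.exposure_betas[:, idx],
            exposure_ses=self.exposure_ses[:, idx],
            outcome_beta=self.outcome_beta.copy(),
            outcome_se=self.outcome_se.copy(),
        )


@dataclass
class MVMREstimate:
    """Per-exposure direct effects from a joint MVMR fit."""

    model: str  # "ivw_random" | "egger"
    exposure_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalue: np.ndarray
    n_snp: int
    conditional_f: dict[str, float] | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    notes: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            name: {
                "beta": float(self.beta[i]),
                "se": float(self.se[i]),
                "ci_low": float(self.ci_low[i]),
                "ci_high": float(self.ci_high[i]),
                "pvalue": float(self.pvalue[i]),
            }
            for i, name in enumerate(self.exposure_names)
        }


# ---------------------------------------------------------------------------
# instrument selection
# ---------------------------------------------------------------------------

def mvmr_select_instruments(
    exposures: list[SummaryStatSet],
    ld: LDReference,
    pval: float = 5e-6,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
    outcome: SummaryStatSet | None = None,
    palindrome_policy: str = "drop_ambiguous",
) -> MVMRInput:
    """Select and align a joint instrument set across several exposures.

    Each exposure is filtered at ``pval``; the union of survivors is jointly
    LD-clumped using each SNP's best (minimum) p-value across exposures;
    surviving SNPs must be present in every exposure (and the outcome, when
    given) with compatible alleles.  Effects are aligned to the first
    exposure's effect alleles via the same rules as pairwise harmonization.
    """
    if len(exposures) < 2:
        raise ConfigurationError("mvmr_select_instruments needs >= 2 exposures")

    union: dict[str, tuple[float, int]] = {}  # snp -> (min p, exposure idx)
    for i, ex in enumerate(exposures):
        sig = filter_by_pvalue(ex, pval)
        for snp, p in zip(sig.records["snp_id"], sig.records["pvalue"]):
            if snp not in union or p < union[snp][0]:
                union[snp] = (float(p), i)
    if not union:
        raise InsufficientInstrumentsError("no SNP passes the p-value filter in any exposure")

    # build a combined set carrying each SNP's most significant record
    rows = []
    for snp, (_, i) in union.items():
        rec = exposures[i].records.loc[exposures[i].records["snp_id"] == snp]
        rows.append(rec.iloc[0])
    combined = SummaryStatSet(
        trait_name="mvmr_union",
        records=pd.DataFrame(rows).reset_index(drop=True),
    )
    clumped = ld_clump(combined, ld, r2_max=r2_max, window_kb=window_kb)
    candidate = clumped.records[["snp_id", "effect_allele", "other_allele"]]

    reference = exposures[0]
    ref_subset = reference.replace_records(
        reference.records[reference.records["snp_id"].isin(candidate["snp_id"])]
    )
    keep_ids: set[str] = set(ref_subset.records["snp_id"])
    targets = exposures[1:] + ([outcome] if outcome is not None else [])
    harmonized = []
    for target in targets:
        ht = harmonize(ref_subset, target, palindrome_policy=palindrome_policy)
        harmonized.append(ht)
        keep_ids &= set(ht.snp_ids)
    m = len(exposures)
    keep_ids = sorted(keep_ids)
    if len(keep_ids) < m + 1:
        raise InsufficientInstrumentsError(
            f"only {len(keep_ids)} joint instruments for {m} exposures"
        )

    ref_recs = ref_subset.records.set_index("snp_id").loc[keep_ids]
    bx = np.empty((len(keep_ids), m))
    sx = np.empty((len(keep_ids), m))
    bx[:, 0] = ref_recs["beta"].to_numpy(float)
    sx[:, 0] = ref_recs["se"].to_numpy(float)
    for j, ht in enumerate(harmonized[: m - 1], start=1):
        sub = ht.table.set_index("snp_id").loc[keep_ids]
        bx[:, j] = sub["beta_out"].to_numpy(float)
        sx[:, j] = sub["se_out"].to_numpy(float)
    if outcome is not None:
        sub = harmonized[-1].table.set_index("snp_id").loc[keep_ids]
        by = sub["beta_out"].to_numpy(float)
        sy = sub["se_out"].to_numpy(float)
    else:
        by = np.full(len(keep_ids), np.nan)
        sy = np.full(len(keep_ids), np.nan)

    return MVMRInput(
        snp_ids=list(keep_ids),
        exposure_names=[e.trait_name for e in exposures],
        exposure_betas=bx,
        exposure_ses=sx,
        outcome_beta=by,
        outcome_se=sy,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        offending = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                offending.append(names[j] if j < len(names) else f"col{j}")
        raise CollinearityError(
            f"exposure matrix rank deficient; involved: {offending}", offending
        )


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, names, df_resid: int):
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    xtx = Xw.T @ Xw
    beta = np.linalg.solve(xtx, Xw.T @ yw)
    resid = y - X @ beta
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / df_resid) if df_resid > 0 else 1.0
    cov = phi * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    return beta, se, q, phi


def mvmr_ivw(input: MVMRInput) -> MVMREstimate:
    """Multivariable random-effect IVW: weighted no-intercept regression of
    outcome effects on all exposure effects, weights 1/outcome_se².

    The covariance is scaled by max(1, Q/(k−m)) (multiplicative random
    effects floored at the fixed-effect level); per-exposure p-values are
    normal.
    """
    X = input.exposure_betas
    y = input.outcome_beta
    w = 1.0 / input.outcome_se**2
    k, m = X.shape
    _check_rank(X, input.exposure_names)
    beta, se, q, phi = _wls(X, y, w, input.exposure_names, k - m)
    z = beta / se
    return MVMREstimate(
        model="ivw_random",
        exposure_names=list(input.exposure_names),
        beta=beta,
        se=se,
        ci_low=beta - _Z95 * se,
        ci_high=beta + _Z95 * se,
        pvalue=2.0 * stats.norm.sf(np.abs(z)),
        n_snp=k,
        conditional_f=conditional_f(input) if m >= 2 else None,
        notes={"Q": q, "phi": phi, "df": k - m},
    )


def mvmr_egger(input: MVMRInput) -> MVMREstimate:
    """Multivariable Egger: as :func:`mvmr_ivw` plus a free intercept.

    Rows are oriented so the first exposure's effects are non-negative
    before fitting; the intercept and its t test (k−m−1 df) are reported.
    """
    X = input.exposure_betas.copy()
    y = input.outcome_beta.copy()
    k, m = X.shape
    if k < m + 2:
        raise InsufficientInstrumentsError(
            f"mvmr_egger needs >= {m + 2} instruments for {m} exposures, got {k}"
        )
    sign = np.where(X[:, 0] < 0, -1.0, 1.0)
    X = X * sign[:, None]
    y = y * sign
    w = 1.0 / input.outcome_se**2
    _check_rank(X, input.exposure_names)
    design = np.column_stack([np.ones(k), X])
    _check_rank(design, ["intercept"] + list(input.exposure_names))
    df = k - m - 1
    coef, se_all, q, phi = _wls(design, y, w, input.exposure_names, df)
    beta, se = coef[1:], se_all[1:]
    tq = stats.t.ppf(0.975, df)
    pvals = 2.0 * stats.t.sf(np.abs(beta / se), df)
    return MVMREstimate(
        model="egger",
        exposure_names=list(input.exposure_names),
        beta=beta,
        se=se,
        ci_low=beta - tq * se,
        ci_high=beta + tq * se,
        pvalue=pvals,
        n_snp=k,
        conditional_f=conditional_f(input) if m >= 2 else None,
        intercept=float(coef[0]),
        intercept_se=float(se_all[0]),
        intercept_p=float(2.0 * stats.t.sf(abs(coef[0] / se_all[0]), df)),
        notes={"Q": q, "phi": phi, "df": df},
    )


# ---------------------------------------------------------------------------
# conditional instrument strength
# ---------------------------------------------------------------------------

def conditional_f(input: MVMRInput) -> dict[str, float]:
    """Conditional F statistic per exposure (see module docstring).

    Each exposure's instrument effects are residualized on every other
    exposure's effects by weighted least squares (weights 1/outcome_se²);
    the residual chi-square against the exposure's own SEs, divided by
    k − m + 1, is the F-scale strength.
    """
    X = input.exposure_betas
    S = input.exposure_ses
    w = 1.0 / input.outcome_se**2
    k, m = X.shape
    if m < 2:
        raise ConfigurationError("conditional_f needs >= 2 exposures")
    out: dict[str, float] = {}
    sw = np.sqrt(w)
    for i, name in enumerate(input.exposure_names):
        target = X[:, i]
        others = np.delete(X, i, axis=1)
        Ow = others * sw[:, None]
        tw = target * sw
        coef, *_ = np.linalg.lstsq(Ow, tw, rcond=None)
        resid = target - others @ coef
        chi = float(np.sum(resid**2 / S[:, i] ** 2))
        out[name] = chi / (k - m + 1)
    return out
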