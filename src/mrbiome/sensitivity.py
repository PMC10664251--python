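"""Heterogeneity, pleiotropy and outlier diagnostics for univariable MR.

Provides Cochran's Q (IVW and Egger parameterizations), the Egger intercept
test for directional pleiotropy, leave-one-out stability analysis, funnel
plot data export, and an MR-PRESSO implementation (global residual test,
per-SNP outlier test, and a distortion test for the outlier-corrected
estimate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError
from .estimators import MREstimate, ivw, mr_egger, wald_ratios
from .gwas_io import HarmonizedTable

__all__ = [
    "SensitivityReport",
    "PressoResult",
    "LeaveOneOutEntry",
    "cochran_q",
    "egger_intercept_test",
    "leave_one_out",
    "funnel_data",
    "mr_presso",
    "sensitivity_report",
]


@dataclass
class LeaveOneOutEntry:
    snp_id: str
    estimate: MREstimate
    flagged: bool  # removal changes the sign or escapes the all-SNP CI


@dataclass
class PressoResult:
    """MR-PRESSO output.

    ``global_p`` and the per-SNP outlier p-values are Monte-Carlo estimates
    using the add-one convention (count+1)/(n_sim+1), so they are never
    exactly zero.  ``distortion_p`` is absent (None) when no outliers are
    detected.
    """

    estimable: bool
    global_rss_obs: float = math.nan
    global_p: float = math.nan
    outlier_snps: list[str] = field(default_factory=list)
    outlier_pvalues: dict[str, float] = field(default_factory=dict)
    corrected_estimate: MREstimate | None = None
    distortion_p: float | None = None
    n_sim: int = 0
    seed: int = 0
    note: str = ""


@dataclass
class SensitivityReport:
    q_ivw: tuple[float, int, float]
    q_egger: tuple[float, int, float] | None
    egger_intercept: tuple[float, float, float] | None
    leave_one_out: list[LeaveOneOutEntry]
    funnel: list[tuple[str, float, float]]
    presso: PressoResult | None


# ---------------------------------------------------------------------------
# heterogeneity
# ---------------------------------------------------------------------------

def cochran_q(table: HarmonizedTable, method: str = "ivw") -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic, its df, and chi-square p-value.

    In the regression parameterization Q = sum w_j (beta_out_j − fit_j)² with
    w_j = 1/se_out_j²; for IVW the fit is the through-origin slope (df k−1),
    for Egger the intercept model (df k−2).  Significant Q (p < 0.05) is the
    conventional trigger for random-effects IVW.
    """
    bx, sx, by, sy = table.arrays()
    k = len(bx)
    w = 1.0 / sy**2
    if method == "ivw":
        if k < 2:
            raise InsufficientInstrumentsError("cochran_q(ivw) needs >= 2 instruments")
        b = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
        resid = by - b * bx
        df = k - 1
    elif method == "egger":
        if k < 3:
            raise InsufficientInstrumentsError("cochran_q(egger) needs >= 3 instruments")
        fit = mr_egger(table)
        sign = np.where(bx < 0, -1.0, 1.0)
        resid = by * sign - fit.intercept - fit.slope.beta * (bx * sign)
        df = k - 2
    else:
        raise ValueError(f"unknown method {method!r}")
    q = float(np.sum(w * resid**2))
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(table: HarmonizedTable) -> tuple[float, float, float]:
    """Egger intercept, its SE, and the two-sided t test (k−2 df).

    A non-zero intercept indicates directional pleiotropy (the average
    pleiotropic effect across instruments).
    """
    fit = mr_egger(table)
    return fit.intercept, fit.intercept_se, fit.intercept_p


# ---------------------------------------------------------------------------
# leave-one-out and funnel
# ---------------------------------------------------------------------------

def leave_one_out(table: HarmonizedTable) -> list[LeaveOneOutEntry]:
    """Per-SNP re-estimation with that SNP removed (IVW, auto effects).

    An entry is flagged when its estimate flips sign relative to the
    all-SNP estimate or leaves the all-SNP fixed-effects confidence
    interval.  The fixed-effects interval (sampling noise only, no
    heterogeneity inflation) is the flagging reference: a single driving
    SNP inflates the random-effects interval enough to hide its own
    influence.
    """
    k = len(table)
    if k < 3:
        raise InsufficientInstrumentsError("leave_one_out needs >= 3 instruments")
    full = ivw(table, effects="auto")
    full_fixed = ivw(table, effects="fixed")
    entries = []
    for i, snp in enumerate(table.snp_ids):
        mask = np.ones(k, dtype=bool)
        mask[i] = False
        sub = ivw(table.subset(mask), effects="auto")
        flagged = bool(
            np.sign(sub.beta) != np.sign(full.beta)
            or not (full_fixed.ci_low <= sub.beta <= full_fixed.ci_high)
        )
        entries.append(LeaveOneOutEntry(snp_id=snp, estimate=sub, flagged=flagged))
    return entries


def funnel_data(table: HarmonizedTable) -> list[tuple[str, float, float]]:
    """(snp_id, Wald ratio, precision = 1/ratio SE) for funnel plotting."""
    if len(table) == 0:
        return []
    r, se_r = wald_ratios(table)
    return [
        (snp, float(ri), float(1.0 / si))
        for snp, ri, si in zip(table.snp_ids, r, se_r)
    ]


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def _loo_slopes(x: np.ndarray, y, w: np.ndarray) -> np.ndarray:
    """Leave-one-out through-origin WLS slopes.

    ``y`` may be a vector (k,) or a matrix (n_sim, k); the result matches its
    shape along the SNP axis.
    """
    wx = w * x
    wxx = w * x * x
    sxx = wxx.sum()
    if y.ndim == 1:
        sxy = float((wx * y).sum())
        return (sxy - wx * y) / (sxx - wxx)
    sxy = y @ wx  # (n_sim,)
    return (sxy[:, None] - wx[None, :] * y) / (sxx - wxx)[None, :]


def mr_presso(
    table: HarmonizedTable,
    n_sim: int = 1000,
    outlier_sig: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Pleiotropy residual sum of squares and outlier (MR-PRESSO) test.

    Global test: each SNP's outcome effect is predicted from the IVW slope
    fitted without it; the observed weighted residual sum of squares is
    compared against ``n_sim`` parametric simulations of the outcome effects
    under no pleiotropy (normal draws centred on the predictions with the
    observed SEs).  Per-SNP outlier test: the same comparison on each SNP's
    own squared distance, Bonferroni-corrected across SNPs at
    ``outlier_sig``.  When outliers are found, the IVW estimate is refitted
    without them and a distortion test compares the observed shift against
    the shifts produced by removing random same-size subsets.

    The computation is invariant to row order and bit-reproducible for a
    given seed; fewer than 4 instruments yields a not-estimable marker.
    """
    k = len(table)
    if k < 4:
        return PressoResult(estimable=False, note=f"needs >= 4 instruments, got {k}", seed=seed)

    # sort by snp_id so the outcome is invariant to input row order
    order = np.argsort(np.asarray(table.snp_ids))
    sorted_table = HarmonizedTable(table=table.table.iloc[order].reset_index(drop=True))
    snp_ids = np.asarray(sorted_table.snp_ids)

    bx, sx, by, sy = sorted_table.arrays()
    w = 1.0 / sy**2
    rng = np.random.default_rng(seed)

    theta_loo = _loo_slopes(bx, by, w)
    pred = theta_loo * bx
    d_obs = w * (by - pred) ** 2
    rss_obs = float(d_obs.sum())

    y_sim = rng.normal(loc=pred[None, :], scale=sy[None, :], size=(n_sim, k))
    theta_sim = _loo_slopes(bx, y_sim, w)
    d_sim = w[None, :] * (y_sim - theta_sim * bx[None, :]) ** 2
    rss_sim = d_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    p_snp = (1 + np.sum(d_sim >= d_obs[None, :], axis=0)) / (n_sim + 1)
    is_outlier = p_snp * k < outlier_sig  # Bonferroni across SNPs
    outlier_snps = [str(s) for s in snp_ids[is_outlier]]
    outlier_pvalues = {str(s): float(p) for s, p in zip(snp_ids, p_snp)}

    corrected = None
    distortion_p = None
    n_out = int(is_outlier.sum())
    if n_out and k - n_out >= 2:
        corrected = ivw(sorted_table.subset(~is_outlier), effects="auto")
        original = ivw(sorted_table, effects="auto")
        obs_shift = abs(original.beta - corrected.beta)
        inliers = np.where(~is_outlier)[0]
        if len(inliers) >= n_out:
            shifts = []
            n_subsets = math.comb(len(inliers), n_out)
            if n_subsets <= n_sim:
                chosen = list(combinations(inliers, n_out))
            else:
                chosen = [
                    rng.choice(inliers, size=n_out, replace=False)
                    for _ in range(n_sim)
                ]
            for subset in chosen:
                mask = np.ones(k, dtype=bool)
                mask[list(subset)] = False
                sub = ivw(sorted_table.subset(mask), effects="fixed")
                shifts.append(abs(original.beta - sub.beta))
            shifts = np.asarray(shifts)
            distortion_p = float((1 + np.sum(shifts >= obs_shift)) / (len(shifts) + 1))

    return PressoResult(
        estimable=True,
        global_rss_obs=rss_obs,
        global_p=global_p,
        outlier_snps=outlier_snps,
        outlier_pvalues=outlier_pvalues,
        corrected_estimate=corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def sensitivity_report(
    table: HarmonizedTable,
    n_sim: int = 1000,
    outlier_sig: float = 0.05,
    seed: int = 0,
) -> SensitivityReport:
    """Assemble the full diagnostic bundle for one exposure–outcome pair."""
    k = len(table)
    q_ivw = cochran_q(table, "ivw")
    q_egger = cochran_q(table, "egger") if k >= 3 else None
    intercept = egger_intercept_test(table) if k >= 3 else None
    loo = leave_one_out(table) if k >= 3 else []
    presso = mr_presso(table, n_sim=n_sim, outlier_sig=outlier_sig, seed=seed)
    return SensitivityReport(
        q_ivw=q_ivw,
        q_egger=q_egger,
        egger_intercept=intercept,
        leave_one_out=loo,
        funnel=funnel_data(table),
        presso=presso,
    )
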