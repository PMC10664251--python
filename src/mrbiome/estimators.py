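"""Univariable two-sample MR estimators.

All estimators consume a :class:`~mrbiome.gwas_io.HarmonizedTable` whose rows
are the selected instruments.  Per-SNP causal estimates are Wald ratios
(outcome effect divided by exposure effect); combined estimates are:

* IVW — inverse-variance-weighted meta-analysis of the ratios, equivalently
  a weighted regression of outcome on exposure effects through the origin
  with weights 1/se_out².  Fixed effects force the residual variance to 1;
  random effects inflate the SE by sqrt(max(1, Q/(k−1))).
* MR-Egger — the same regression with a free intercept; the intercept
  estimates the average directional pleiotropy, the slope the causal effect.
  Inference uses a t distribution with k−2 df and a multiplicative
  random-effects scale floored at 1.
* Weighted median — the 50% weighted quantile of the ordered ratios; valid
  when instruments carrying more than half the weight are valid.
* Simple / weighted mode — the argmax of a kernel-smoothed density of the
  ratios (unit or inverse-variance weights); valid when the largest group of
  instruments share the true ratio.

Bootstrap standard errors (weighted median, modes) use a parametric
bootstrap: exposure and outcome effects are redrawn from normal
distributions centred at their estimates with their reported SEs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientInstrumentsError
from .gwas_io import HarmonizedTable

__all__ = [
    "MREstimate",
    "EstimateBatch",
    "wald_ratio",
    "wald_ratios",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mode_estimate",
    "run_all_methods",
]

METHODS = (
    "ivw",
    "egger",
    "weighted_median",
    "simple_mode",
    "weighted_mode",
)

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    """A causal estimate on the per-unit-exposure (beta) scale.

    ``or_scale`` is the exp-transformed (OR, CI low, CI high) triple,
    populated only when the outcome is binary (effects are log odds ratios).
    """

    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    estimable: bool = True
    note: str = ""
    or_scale: tuple[float, float, float] | None = None

    def odds_ratio(self) -> tuple[float, float, float]:
        return (math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high))

    def with_or_scale(self) -> "MREstimate":
        if self.estimable:
            self.or_scale = self.odds_ratio()
        return self

    @classmethod
    def not_estimable(cls, method: str, n_snp: int, note: str) -> "MREstimate":
        return cls(
            method=method,
            n_snp=n_snp,
            beta=math.nan,
            se=math.nan,
            ci_low=math.nan,
            ci_high=math.nan,
            pvalue=math.nan,
            estimable=False,
            note=note,
        )


def _normal_estimate(method, n_snp, beta, se, note="") -> MREstimate:
    z = beta / se
    return MREstimate(
        method=method,
        n_snp=int(n_snp),
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z95 * se),
        ci_high=float(beta + _Z95 * se),
        pvalue=float(2.0 * stats.norm.sf(abs(z))),
        note=note,
    )


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------

def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    second_order: bool = False,
) -> MREstimate:
    """Single-variant causal estimate beta_out / beta_exp.

    The first-order delta-method SE is se_out/|beta_exp|; the second-order
    variant adds the exposure-uncertainty term
    beta_out²·se_exp²/beta_exp⁴ under the square root.
    """
    if beta_exp == 0:
        raise DomainError("wald_ratio undefined for beta_exp = 0")
    est = beta_out / beta_exp
    if second_order:
        se = math.sqrt(se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4)
    else:
        se = se_out / abs(beta_exp)
    return _normal_estimate("wald_ratio", 1, est, se)


def wald_ratios(
    table: HarmonizedTable, second_order: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratios and their delta-method SEs as arrays."""
    bx, sx, by, sy = table.arrays()
    if np.any(bx == 0):
        raise DomainError("wald ratios undefined: some beta_exp are 0")
    r = by / bx
    if second_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / np.abs(bx)
    return r, se


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def ivw(table: HarmonizedTable, effects: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``effects`` is ``fixed``, ``random``, or ``auto`` (random when the
    Cochran Q p-value is below 0.05).  With a single instrument the Wald
    ratio is returned, labelled ``ivw_fixed``.
    """
    if effects not in ("fixed", "random", "auto"):
        raise DomainError(f"unknown effects {effects!r}")
    bx, sx, by, sy = table.arrays()
    k = len(bx)
    if k == 0:
        raise InsufficientInstrumentsError("ivw needs at least 1 instrument")
    if k == 1:
        est = wald_ratio(bx[0], sx[0], by[0], sy[0])
        est.method = "ivw_fixed"
        return est
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    if sxx == 0:
        raise DomainError("all exposure effects are zero; IVW design degenerate")
    b = float(np.sum(w * bx * by)) / sxx
    se_fixed = math.sqrt(1.0 / sxx)
    q = float(np.sum(w * (by - b * bx) ** 2))
    if effects == "auto":
        q_p = float(stats.chi2.sf(q, k - 1))
        effects = "random" if q_p < 0.05 else "fixed"
    if effects == "random":
        se = se_fixed * math.sqrt(max(1.0, q / (k - 1)))
    else:
        se = se_fixed
    return _normal_estimate(f"ivw_{effects}", k, b, se)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

@dataclass
class EggerFit:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float


def mr_egger(table: HarmonizedTable) -> EggerFit:
    """Egger regression: weighted fit of beta_out on beta_exp with intercept.

    Rows are first oriented so every exposure effect is non-negative (the
    intercept is only meaningful for a fixed exposure-effect sign).
    """
    bx, sx, by, sy = table.arrays()
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError(f"mr_egger needs >= 3 instruments, got {k}")
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2

    sw = w.sum()
    swx = float(np.sum(w * x))
    swxx = float(np.sum(w * x * x))
    swy = float(np.sum(w * y))
    swxy = float(np.sum(w * x * y))
    det = sw * swxx - swx**2
    if det <= 0:
        raise DomainError("degenerate Egger design (no exposure-effect spread)")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det

    resid = y - intercept - slope * x
    q = float(np.sum(w * resid**2))
    scale = max(1.0, q / (k - 2))
    var_slope = scale * sw / det
    var_intercept = scale * swxx / det
    se_slope = math.sqrt(var_slope)
    se_intercept = math.sqrt(var_intercept)

    tq = stats.t.ppf(0.975, k - 2)
    slope_p = float(2.0 * stats.t.sf(abs(slope / se_slope), k - 2))
    est = MREstimate(
        method="egger",
        n_snp=k,
        beta=float(slope),
        se=float(se_slope),
        ci_low=float(slope - tq * se_slope),
        ci_high=float(slope + tq * se_slope),
        pvalue=slope_p,
    )
    intercept_p = float(2.0 * stats.t.sf(abs(intercept / se_intercept), k - 2))
    return EggerFit(
        slope=est,
        intercept=float(intercept),
        intercept_se=float(se_intercept),
        intercept_p=intercept_p,
    )


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------

def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, r))


def _parametric_boot(table, point_fn, n_boot, seed):
    bx, sx, by, sy = table.arrays()
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for i in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        ests[i] = point_fn(by_b / bx_b, sy / np.abs(bx_b))
    return float(np.std(ests, ddof=1))


def weighted_median(
    table: HarmonizedTable, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator with a parametric-bootstrap SE.

    Ratio weights are the inverse delta-method variances; the estimate is
    the ratio at which the cumulative (midpoint-adjusted) weight crosses
    0.5, linearly interpolated.  ``n_boot = 0`` skips the bootstrap and
    reports NaN uncertainty (point estimate only).
    """
    if len(table) < 3:
        raise InsufficientInstrumentsError(
            f"weighted_median needs >= 3 instruments, got {len(table)}"
        )
    r, se_r = wald_ratios(table)
    point = _weighted_median_point(r, 1.0 / se_r**2)
    if n_boot <= 0:
        return MREstimate(
            "weighted_median", len(table), point,
            math.nan, math.nan, math.nan, math.nan, note="no bootstrap",
        )
    se = _parametric_boot(
        table,
        lambda ratios, ses: _weighted_median_point(ratios, 1.0 / ses**2),
        n_boot,
        seed,
    )
    return _normal_estimate("weighted_median", len(table), point, se)


# ---------------------------------------------------------------------------
# mode-based estimators
# ---------------------------------------------------------------------------

def _mode_point(
    ratios: np.ndarray,
    weights: np.ndarray,
    bandwidth_factor: float,
    grid_size: int = 512,
) -> float:
    if np.ptp(ratios) == 0.0:
        return float(ratios[0])
    sd = float(np.std(ratios, ddof=1))
    mad = float(np.median(np.abs(ratios - np.median(ratios)))) * 1.4826
    spread = min(sd, mad) if mad > 0 else sd
    h = bandwidth_factor * 0.9 * spread * len(ratios) ** (-1.0 / 5.0)
    if h <= 0:
        return float(np.median(ratios))
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_size)
    dens = (weights[:, None] * stats.norm.pdf((grid[None, :] - ratios[:, None]) / h)).sum(axis=0)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    table: HarmonizedTable,
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimate: argmax of a Gaussian-kernel density of ratios.

    The bandwidth is ``bandwidth_factor`` times a modified Silverman rule,
    0.9·min(SD, 1.4826·MAD)·k^(−1/5).  ``weighted=False`` gives the simple
    mode (unit weights); ``weighted=True`` weights each ratio by its inverse
    delta-method variance.  When every ratio is identical the common value
    is returned directly.
    """
    if len(table) < 3:
        raise InsufficientInstrumentsError(
            f"mode_estimate needs >= 3 instruments, got {len(table)}"
        )
    r, se_r = wald_ratios(table)
    method = "weighted_mode" if weighted else "simple_mode"

    def weights_of(ses):
        return 1.0 / ses**2 if weighted else np.ones_like(ses)

    point = _mode_point(r, weights_of(se_r), bandwidth_factor)
    if n_boot <= 0:
        return MREstimate(
            method, len(table), point,
            math.nan, math.nan, math.nan, math.nan, note="no bootstrap",
        )
    se = _parametric_boot(
        table,
        lambda ratios, ses: _mode_point(ratios, weights_of(ses), bandwidth_factor),
        n_boot,
        seed,
    )
    if se == 0.0:
        se = np.finfo(float).eps
    return _normal_estimate(method, len(table), point, se)


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------

@dataclass
class EstimateBatch:
    """All five estimates plus per-method direction agreement with IVW."""

    estimates: list[MREstimate]
    heterogeneity_p: float
    direction_agrees: dict[str, bool | None] = field(default_factory=dict)

    def by_method(self, prefix: str) -> MREstimate | None:
        for e in self.estimates:
            if e.method.startswith(prefix):
                return e
        return None

    @property
    def ivw(self) -> MREstimate:
        return self.by_method("ivw")


def run_all_methods(
    table: HarmonizedTable,
    n_boot: int = 1000,
    seed: int = 0,
    bandwidth_factor: float = 1.0,
    or_scale: bool = False,
) -> EstimateBatch:
    """Run IVW, Egger, weighted median, simple and weighted mode.

    The IVW uses random effects when Cochran's Q is significant at 0.05 and
    fixed effects otherwise.  Methods that need more instruments than are
    available are recorded as not estimable rather than failing the batch.
    Direction-agreement flags compare each method's sign with IVW's.
    """
    if len(table) == 0:
        raise InsufficientInstrumentsError("empty harmonized table")
    k = len(table)
    if k >= 2:
        bx, _, by, sy = table.arrays()
        w = 1.0 / sy**2
        b = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
        q = float(np.sum(w * (by - b * bx) ** 2))
        het_p = float(stats.chi2.sf(q, k - 1))
    else:
        het_p = math.nan
    estimates = [ivw(table, effects="auto" if k >= 2 else "fixed")]

    runners = [
        ("egger", lambda: mr_egger(table).slope),
        ("weighted_median", lambda: weighted_median(table, n_boot=n_boot, seed=seed)),
        (
            "simple_mode",
            lambda: mode_estimate(
                table, weighted=False, bandwidth_factor=bandwidth_factor,
                n_boot=n_boot, seed=seed + 1,
            ),
        ),
        (
            "weighted_mode",
            lambda: mode_estimate(
                table, weighted=True, bandwidth_factor=bandwidth_factor,
                n_boot=n_boot, seed=seed + 2,
            ),
        ),
    ]
    for name, fn in runners:
        try:
            estimates.append(fn())
        except InsufficientInstrumentsError as exc:
            estimates.append(MREstimate.not_estimable(name, k, str(exc)))

    ivw_beta = estimates[0].beta
    agrees: dict[str, bool | None] = {}
    for e in estimates[1:]:
        agrees[e.method] = (
            bool(np.sign(e.beta) == np.sign(ivw_beta)) if e.estimable else None
        )
    if or_scale:
        for e in estimates:
            e.with_or_scale()
    return EstimateBatch(estimates=estimates, heterogeneity_p=het_p, direction_agrees=agrees)
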