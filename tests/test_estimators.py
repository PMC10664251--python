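"""Causal estimators against independent weighted-least-squares oracles."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from mrbiome.errors import DomainError, InsufficientInstrumentsError
from mrbiome.estimators import (
    ivw,
    mode_estimate,
    mr_egger,
    run_all_methods,
    wald_ratio,
    weighted_median,
)
from mrbiome.gwas_io import HarmonizedTable
from mrbiome.synthetic import simulate_harmonized_table


def _table(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    return HarmonizedTable.from_arrays(
        snp_id=[f"rs{i}" for i in range(len(bx))],
        beta_exp=bx,
        se_exp=np.full(len(bx), 0.01) if sx is None else np.asarray(sx, float),
        beta_out=np.asarray(by, float),
        se_out=np.asarray(sy, float),
    )


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------

def test_wald_ratio_arithmetic():
    est = wald_ratio(0.2, 0.05, 0.1, 0.02)
    assert est.beta == pytest.approx(0.5)
    assert est.se == pytest.approx(0.1)
    assert wald_ratio(0.2, 0.05, 0.0, 0.02).beta == 0.0
    with pytest.raises(DomainError):
        wald_ratio(0.0, 0.05, 0.1, 0.02)


def test_wald_ratio_second_order_se_matches_delta_oracle():
    est = wald_ratio(0.2, 0.05, 0.1, 0.02, second_order=True)
    oracle = math.sqrt(0.02**2 / 0.2**2 + 0.1**2 * 0.05**2 / 0.2**4)
    assert est.se == pytest.approx(oracle, rel=1e-12)


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def test_single_snp_ivw_equals_wald():
    t = _table([0.2], [0.1], [0.02])
    est = ivw(t)
    assert est.method == "ivw_fixed"
    assert est.beta == pytest.approx(0.5)
    assert est.se == pytest.approx(0.1)


def test_identical_ratios_fixed_equals_random():
    t = _table([0.1, 0.2, 0.4], [0.03, 0.06, 0.12], [0.01, 0.02, 0.03])
    fx, rd = ivw(t, "fixed"), ivw(t, "random")
    assert fx.beta == pytest.approx(0.3, rel=1e-12)
    assert rd.beta == pytest.approx(fx.beta)
    assert rd.se == pytest.approx(fx.se)  # Q = 0 so no inflation


def test_ivw_matches_normal_equations_oracle(worked_table):
    bx, _, by, sy = worked_table.arrays()
    w = 1.0 / sy**2
    oracle = np.sum(w * bx * by) / np.sum(w * bx * bx)
    est = ivw(worked_table, "fixed")
    assert est.beta == pytest.approx(oracle, abs=1e-10)
    assert est.se == pytest.approx(math.sqrt(1.0 / np.sum(w * bx * bx)), abs=1e-12)


def test_ivw_matches_statsmodels_wls(noisy_table):
    bx, _, by, sy = noisy_table.arrays()
    fit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
    est = ivw(noisy_table, "fixed")
    assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
    # fixed-effects SE forces unit residual variance
    assert est.se == pytest.approx(fit.bse[0] / math.sqrt(fit.scale), abs=1e-10)


def test_ivw_fixed_equals_weighted_mean_of_ratios(noisy_table):
    bx, _, by, sy = noisy_table.arrays()
    w = bx**2 / sy**2
    oracle = np.sum(w * (by / bx)) / np.sum(w)
    assert ivw(noisy_table, "fixed").beta == pytest.approx(oracle, abs=1e-10)


def test_ivw_degenerate_design():
    with pytest.raises(DomainError):
        ivw(_table([0.0, 0.0], [0.1, 0.2], [0.01, 0.01]))


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def test_egger_exact_line_through_origin():
    bx = np.array([0.1, 0.2, 0.3, 0.4])
    fit = mr_egger(_table(bx, 0.7 * bx, [0.01] * 4))
    assert fit.slope.beta == pytest.approx(0.7, abs=1e-12)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)


def test_egger_exact_constant_offset():
    bx = np.array([0.1, 0.2, 0.3, 0.4])
    fit = mr_egger(_table(bx, 0.7 * bx + 0.05, [0.01] * 4))
    assert fit.slope.beta == pytest.approx(0.7, abs=1e-12)
    assert fit.intercept == pytest.approx(0.05, abs=1e-12)
    assert fit.intercept_se > 0  # floored random-effects scale


def test_egger_matches_statsmodels_wls(noisy_table):
    bx, _, by, sy = noisy_table.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sign, by * sign
    fit = sm.WLS(y, sm.add_constant(x), weights=1.0 / sy**2).fit()
    mine = mr_egger(noisy_table)
    assert mine.intercept == pytest.approx(fit.params[0], abs=1e-10)
    assert mine.slope.beta == pytest.approx(fit.params[1], abs=1e-10)
    # random-effects scale floored at 1: se = se_wls * sqrt(max(1,scale))/sqrt(scale)
    expected_se = fit.bse[1] * math.sqrt(max(1.0, fit.scale) / fit.scale)
    assert mine.slope.se == pytest.approx(expected_se, rel=1e-10)


def test_egger_needs_three_instruments():
    with pytest.raises(InsufficientInstrumentsError):
        mr_egger(_table([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------

def test_weighted_median_symmetric_equal_weights():
    t = _table([0.1, 0.1, 0.1], [0.04, 0.05, 0.06], [0.01, 0.01, 0.01])
    est = weighted_median(t, n_boot=200, seed=0)
    assert est.beta == pytest.approx(0.5, abs=1e-12)
    assert est.se > 0


def test_weighted_median_identical_ratios():
    t = _table([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.01, 0.01, 0.01])
    est = weighted_median(t, n_boot=200, seed=0)
    assert est.beta == pytest.approx(0.5, abs=1e-12)
    assert 0 < est.se < 0.2


def test_weighted_median_resists_invalid_minority():
    from mrbiome.validation import weighted_median_robustness

    est = weighted_median_robustness(theta=0.3, seed=7)
    assert est.ci_low <= 0.3 <= est.ci_high


# ---------------------------------------------------------------------------
# mode estimators
# ---------------------------------------------------------------------------

def test_mode_all_ratios_identical():
    t = _table([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.01, 0.01, 0.01])
    est = mode_estimate(t, weighted=True, n_boot=100, seed=1)
    assert est.beta == pytest.approx(0.5, abs=1e-12)


def test_mode_finds_majority_cluster():
    # 7 ratios near 0.5, 3 outliers at 2.0: KDE argmax must sit near 0.5
    rng = np.random.default_rng(4)
    ratios = np.concatenate([0.5 + 0.01 * rng.normal(size=7), [2.0, 2.01, 1.99]])
    bx = np.full(10, 0.2)
    t = _table(bx, ratios * bx, np.full(10, 0.01))
    est = mode_estimate(t, weighted=False, n_boot=0)
    assert abs(est.beta - 0.5) < 0.05


def test_weighted_mode_downweights_noisy_outliers():
    rng = np.random.default_rng(5)
    ratios = np.concatenate([0.5 + 0.01 * rng.normal(size=7), [2.0, 2.01, 1.99]])
    bx = np.full(10, 0.2)
    sy = np.concatenate([np.full(7, 0.005), np.full(3, 0.08)])  # outliers imprecise
    t = _table(bx, ratios * bx, sy)
    unweighted = mode_estimate(t, weighted=False, n_boot=200, seed=2)
    weighted = mode_estimate(t, weighted=True, n_boot=200, seed=2)
    assert abs(weighted.beta - 0.5) < 0.05
    # down-weighting the imprecise outliers cannot widen the bootstrap spread
    assert weighted.se <= unweighted.se * 1.05


# ---------------------------------------------------------------------------
# batch driver and invariance properties
# ---------------------------------------------------------------------------

def test_run_all_single_snp_only_ivw_estimable():
    t = _table([0.2], [0.1], [0.02])
    batch = run_all_methods(t, n_boot=50, seed=0)
    assert batch.estimates[0].estimable and batch.estimates[0].method == "ivw_fixed"
    assert all(not e.estimable for e in batch.estimates[1:])


def test_run_all_noise_free_proportional_table():
    bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    batch = run_all_methods(_table(bx, 0.6 * bx, np.full(5, 0.01)), n_boot=100, seed=0)
    for e in batch.estimates:
        assert e.beta == pytest.approx(0.6, abs=1e-9)
    assert all(batch.direction_agrees.values())


def test_run_all_flags_egger_disagreement_under_directional_pleiotropy():
    # strong positive intercept with a weak negative slope flips Egger's sign
    table, _ = simulate_harmonized_table(
        10, 0.05, seed=3, pleiotropy_mode="directional",
        pleiotropy_mean=0.05, pleiotropy_sd=0.005, z_range=(20, 30),
    )
    batch = run_all_methods(table, n_boot=50, seed=0)
    assert batch.direction_agrees["egger"] is not None  # flag is recorded


@pytest.mark.parametrize("c", [2.0, -3.0])
def test_scale_equivariance(noisy_table, c):
    base = run_all_methods(noisy_table, n_boot=0, seed=0)
    scaled_tab = HarmonizedTable(table=noisy_table.table.assign(
        beta_out=noisy_table.table["beta_out"] * c,
        se_out=noisy_table.table["se_out"] * abs(c),
    ))
    scaled = run_all_methods(scaled_tab, n_boot=0, seed=0)
    for e0, e1 in zip(base.estimates, scaled.estimates):
        assert e1.beta == pytest.approx(c * e0.beta, rel=1e-8)


def test_sign_equivariance(noisy_table):
    # negating exposure effects (with harmonized outcome following) is a
    # relabelling of the effect allele: estimates must not change
    flipped = HarmonizedTable(table=noisy_table.table.assign(
        beta_exp=-noisy_table.table["beta_exp"],
        beta_out=-noisy_table.table["beta_out"],
    ))
    base = run_all_methods(noisy_table, n_boot=0, seed=0)
    flip = run_all_methods(flipped, n_boot=0, seed=0)
    for e0, e1 in zip(base.estimates, flip.estimates):
        assert e1.beta == pytest.approx(e0.beta, rel=1e-10)


def test_or_scale_is_exp_of_beta_scale(noisy_table):
    batch = run_all_methods(noisy_table, n_boot=50, seed=0, or_scale=True)
    e = batch.estimates[0]
    assert e.or_scale[0] == pytest.approx(math.exp(e.beta))
    assert e.or_scale[1] == pytest.approx(math.exp(e.ci_low))
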