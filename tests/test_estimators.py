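import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.base import clone

from mr2step.errors import InsufficientInstrumentsError
from mr2step.estimators import (EggerEstimator, IVWEstimator,
                                WeightedMedianEstimator, confint, egger, ivw,
                                wald_ratio, weighted_median)

from conftest import make_harmonized


# --- Wald ratio -------------------------------------------------------------

@pytest.mark.parametrize("gamma,se_g,Gamma,se_G,beta,se", [
    (0.1, 0.01, 0.025, 0.005, 0.25, 0.05),
    (-0.1, 0.01, 0.025, 0.005, -0.25, 0.05),   # sign flips with gamma
])
def test_wald_ratio(gamma, se_g, Gamma, se_G, beta, se):
    est = wald_ratio(gamma, se_g, Gamma, se_G)
    assert est.beta == pytest.approx(beta)
    assert est.se == pytest.approx(se)      # se invariant to sign of gamma


def test_wald_ratio_rejects_zero_gamma():
    with pytest.raises(ValueError):
        wald_ratio(0.0, 0.01, 0.02, 0.005)


# --- confidence intervals ---------------------------------------------------

@pytest.mark.parametrize("beta,se,lo,hi,ndigits", [
    (0.20, 0.010, 0.18, 0.22, 2),
    (0.25, 0.031, 0.19, 0.31, 2),
    (0.042, 0.015, 0.013, 0.071, 3),
])
def test_confint_reconstructs_reported_intervals(beta, se, lo, hi, ndigits):
    got_lo, got_hi = confint(beta, se)
    assert round(got_lo, ndigits) == lo
    assert round(got_hi, ndigits) == hi


def test_confint_collapses_as_level_shrinks():
    lo, hi = confint(0.3, 0.1, level=1e-12)
    assert lo == pytest.approx(0.3, abs=1e-9)
    assert hi == pytest.approx(0.3, abs=1e-9)
    with pytest.raises(ValueError):
        confint(0.3, 0.1, level=1.0)


# --- IVW --------------------------------------------------------------------

def test_ivw_degenerate_homogeneity():
    # all Wald ratios equal -> beta = c, Q = 0, identical fixed/random SEs
    gamma = np.array([0.1, 0.2, 0.4])
    h = make_harmonized(gamma, 0.3 * gamma, se_Gamma=np.array([0.01, 0.02, 0.03]))
    re = ivw(h, effects="random")
    fe = ivw(h, effects="fixed")
    assert re.beta == pytest.approx(0.3, abs=1e-14)
    assert re.q_scale == pytest.approx(1.0)
    assert re.se == pytest.approx(fe.se)


def test_ivw_matches_closed_form_sums():
    gamma = np.array([0.08, 0.15, -0.05])
    Gamma = np.array([0.02, 0.05, -0.021])
    se_G = np.array([0.004, 0.007, 0.003])
    h = make_harmonized(gamma, Gamma, se_Gamma=se_G)
    w = 1 / se_G**2
    beta_hand = np.sum(w * gamma * Gamma) / np.sum(w * gamma**2)
    se_fe_hand = np.sqrt(1 / np.sum(w * gamma**2))
    q_hand = np.sum(w * (Gamma - beta_hand * gamma) ** 2)
    scale = max(1.0, np.sqrt(q_hand / 2))
    est = ivw(h, effects="random")
    assert est.beta == pytest.approx(beta_hand, abs=1e-12)
    assert est.se == pytest.approx(se_fe_hand * scale, abs=1e-12)
    fe = ivw(h, effects="fixed")
    assert fe.se == pytest.approx(se_fe_hand, abs=1e-12)


def test_ivw_requires_two_instruments():
    with pytest.raises(InsufficientInstrumentsError, match="wald_ratio"):
        ivw(make_harmonized([0.1], [0.02]))


def test_ivw_duplication_invariance(rng):
    gamma = rng.normal(0, 0.1, 10)
    Gamma = 0.2 * gamma + rng.normal(0, 0.01, 10)
    h1 = make_harmonized(gamma, Gamma)
    h2 = make_harmonized(np.tile(gamma, 2), np.tile(Gamma, 2))
    e1, e2 = ivw(h1, effects="fixed"), ivw(h2, effects="fixed")
    assert e2.beta == pytest.approx(e1.beta, abs=1e-12)
    assert e2.se == pytest.approx(e1.se / np.sqrt(2), abs=1e-12)


# --- Egger ------------------------------------------------------------------

def test_egger_exact_line():
    gamma = np.array([0.05, 0.1, 0.15, 0.2])
    h = make_harmonized(gamma, 0.02 + 0.5 * gamma)
    est = egger(h)
    assert est.intercept == pytest.approx(0.02, abs=1e-12)
    assert est.beta == pytest.approx(0.5, abs=1e-12)


def test_egger_matches_weighted_normal_equations():
    gamma = np.array([0.05, 0.12, 0.2, 0.33])
    Gamma = np.array([0.04, 0.05, 0.13, 0.16])
    se_G = np.array([0.01, 0.02, 0.015, 0.03])
    w = 1 / se_G**2
    X = np.column_stack([np.ones(4), gamma])
    XtWX = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(XtWX, X.T @ (w * Gamma))
    resid = Gamma - X @ coef
    sigma2 = np.sum(w * resid**2) / 2
    cov_unit = np.linalg.inv(XtWX)
    scale = max(1.0, np.sqrt(sigma2))
    est = egger(make_harmonized(gamma, Gamma, se_Gamma=se_G))
    assert est.intercept == pytest.approx(coef[0], abs=1e-12)
    assert est.beta == pytest.approx(coef[1], abs=1e-12)
    assert est.se == pytest.approx(np.sqrt(cov_unit[1, 1]) * scale, abs=1e-12)
    assert est.intercept_se == pytest.approx(np.sqrt(cov_unit[0, 0]) * scale,
                                             abs=1e-12)
    # t reference with J-2 df
    assert est.pval == pytest.approx(2 * stats.t.sf(abs(est.beta / est.se), 2))


def test_egger_cross_checked_against_statsmodels(rng):
    import statsmodels.api as sm
    gamma = np.abs(rng.normal(0.1, 0.05, 30))
    Gamma = 0.01 + 0.4 * gamma + rng.normal(0, 0.05, 30)
    se_G = np.full(30, 0.01)   # overdispersed: sigma > 1, floor inactive
    res = sm.WLS(Gamma, sm.add_constant(gamma), weights=1 / se_G**2).fit()
    est = egger(make_harmonized(gamma, Gamma, se_Gamma=se_G))
    assert est.beta == pytest.approx(res.params[1], abs=1e-10)
    assert est.intercept == pytest.approx(res.params[0], abs=1e-10)
    assert est.se == pytest.approx(res.bse[1], abs=1e-10)
    assert est.pval == pytest.approx(res.pvalues[1], abs=1e-10)


def test_egger_orientation_invariance(rng):
    # negating (gamma, Gamma) of any subset leaves the fit unchanged
    gamma = rng.normal(0, 0.1, 20)
    Gamma = 0.01 + 0.3 * gamma + rng.normal(0, 0.01, 20)
    h1 = make_harmonized(gamma, Gamma)
    flip = rng.random(20) < 0.5
    s = np.where(flip, -1.0, 1.0)
    h2 = make_harmonized(s * gamma, s * Gamma)
    e1, e2 = egger(h1), egger(h2)
    assert e1.beta == pytest.approx(e2.beta, abs=1e-12)
    assert e1.intercept == pytest.approx(e2.intercept, abs=1e-12)


def test_egger_requires_three_instruments():
    with pytest.raises(InsufficientInstrumentsError):
        egger(make_harmonized([0.1, 0.2], [0.02, 0.04]))


# --- weighted median --------------------------------------------------------

def test_weighted_median_equal_weights_interpolation():
    # ratios {1,2,3}, equal weights: p grid {1/6,1/2,5/6} hits 0.5 at ratio 2
    h = make_harmonized([1.0, 1.0, 1.0], [1.0, 2.0, 3.0],
                        se_Gamma=np.ones(3))
    est = weighted_median(h, n_boot=0)
    assert est.beta == pytest.approx(2.0)


def test_weighted_median_constant_ratios_small_bootstrap_se():
    gamma = np.array([0.1, 0.2, 0.3, 0.4])
    h = make_harmonized(gamma, 0.7 * gamma,
                        se_gamma=np.full(4, 1e-6), se_Gamma=np.full(4, 1e-6))
    est = weighted_median(h, n_boot=200, seed=1)
    assert est.beta == pytest.approx(0.7, abs=1e-6)
    assert est.se < 1e-4


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-10, 10), min_size=3, max_size=15).filter(
    lambda v: len(v) % 2 == 1))
def test_weighted_median_equals_plain_median_for_equal_weights_odd_j(ratios):
    h = make_harmonized(np.ones(len(ratios)), np.array(ratios),
                        se_Gamma=np.ones(len(ratios)))
    est = weighted_median(h, n_boot=0)
    assert est.beta == pytest.approx(np.median(ratios), abs=1e-12)


def test_weighted_median_seeded_reproducibility():
    rng = np.random.default_rng(5)
    gamma = np.abs(rng.normal(0.1, 0.03, 20))
    Gamma = 0.2 * gamma + rng.normal(0, 0.01, 20)
    h = make_harmonized(gamma, Gamma)
    e1 = weighted_median(h, n_boot=100, seed=42)
    e2 = weighted_median(h, n_boot=100, seed=42)
    assert e1.se == e2.se


# --- cross-estimator properties ---------------------------------------------

def _random_h(rng, J=25, beta=0.3):
    gamma = rng.normal(0, 0.1, J)
    se_G = rng.uniform(0.005, 0.02, J)
    Gamma = beta * gamma + rng.normal(0, se_G)
    return gamma, Gamma, se_G


def test_scale_equivariance(rng):
    # multiplying Gamma and se_Gamma by k multiplies every beta and se by k
    gamma, Gamma, se_G = _random_h(rng)
    k = 3.7
    h1 = make_harmonized(gamma, Gamma, se_Gamma=se_G)
    h2 = make_harmonized(gamma, k * Gamma, se_Gamma=k * se_G)
    for fn in (lambda h: ivw(h), lambda h: egger(h),
               lambda h: weighted_median(h, n_boot=50, seed=0)):
        e1, e2 = fn(h1), fn(h2)
        assert e2.beta == pytest.approx(k * e1.beta, rel=1e-9)
        assert e2.se == pytest.approx(k * e1.se, rel=0.3 if
                                      e1.method == "weighted-median" else 1e-9)


def test_estimators_agree_without_pleiotropy(rng):
    gamma = np.abs(rng.normal(0.1, 0.03, 200))
    se_G = np.full(200, 0.002)
    Gamma = 0.25 * gamma + rng.normal(0, se_G)
    h = make_harmonized(gamma, Gamma, se_Gamma=se_G)
    b_ivw = ivw(h).beta
    b_egger = egger(h).beta
    b_wm = weighted_median(h, n_boot=0).beta
    assert b_ivw == pytest.approx(0.25, abs=0.01)
    assert b_egger == pytest.approx(b_ivw, abs=0.02)
    assert b_wm == pytest.approx(b_ivw, abs=0.02)


def test_pval_consistent_with_z_score(rng):
    gamma, Gamma, se_G = _random_h(rng)
    h = make_harmonized(gamma, Gamma, se_Gamma=se_G)
    est = ivw(h)
    assert est.pval == pytest.approx(2 * stats.norm.sf(abs(est.beta / est.se)))
    wm = weighted_median(h, n_boot=100, seed=3)
    assert wm.pval == pytest.approx(2 * stats.norm.sf(abs(wm.beta / wm.se)))
    assert est.ci_low <= est.beta <= est.ci_high


# --- sklearn interface ------------------------------------------------------

def test_sklearn_estimator_interface(rng):
    gamma, Gamma, se_G = _random_h(rng)
    est = IVWEstimator(effects="fixed")
    assert est.get_params()["effects"] == "fixed"
    cloned = clone(est)
    cloned.fit(gamma, Gamma, se_outcome=se_G)
    np.testing.assert_allclose(cloned.predict([1.0]), [cloned.beta_])
    eg = EggerEstimator().fit(gamma, Gamma, se_outcome=se_G)
    assert eg.predict(np.zeros(2)) == pytest.approx([eg.intercept_] * 2)
    wm = WeightedMedianEstimator(n_boot=10, random_state=0)
    wm.set_params(n_boot=20)
    wm.fit(gamma, Gamma, se_outcome=se_G, se_exposure=np.full_like(se_G, 0.01))
    assert wm.boot_reps_ == 20
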