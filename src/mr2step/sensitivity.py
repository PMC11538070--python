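"""Heterogeneity, pleiotropy, influence, and outlier diagnostics.

Covers Cochran's Q, the MR-Egger intercept test, leave-one-out influence
analysis, and an MR-PRESSO-style simulation test (global heterogeneity,
per-SNP outlier detection with Bonferroni adjustment, and a distortion test
comparing the outlier-corrected estimate against random-subset removals).

All simulation p-values are computed as (1 + #{simulated >= observed}) /
(1 + n_sim), so they are strictly positive and exactly reproducible for a
given seed; the PRESSO computation sorts SNPs by identifier internally, so
the outlier set does not depend on row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import InsufficientInstrumentsError
from .estimators import MREstimate, egger, ivw, _norm_pval, confint
from .harmonize import HarmonizedSet, harmonized_from_frame

__all__ = [
    "cochran_q", "egger_intercept_test", "leave_one_out", "mr_presso",
    "MRPresso", "PressoResult", "SensitivityReport", "sensitivity_report",
]


def _arrays(h: HarmonizedSet, min_snps: int):
    r = h.retained
    if len(r) < min_snps:
        raise InsufficientInstrumentsError(
            f"needs >= {min_snps} instruments, got {len(r)}")
    return (r["snp_id"].to_numpy(), r["gamma"].to_numpy(dtype=float),
            r["Gamma"].to_numpy(dtype=float),
            r["se_gamma"].to_numpy(dtype=float),
            r["se_Gamma"].to_numpy(dtype=float))


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q over per-SNP Wald ratios against the fixed-effects IVW fit.

    Q = sum_j w_j (beta_j - beta_FE)^2 with w_j = gamma_j^2 / se_Gamma_j^2;
    equals the weighted residual sum of squares of the origin regression.
    Returns (Q, df = J-1, upper-tail chi-square p).
    """
    _, x, y, _, sy = _arrays(h, 2)
    w = 1.0 / sy**2
    beta_fe = float(np.sum(w * x * y) / np.sum(w * x * x))
    q = float(np.sum(w * (y - beta_fe * x) ** 2))
    df = len(x) - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """Directional-pleiotropy test: the MR-Egger intercept triple."""
    e = egger(h)
    return e.intercept, e.intercept_se, e.intercept_pval


def leave_one_out(h: HarmonizedSet, alpha: float = 0.05) -> pd.DataFrame:
    """Random-effects IVW refitted excluding each SNP in turn.

    The distortion flag marks exclusions that flip the sign of the full-set
    estimate or lose its nominal significance.
    """
    snp, x, y, _, sy = _arrays(h, 3)
    full = ivw(h, effects="random")
    rows = []
    for j in range(len(x)):
        keep = np.arange(len(x)) != j
        sub = harmonized_from_frame(pd.DataFrame({
            "snp_id": snp[keep], "gamma": x[keep], "se_gamma": 1.0,
            "Gamma": y[keep], "se_Gamma": sy[keep]}))
        est = ivw(sub, effects="random")
        distorted = (np.sign(est.beta) != np.sign(full.beta)
                     or (full.pval < alpha and est.pval >= alpha))
        rows.append({"excluded_snp": snp[j], "beta": est.beta, "se": est.se,
                     "pval": est.pval, "distortion_flag": bool(distorted)})
    return pd.DataFrame(rows)


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier, and distortion results."""

    global_rss_obs: float
    global_pval: float
    per_snp_outlier_pval: dict
    outliers: list
    corrected_estimate: MREstimate | None = None
    distortion_pval: float | None = None


def _loo_slopes(w, x, y):
    """Leave-one-out origin-regression slopes, vectorized over SNPs (axis -1)."""
    sxx = np.sum(w * x * x, axis=-1, keepdims=True)
    sxy = np.sum(w * x * y, axis=-1, keepdims=True)
    return (sxy - w * x * y) / (sxx - w * x * x)


class MRPresso(BaseEstimator):
    """MR-PRESSO outlier diagnostic as a fit-style detector.

    Parameters
    ----------
    n_sim : int
        Parametric simulations for the global/outlier null distributions.
    outlier_alpha : float
        Familywise level for the Bonferroni-adjusted per-SNP test.
    n_distortion : int
        Random-subset draws for the distortion test.
    random_state : int or None
        Seed for all simulation draws.

    Fitted attributes: ``global_rss_obs_``, ``global_pval_``,
    ``outlier_pvals_`` (Bonferroni-adjusted, by snp_id), ``outliers_``,
    ``corrected_estimate_``, ``distortion_pval_``, ``result_``.
    """

    def __init__(self, n_sim: int = 1000, outlier_alpha: float = 0.05,
                 n_distortion: int = 1000, random_state=None):
        self.n_sim = n_sim
        self.outlier_alpha = outlier_alpha
        self.n_distortion = n_distortion
        self.random_state = random_state

    def fit(self, X, y, *, se_outcome=None, se_exposure=None, snp_ids=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        sy = np.asarray(se_outcome, dtype=float).reshape(-1)
        sx = np.asarray(se_exposure, dtype=float).reshape(-1)
        J = len(x)
        if J < 4:
            raise InsufficientInstrumentsError(
                f"MR-PRESSO needs >= 4 instruments, got {J}")
        snp_ids = (np.array([f"snp{j}" for j in range(J)])
                   if snp_ids is None else np.asarray(snp_ids))
        # canonical order: outlier set must not depend on input row order
        order = np.argsort(snp_ids, kind="mergesort")
        snp_ids, x, y, sx, sy = (a[order] for a in (snp_ids, x, y, sx, sy))

        rng = np.random.default_rng(self.random_state)
        w = 1.0 / sy**2
        b_loo = _loo_slopes(w, x, y)
        res_obs = w * (y - b_loo * x) ** 2
        rss_obs = float(np.sum(res_obs))

        gx = rng.normal(x, sx, size=(self.n_sim, J))
        gy = rng.normal(b_loo * x, sy, size=(self.n_sim, J))
        b_sim = _loo_slopes(w, gx, gy)
        res_sim = w * (gy - b_sim * gx) ** 2
        rss_sim = res_sim.sum(axis=1)

        self.global_rss_obs_ = rss_obs
        self.global_pval_ = float(
            (1 + np.sum(rss_sim >= rss_obs)) / (1 + self.n_sim))
        p_raw = (1 + np.sum(res_sim >= res_obs, axis=0)) / (1 + self.n_sim)
        p_adj = np.minimum(1.0, p_raw * J)
        self.outlier_pvals_ = dict(zip(snp_ids.tolist(), p_adj.tolist()))
        out_mask = p_adj < self.outlier_alpha
        self.outliers_ = sorted(snp_ids[out_mask].tolist())

        self.corrected_estimate_ = None
        self.distortion_pval_ = None
        k = int(out_mask.sum())
        if k and J - k >= 2:
            keep = ~out_mask
            self.corrected_estimate_ = self._ivw_re(x[keep], y[keep], sy[keep])
            beta_full = self._ivw_re(x, y, sy).beta
            d_obs = self.corrected_estimate_.beta - beta_full
            d_rand = np.empty(self.n_distortion)
            for i in range(self.n_distortion):
                drop = rng.choice(J, size=k, replace=False)
                m = np.ones(J, dtype=bool)
                m[drop] = False
                d_rand[i] = self._ivw_re(x[m], y[m], sy[m]).beta - beta_full
            self.distortion_pval_ = float(
                (1 + np.sum(np.abs(d_rand) >= abs(d_obs)))
                / (1 + self.n_distortion))

        self.result_ = PressoResult(
            global_rss_obs=self.global_rss_obs_,
            global_pval=self.global_pval_,
            per_snp_outlier_pval=self.outlier_pvals_,
            outliers=self.outliers_,
            corrected_estimate=self.corrected_estimate_,
            distortion_pval=self.distortion_pval_)
        return self

    @staticmethod
    def _ivw_re(x, y, sy) -> MREstimate:
        w = 1.0 / sy**2
        beta = float(np.sum(w * x * y) / np.sum(w * x * x))
        q = float(np.sum(w * (y - beta * x) ** 2))
        scale = max(1.0, np.sqrt(q / (len(x) - 1))) if len(x) > 1 else 1.0
        se = float(np.sqrt(1.0 / np.sum(w * x * x)) * scale)
        lo, hi = confint(beta, se)
        return MREstimate(method="ivw-re", beta=beta, se=se, ci_low=lo,
                          ci_high=hi, pval=_norm_pval(beta, se),
                          n_snps=len(x), q_scale=scale)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, seed=None,
              outlier_alpha: float = 0.05,
              n_distortion: int = 1000) -> PressoResult:
    """MR-PRESSO global heterogeneity, outlier, and distortion tests."""
    snp, x, y, sx, sy = _arrays(h, 4)
    det = MRPresso(n_sim=n_sim, outlier_alpha=outlier_alpha,
                   n_distortion=n_distortion, random_state=seed)
    det.fit(x, y, se_outcome=sy, se_exposure=sx, snp_ids=snp)
    return det.result_


@dataclass
class SensitivityReport:
    """Bundle of all diagnostics for one exposure-outcome pair."""

    q: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    loo: pd.DataFrame
    presso: PressoResult | None = None
    extras: dict = field(default_factory=dict)


def sensitivity_report(h: HarmonizedSet, n_sim: int = 1000, seed=None,
                       run_presso: bool = True) -> SensitivityReport:
    """Run the full diagnostic suite on one harmonized pair."""
    q, df, q_p = cochran_q(h)
    ei, ei_se, ei_p = egger_intercept_test(h)
    loo = leave_one_out(h)
    presso = None
    if run_presso and len(h) >= 4:
        presso = mr_presso(h, n_sim=n_sim, seed=seed)
    return SensitivityReport(q=q, q_df=df, q_pval=q_p, egger_intercept=ei,
                             egger_intercept_se=ei_se, egger_intercept_pval=ei_p,
                             loo=loo, presso=presso)
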