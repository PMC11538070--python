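"""Causal-effect estimators for summary-data Mendelian randomization.

Each estimator is a scikit-learn-style regressor fitted on per-SNP effect
pairs: ``X`` holds the SNP-exposure effects gamma_j (shape ``(J,)`` or
``(J, 1)``), ``y`` the aligned SNP-outcome effects Gamma_j, with standard
errors passed as keyword arguments to :meth:`fit`.  Fitted attributes follow
the sklearn trailing-underscore convention (``beta_``, ``se_``, ``pval_``,
...), and ``predict(X)`` returns ``beta_ * gamma``, the outcome effect the
fitted causal slope implies for a given instrument strength.

The module-level functions (:func:`ivw`, :func:`egger`,
:func:`weighted_median`, :func:`wald_ratio`) are thin wrappers operating on a
:class:`~mr2step.harmonize.HarmonizedSet` and returning an
:class:`MREstimate` record.

Conventions
-----------
* IVW is weighted regression of Gamma on gamma through the origin with
  weights 1/se_Gamma^2; the random-effects variant applies multiplicative
  overdispersion, scaling the fixed-effects SE by max(1, sqrt(Q/(J-1))).
* MR-Egger is the same weighted regression with a free intercept after
  re-orienting every SNP so gamma >= 0; slope and intercept use a t
  reference with J-2 degrees of freedom and the same multiplicative SE
  floor.
* The weighted median interpolates the inverse-variance-weighted empirical
  quantile function of the per-SNP Wald ratios at probability 0.5; its SE
  comes from a seeded parametric bootstrap.
* IVW and weighted-median p-values use the normal reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InsufficientInstrumentsError
from .harmonize import HarmonizedSet

__all__ = [
    "MREstimate", "confint", "wald_ratio", "ivw", "egger", "weighted_median",
    "IVWEstimator", "EggerEstimator", "WeightedMedianEstimator",
]


@dataclass
class MREstimate:
    """One method's causal-effect estimate with its inference.

    ``beta`` is in outcome units per exposure unit.  Egger-only fields are
    ``None`` for other methods; ``q_scale`` is the multiplicative
    overdispersion factor applied by random-effects IVW.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    q_scale: float | None = None


def confint(beta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-theory confidence interval beta +/- z_{(1+level)/2} * se."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    return beta - z * se, beta + z * se


def _norm_pval(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else np.nextafter(0, 1)
    return max(float(2 * stats.norm.sf(abs(beta / se))), np.nextafter(0, 1))


def wald_ratio(gamma: float, se_gamma: float, Gamma: float,
               se_Gamma: float, ci_level: float = 0.95) -> MREstimate:
    """Single-SNP causal estimate Gamma/gamma with first-order SE se_Gamma/|gamma|."""
    if gamma == 0:
        raise ValueError("wald ratio undefined for gamma = 0")
    if se_Gamma <= 0 or se_gamma <= 0:
        raise ValueError("standard errors must be positive")
    beta = Gamma / gamma
    se = se_Gamma / abs(gamma)
    lo, hi = confint(beta, se, ci_level)
    return MREstimate(method="wald", beta=beta, se=se, ci_low=lo, ci_high=hi,
                      pval=_norm_pval(beta, se), n_snps=1)


def _check_xy(X, y, se_outcome, se_exposure, min_snps: int):
    x = np.asarray(X, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if se_outcome is None:
        raise ValueError("se_outcome is required")
    sy = np.asarray(se_outcome, dtype=float).reshape(-1)
    sx = (None if se_exposure is None
          else np.asarray(se_exposure, dtype=float).reshape(-1))
    if not (len(x) == len(y) == len(sy)) or (sx is not None and len(sx) != len(x)):
        raise ValueError("gamma, Gamma and standard errors must have equal length")
    if np.any(sy <= 0) or (sx is not None and np.any(sx <= 0)):
        raise ValueError("standard errors must be strictly positive")
    if len(x) < min_snps:
        raise InsufficientInstrumentsError(
            f"needs >= {min_snps} instruments, got {len(x)}"
            + ("; use wald_ratio for a single SNP" if min_snps == 2 else ""))
    return x, y, sy, sx


class _BaseMR(RegressorMixin, BaseEstimator):
    """Shared plumbing: validation, predict, MREstimate assembly."""

    _min_snps = 2
    _method = ""

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        pred = self.beta_ * x
        if getattr(self, "intercept_", None) is not None:
            pred = pred + self.intercept_
        return pred

    def _finalize(self):
        self.ci_low_, self.ci_high_ = confint(self.beta_, self.se_, self.ci_level)
        self.estimate_ = MREstimate(
            method=self._method, beta=self.beta_, se=self.se_,
            ci_low=self.ci_low_, ci_high=self.ci_high_, pval=self.pval_,
            n_snps=self.nsnps_,
            intercept=getattr(self, "intercept_", None),
            intercept_se=getattr(self, "intercept_se_", None),
            intercept_pval=getattr(self, "intercept_pval_", None),
            q_scale=getattr(self, "q_scale_", None))
        return self


class IVWEstimator(_BaseMR):
    """Inverse-variance-weighted estimator (regression through the origin).

    Parameters
    ----------
    effects : {"random", "fixed"}
        "random" applies the multiplicative overdispersion factor
        max(1, sqrt(Q/(J-1))) to the fixed-effects SE.
    ci_level : float
        Two-sided confidence level.
    """

    _method = "ivw-re"
    _min_snps = 2

    def __init__(self, effects: str = "random", ci_level: float = 0.95):
        self.effects = effects
        self.ci_level = ci_level

    def fit(self, X, y, *, se_outcome=None, se_exposure=None):
        if self.effects not in ("random", "fixed"):
            raise ValueError("effects must be 'random' or 'fixed'")
        x, y, sy, _ = _check_xy(X, y, se_outcome, se_exposure, self._min_snps)
        w = 1.0 / sy**2
        sxx = float(np.sum(w * x * x))
        self.beta_ = float(np.sum(w * x * y)) / sxx
        se_fe = np.sqrt(1.0 / sxx)
        self.q_ = float(np.sum(w * (y - self.beta_ * x) ** 2))
        self.q_scale_ = float(max(1.0, np.sqrt(self.q_ / (len(x) - 1))))
        self._method = "ivw-re" if self.effects == "random" else "ivw-fe"
        self.se_ = float(se_fe * (self.q_scale_ if self.effects == "random" else 1.0))
        if self.effects == "fixed":
            self.q_scale_ = None
        self.pval_ = _norm_pval(self.beta_, self.se_)
        self.nsnps_ = len(x)
        return self._finalize()


class EggerEstimator(_BaseMR):
    """MR-Egger: weighted regression with a free pleiotropy intercept.

    SNPs are re-oriented so gamma >= 0 before fitting (the intercept is
    orientation-dependent); inference uses a t reference with J-2 df and the
    multiplicative SE floor max(1, sigma_hat).
    """

    _method = "egger"
    _min_snps = 3

    def __init__(self, ci_level: float = 0.95):
        self.ci_level = ci_level

    def fit(self, X, y, *, se_outcome=None, se_exposure=None):
        x, y, sy, _ = _check_xy(X, y, se_outcome, se_exposure, self._min_snps)
        sign = np.where(x < 0, -1.0, 1.0)
        x, y = sign * x, sign * y
        w = 1.0 / sy**2
        J = len(x)
        # weighted normal equations for [intercept, slope]
        s0, s1, s2 = np.sum(w), np.sum(w * x), np.sum(w * x * x)
        t0, t1 = np.sum(w * y), np.sum(w * x * y)
        det = s0 * s2 - s1 * s1
        intercept = (s2 * t0 - s1 * t1) / det
        slope = (s0 * t1 - s1 * t0) / det
        resid = y - intercept - slope * x
        sigma2 = float(np.sum(w * resid**2) / (J - 2))
        scale = max(1.0, np.sqrt(sigma2))
        se_slope_unit = np.sqrt(s0 / det)
        se_int_unit = np.sqrt(s2 / det)

        self.beta_ = float(slope)
        self.se_ = float(se_slope_unit * scale)
        self.pval_ = max(float(2 * stats.t.sf(abs(self.beta_ / self.se_), J - 2)),
                         np.nextafter(0, 1))
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(se_int_unit * scale)
        self.intercept_pval_ = max(
            float(2 * stats.t.sf(abs(self.intercept_ / self.intercept_se_), J - 2)),
            np.nextafter(0, 1))
        self.sigma_ = float(np.sqrt(sigma2))
        self.nsnps_ = J
        return self._finalize()


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of `ratios` under `weights`."""
    order = np.argsort(ratios, kind="mergesort")
    b = ratios[order]
    w = weights[order] / np.sum(weights)
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, p, b))


class WeightedMedianEstimator(_BaseMR):
    """Weighted-median estimator with parametric-bootstrap SE.

    Consistent when instruments carrying at least half the weight are valid.
    Per-SNP ratios Gamma_j/gamma_j are weighted by gamma_j^2/se_Gamma_j^2
    (the inverse first-order ratio variance); the estimate interpolates the
    weighted quantile function at 0.5.  ``n_boot=0`` skips the bootstrap
    (point estimate only; se/pval are NaN).
    """

    _method = "weighted-median"
    _min_snps = 3

    def __init__(self, n_boot: int = 1000, random_state=None,
                 ci_level: float = 0.95):
        self.n_boot = n_boot
        self.random_state = random_state
        self.ci_level = ci_level

    def fit(self, X, y, *, se_outcome=None, se_exposure=None):
        x, y, sy, sx = _check_xy(X, y, se_outcome, se_exposure, self._min_snps)
        weights = x**2 / sy**2
        self.beta_ = _weighted_median_point(y / x, weights)
        if self.n_boot:
            if sx is None:
                raise ValueError("se_exposure is required for the bootstrap SE")
            rng = np.random.default_rng(self.random_state)
            gx = rng.normal(x, sx, size=(self.n_boot, len(x)))
            gy = rng.normal(y, sy, size=(self.n_boot, len(x)))
            reps = np.empty(self.n_boot)
            for i in range(self.n_boot):
                reps[i] = _weighted_median_point(gy[i] / gx[i], gx[i] ** 2 / sy**2)
            self.se_ = float(np.std(reps, ddof=1))
            self.pval_ = _norm_pval(self.beta_, self.se_)
        else:
            self.se_ = float("nan")
            self.pval_ = float("nan")
        self.boot_reps_ = self.n_boot
        self.nsnps_ = len(x)
        if np.isnan(self.se_):
            self.ci_low_ = self.ci_high_ = float("nan")
            self.estimate_ = MREstimate(
                method=self._method, beta=self.beta_, se=self.se_,
                ci_low=self.ci_low_, ci_high=self.ci_high_, pval=self.pval_,
                n_snps=self.nsnps_)
            return self
        return self._finalize()


def _hxy(h: HarmonizedSet):
    r = h.retained
    return (r["gamma"].to_numpy(dtype=float), r["Gamma"].to_numpy(dtype=float),
            r["se_gamma"].to_numpy(dtype=float), r["se_Gamma"].to_numpy(dtype=float))


def ivw(h: HarmonizedSet, effects: str = "random",
        ci_level: float = 0.95) -> MREstimate:
    """Inverse-variance-weighted estimate on a harmonized set."""
    x, y, _, sy = _hxy(h)
    est = IVWEstimator(effects=effects, ci_level=ci_level)
    return est.fit(x, y, se_outcome=sy).estimate_


def egger(h: HarmonizedSet, ci_level: float = 0.95) -> MREstimate:
    """MR-Egger estimate (slope + pleiotropy intercept) on a harmonized set."""
    x, y, _, sy = _hxy(h)
    return EggerEstimator(ci_level=ci_level).fit(x, y, se_outcome=sy).estimate_


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed=None,
                    ci_level: float = 0.95) -> MREstimate:
    """Weighted-median estimate with seeded parametric-bootstrap SE."""
    x, y, sx, sy = _hxy(h)
    est = WeightedMedianEstimator(n_boot=n_boot, random_state=seed,
                                  ci_level=ci_level)
    return est.fit(x, y, se_outcome=sy, se_exposure=sx).estimate_
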