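"""Two-step MR mediation: product-of-coefficients decomposition.

The total exposure->outcome effect is decomposed using the two intermediate
fits: mediated = a * b (exposure->mediator times mediator->outcome), direct
= total - mediated, proportion = mediated / total.  The paper-style workflow
only decomposes pairs whose mediator->outcome estimate passes a nominal
significance gate (with a Bonferroni flag at alpha / m_tests).

Delta-method uncertainties are an optional extension: the source analyses
report no SE or CI for the mediated effect or the proportion, so these are
first-order approximations treating the three inputs as independent (the
total and step-one fits share exposure instruments, so the independence is
approximate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedProportionError
from .estimators import MREstimate

__all__ = ["MediationResult", "two_step_mediation", "mediation_gate", "GateResult"]


@dataclass
class MediationResult:
    """Decomposition of a total effect through one mediator."""

    total: float
    a: float          # exposure -> mediator
    b: float          # mediator -> outcome
    mediated: float   # a * b
    direct: float     # total - mediated
    proportion: float  # mediated / total
    mediated_se: float | None = None
    proportion_ci_low: float | None = None
    proportion_ci_high: float | None = None

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion


def two_step_mediation(total: MREstimate, a: MREstimate,
                       b: MREstimate, ci_level: float = 0.95) -> MediationResult:
    """Decompose `total` through the mediator defined by fits `a` and `b`.

    mediated = a.beta * b.beta; direct = total.beta - mediated;
    proportion = mediated / total.beta.  Delta-method SE for the mediated
    effect is sqrt(a^2 se_b^2 + b^2 se_a^2); the proportion CI propagates
    that SE together with the total's (first-order, independence assumed).
    """
    if total.beta == 0:
        raise UndefinedProportionError("proportion undefined: total effect is zero")
    mediated = a.beta * b.beta
    direct = total.beta - mediated
    proportion = mediated / total.beta

    med_se = prop_lo = prop_hi = None
    if a.se == a.se and b.se == b.se:  # both SEs non-NaN
        med_se = float(np.sqrt(a.beta**2 * b.se**2 + b.beta**2 * a.se**2))
        var_prop = (med_se**2 / total.beta**2
                    + mediated**2 * total.se**2 / total.beta**4)
        from scipy.stats import norm
        z = norm.ppf(0.5 + ci_level / 2)
        prop_lo = float(proportion - z * np.sqrt(var_prop))
        prop_hi = float(proportion + z * np.sqrt(var_prop))

    return MediationResult(total=total.beta, a=a.beta, b=b.beta,
                           mediated=mediated, direct=direct,
                           proportion=proportion, mediated_se=med_se,
                           proportion_ci_low=prop_lo, proportion_ci_high=prop_hi)


@dataclass
class GateResult:
    """One mediator-outcome pair's eligibility for mediation."""

    label: object
    estimate: MREstimate
    bonferroni_significant: bool


def mediation_gate(step2_estimates, alpha: float = 0.05,
                   m_tests: int = 1, labels=None) -> list[GateResult]:
    """Select mediator-outcome pairs eligible for mediation.

    A pair is eligible when its p-value is below the nominal ``alpha``; the
    returned records also flag whether it clears the Bonferroni threshold
    ``alpha / m_tests``.
    """
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    if labels is None:
        labels = list(range(len(step2_estimates)))
    eligible = []
    for label, est in zip(labels, step2_estimates):
        if est.pval < alpha:
            eligible.append(GateResult(
                label=label, estimate=est,
                bonferroni_significant=bool(est.pval < alpha / m_tests)))
    return eligible
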