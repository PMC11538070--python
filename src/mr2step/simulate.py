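"""Synthetic GWAS summary statistics under the linear instrumental-variable model.

Emulates the statistical structure of large continuous-trait GWAS meta-analyses:
hundreds of independent genome-wide-significant instruments, per-SNP standard
errors se = 1/sqrt(2 maf (1-maf) n) for a standardized trait, outcome effects
generated as Gamma_j = beta * gamma_j + alpha_j with configurable horizontal
pleiotropy alpha_j, and observation noise at the stated GWAS sample sizes.
Instruments are generated mutually independent and spaced >= 2 Mb apart, the
post-clumping state the estimators assume.

Default sample sizes mirror the cohorts the package's analysis plan targets:
exposure n = 766,345 (an educational-attainment-scale meta-analysis), outcome
n = 450,243 (a UK-Biobank-scale body-composition GWAS), mediator n = 51,665
(a brain-imaging consortium GWAS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .io import SummaryStats
from scipy import stats

__all__ = ["PleiotropyConfig", "MediationConfig", "ScenarioConfig",
           "simulate_pair", "simulate_mediation_chain", "load_scenario"]

_NON_PALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                          ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class PleiotropyConfig:
    """Horizontal-pleiotropy regime for the generator.

    mode: "none", "balanced" (mean 0), "directional" (nonzero mean), or
    "correlated" (alpha = rho * gamma + noise, violating InSIDE).  For the
    balanced/directional modes the pleiotropic effect is aligned to the
    exposure-increasing allele (multiplied by sign(gamma)), so a directional
    mean is recoverable by the Egger intercept under its gamma >= 0
    orientation.
    """

    mode: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    rho: float = 0.0


@dataclass
class MediationConfig:
    """True effects for a mediation chain: total = direct + a * b."""

    a: float
    b: float
    direct: float
    n_mediator: int = 51_665


@dataclass
class ScenarioConfig:
    """Study conditions for one simulated exposure-outcome pair.

    gamma_sd is the spread of true per-allele SNP-exposure effects on the
    standardized-trait scale; draws are resampled until the expected
    single-SNP F exceeds ``f_min`` so instruments pass strength selection.
    """

    n_snps: int = 300
    beta_true: float = 0.25
    n_exposure: int = 766_345
    n_outcome: int = 450_243
    gamma_sd: float = 0.05
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    n_outliers: int = 0
    outlier_offset_sd_multiple: float = 10.0
    mediation: MediationConfig | None = None
    maf_range: tuple = (0.05, 0.5)
    palindromic_fraction: float = 0.0
    f_min: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be positive")
        if min(self.n_exposure, self.n_outcome) < 1:
            raise ConfigurationError("sample sizes must be positive")
        if self.gamma_sd <= 0:
            raise ConfigurationError("gamma_sd must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.pleiotropy.mode not in ("none", "balanced", "directional",
                                        "correlated"):
            raise ConfigurationError(
                f"unknown pleiotropy mode {self.pleiotropy.mode!r}")
        if not 0 <= self.n_outliers <= self.n_snps:
            raise ConfigurationError("n_outliers must be in [0, n_snps]")
        if not 0 <= self.palindromic_fraction <= 1:
            raise ConfigurationError("palindromic_fraction must be in [0, 1]")
        if self.outlier_offset_sd_multiple <= 0:
            raise ConfigurationError("outlier_offset_sd_multiple must be positive")


def _pvals(beta, se):
    p = 2 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-300, 1.0)


def _positions(n, start=0):
    """Chromosome/position grid: >= 2 Mb between same-chromosome SNPs."""
    idx = np.arange(start, start + n)
    chrom = (idx % 22 + 1).astype(str)
    pos = 1_000_000 + (idx // 22) * 2_000_000
    return chrom, pos


def _alleles(rng, n, palindromic_fraction):
    pal = rng.random(n) < palindromic_fraction
    ea = np.empty(n, dtype="<U1")
    oa = np.empty(n, dtype="<U1")
    ip = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
    inp = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=n)
    for j in range(n):
        ea[j], oa[j] = (_PALINDROMIC_PAIRS[ip[j]] if pal[j]
                        else _NON_PALINDROMIC_PAIRS[inp[j]])
    return ea, oa


def _draw_gamma(rng, n, gamma_sd, se, f_min):
    """True instrument effects, resampled until expected F > f_min."""
    gamma = rng.normal(0.0, gamma_sd, size=n)
    weak = (gamma / se) ** 2 <= f_min
    while weak.any():
        gamma[weak] = rng.normal(0.0, gamma_sd, size=int(weak.sum()))
        weak = (gamma / se) ** 2 <= f_min
    return gamma


def _table(snp_id, chrom, pos, ea, oa, eaf, beta, se, n, trait) -> SummaryStats:
    df = pd.DataFrame({
        "snp_id": snp_id, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pval": _pvals(beta, se), "n": n,
    })
    return SummaryStats.from_frame(df, trait=trait)


def simulate_pair(config: ScenarioConfig, rng=None,
                  ) -> tuple[SummaryStats, SummaryStats]:
    """Simulate one exposure GWAS and one outcome GWAS over shared SNPs.

    Per SNP j: maf ~ U(maf_range); se_gamma = 1/sqrt(2 maf (1-maf) n_exp);
    true gamma_j ~ N(0, gamma_sd^2) resampled until expected F > f_min;
    alpha_j per the pleiotropy mode; Gamma_j = beta_true * gamma_j + alpha_j
    (+ an offset of outlier_offset_sd_multiple * se_Gamma for n_outliers
    randomly chosen SNPs); observed effects add N(0, se^2) noise.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    J = config.n_snps
    maf = rng.uniform(*config.maf_range, size=J)
    se_g = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_exposure)
    se_G = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_outcome)
    gamma = _draw_gamma(rng, J, config.gamma_sd, se_g, config.f_min)

    pl = config.pleiotropy
    if pl.mode == "none":
        alpha = np.zeros(J)
    elif pl.mode in ("balanced", "directional"):
        alpha = np.sign(gamma) * rng.normal(pl.mean, pl.sd, size=J)
    else:  # correlated: InSIDE violated
        alpha = pl.rho * gamma + rng.normal(0.0, pl.sd, size=J)

    Gamma = config.beta_true * gamma + alpha
    if config.n_outliers:
        idx = rng.choice(J, size=config.n_outliers, replace=False)
        Gamma[idx] += config.outlier_offset_sd_multiple * se_G[idx]

    gamma_hat = rng.normal(gamma, se_g)
    Gamma_hat = rng.normal(Gamma, se_G)

    snp_id = np.array([f"rs{j + 1}" for j in range(J)])
    chrom, pos = _positions(J)
    ea, oa = _alleles(rng, J, config.palindromic_fraction)

    exposure = _table(snp_id, chrom, pos, ea, oa, maf, gamma_hat, se_g,
                      config.n_exposure, trait="exposure")
    outcome = _table(snp_id, chrom, pos, ea, oa, maf, Gamma_hat, se_G,
                     config.n_outcome, trait="outcome")
    return exposure, outcome


def simulate_mediation_chain(config: ScenarioConfig, rng=None):
    """Simulate exposure, mediator, and outcome GWAS for a mediation chain.

    Two independent instrument sets are generated: set 1 instruments the
    exposure (mediator effect a * gamma, outcome effect total * gamma with
    total = direct + a*b); set 2 instruments the mediator (outcome effect
    b * delta).  The mediator table concatenates set 1's mediator-side rows
    with set 2's instrument rows; the outcome table concatenates both sets'
    outcome-side rows.

    Returns (exposure, mediator, outcome, truth) where truth records the
    generating a, b, direct, total, and proportion = a*b/total.
    """
    config.validate()
    if config.mediation is None:
        raise ConfigurationError("config.mediation is required")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    med = config.mediation
    total = med.direct + med.a * med.b
    J = config.n_snps

    def _set(start, n_trait):
        maf = rng.uniform(*config.maf_range, size=J)
        se_inst = 1.0 / np.sqrt(2 * maf * (1 - maf) * n_trait)
        g = _draw_gamma(rng, J, config.gamma_sd, se_inst, config.f_min)
        snp_id = np.array([f"rs{start + j + 1}" for j in range(J)])
        chrom, pos = _positions(J, start=start)
        ea, oa = _alleles(rng, J, config.palindromic_fraction)
        return maf, se_inst, g, snp_id, chrom, pos, ea, oa

    # set 1: exposure instruments
    maf1, se_g1, g1, id1, ch1, pos1, ea1, oa1 = _set(0, config.n_exposure)
    se_m1 = 1.0 / np.sqrt(2 * maf1 * (1 - maf1) * med.n_mediator)
    se_o1 = 1.0 / np.sqrt(2 * maf1 * (1 - maf1) * config.n_outcome)
    # set 2: mediator instruments
    maf2, se_d2, d2, id2, ch2, pos2, ea2, oa2 = _set(J, med.n_mediator)
    se_o2 = 1.0 / np.sqrt(2 * maf2 * (1 - maf2) * config.n_outcome)

    exposure = _table(id1, ch1, pos1, ea1, oa1, maf1,
                      rng.normal(g1, se_g1), se_g1, config.n_exposure,
                      trait="exposure")
    mediator = _table(
        np.concatenate([id1, id2]), np.concatenate([ch1, ch2]),
        np.concatenate([pos1, pos2]), np.concatenate([ea1, ea2]),
        np.concatenate([oa1, oa2]), np.concatenate([maf1, maf2]),
        np.concatenate([rng.normal(med.a * g1, se_m1),
                        rng.normal(d2, se_d2)]),
        np.concatenate([se_m1, se_d2]), med.n_mediator, trait="mediator")
    outcome = _table(
        np.concatenate([id1, id2]), np.concatenate([ch1, ch2]),
        np.concatenate([pos1, pos2]), np.concatenate([ea1, ea2]),
        np.concatenate([oa1, oa2]), np.concatenate([maf1, maf2]),
        np.concatenate([rng.normal(total * g1, se_o1),
                        rng.normal(med.b * d2, se_o2)]),
        np.concatenate([se_o1, se_o2]), config.n_outcome, trait="outcome")

    truth = {"a": med.a, "b": med.b, "direct": med.direct, "total": total,
             "proportion": med.a * med.b / total if total != 0 else np.nan}
    return exposure, mediator, outcome, truth


def load_scenario(path) -> ScenarioConfig:
    """Load a ScenarioConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "pleiotropy" in raw:
        raw["pleiotropy"] = PleiotropyConfig(**raw["pleiotropy"])
    if raw.get("mediation") is not None:
        raw["mediation"] = MediationConfig(**raw["mediation"])
    if "maf_range" in raw:
        raw["maf_range"] = tuple(raw["maf_range"])
    try:
        config = ScenarioConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"invalid scenario file {path}: {exc}") from exc
    config.validate()
    return config
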