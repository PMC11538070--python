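"""Two-step MR pipeline: exposure -> outcomes, exposure -> mediators,
mediators -> outcomes, gated mediation, and a Table-style report.

Every pair goes through instrument selection, clumping, harmonization, the
requested estimators, and the sensitivity suite; mediation is run only on
mediator-outcome pairs passing the nominal gate.  Stage failures are
recorded per pair and the run continues; a PipelineError is raised only if
every pair fails.  All stochastic components draw deterministic sub-seeds
from the plan seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MRError, PipelineError
from .estimators import MREstimate, egger, ivw, weighted_median
from .harmonize import HarmonizedSet, harmonize
from .instruments import clump, select_instruments
from .io import SummaryStats, read_summary_stats, write_summary_stats
from .mediation import MediationResult, mediation_gate, two_step_mediation
from .sensitivity import SensitivityReport, sensitivity_report

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("ivw-re", "egger", "weighted-median")


@dataclass
class AnalysisPlan:
    """Inputs and settings for one two-step analysis.

    ``exposure``/``mediators``/``outcomes`` are SummaryStats objects or file
    paths.  ``step1_tests``/``step2_tests`` are the Bonferroni denominators;
    ``None`` computes them from the plan (step 1: number of outcomes; step 2:
    mediators + mediators x outcomes).  Set ``step2_tests`` explicitly to
    replicate a published denominator that differs from the pairwise count.
    """

    exposure: object
    mediators: list = field(default_factory=list)
    outcomes: list = field(default_factory=list)
    methods: tuple = DEFAULT_METHODS
    p_threshold: float = 5e-8
    f_threshold: float = 10.0
    window_bp: int = 1_000_000
    r2_threshold: float = 0.001
    ld: dict | None = None
    palindrome_eaf_window: float = 0.08
    alpha: float = 0.05
    step1_tests: int | None = None
    step2_tests: int | None = None
    n_boot: int = 1000
    presso_n_sim: int = 1000
    run_presso: bool = True
    seed: int = 0

    @property
    def step1_alpha(self) -> float:
        m = self.step1_tests if self.step1_tests else max(1, len(self.outcomes))
        return self.alpha / m

    @property
    def step2_alpha(self) -> float:
        return self.alpha / self._step2_m()

    def _step2_m(self) -> int:
        if self.step2_tests:
            return self.step2_tests
        return max(1, len(self.mediators) * (1 + len(self.outcomes)))


@dataclass
class PairResult:
    """Full analysis of one exposure-outcome pair."""

    exposure: str
    outcome: str
    step: int
    n_instruments: int = 0
    n_retained: int = 0
    estimates: dict = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    harmonized: HarmonizedSet | None = None
    error: str | None = None


@dataclass
class ReportBundle:
    """Outputs of a pipeline run."""

    pairs: list
    report: pd.DataFrame
    estimates_long: pd.DataFrame
    mediation: list
    plan: AnalysisPlan


def _load(ref, fallback_label: str) -> SummaryStats:
    if isinstance(ref, SummaryStats):
        if not ref.trait:
            ref.trait = fallback_label
        return ref
    table = read_summary_stats(ref, trait=fallback_label)
    table.trait = table.trait or Path(str(ref)).stem
    return table


def _sub_seed(base: int, index: int) -> int:
    ss = np.random.SeedSequence([int(base), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def analyze_pair(exposure: SummaryStats, outcome: SummaryStats,
                 plan: AnalysisPlan, step: int, seed: int,
                 outdir: Path | None = None) -> PairResult:
    """Select instruments, harmonize, estimate, and diagnose one pair."""
    res = PairResult(exposure=exposure.trait, outcome=outcome.trait, step=step)
    try:
        inst = select_instruments(exposure, plan.p_threshold, plan.f_threshold)
        inst = clump(inst, plan.window_bp, plan.r2_threshold, plan.ld)
        res.n_instruments = len(inst)
        h = harmonize(inst, outcome, plan.palindrome_eaf_window)
        res.harmonized = h
        res.n_retained = len(h)
        for method in plan.methods:
            if method in ("ivw-re", "ivw"):
                res.estimates[method] = ivw(h, effects="random")
            elif method == "ivw-fe":
                res.estimates[method] = ivw(h, effects="fixed")
            elif method == "egger":
                res.estimates[method] = egger(h)
            elif method == "weighted-median":
                res.estimates[method] = weighted_median(
                    h, n_boot=plan.n_boot, seed=seed)
            else:
                raise MRError(f"unknown method {method!r}")
        res.sensitivity = sensitivity_report(
            h, n_sim=plan.presso_n_sim, seed=seed + 1,
            run_presso=plan.run_presso)
        if outdir is not None:
            stem = f"{exposure.trait}__{outcome.trait}".replace(" ", "_")
            write_summary_stats(
                SummaryStats(inst.df.drop(columns=["f_stat"]), exposure.trait),
                outdir / f"{stem}.instruments.tsv")
            h.df.to_csv(outdir / f"{stem}.harmonized.tsv", sep="\t",
                        index=False, na_rep="NA")
    except MRError as exc:
        res.error = f"{type(exc).__name__}: {exc}"
        logger.warning("pair %s -> %s failed: %s",
                       exposure.trait, outcome.trait, res.error)
    return res


def _report_rows(pairs, plan: AnalysisPlan) -> pd.DataFrame:
    rows = []
    for p in pairs:
        alpha = plan.step1_alpha if p.step == 1 else plan.step2_alpha
        main = p.estimates.get("ivw-re") or p.estimates.get("ivw")
        sens = p.sensitivity
        rows.append({
            "exposure": p.exposure, "outcome": p.outcome, "step": p.step,
            "n_snps": p.n_retained,
            "ivw_pval": main.pval if main else np.nan,
            "beta": main.beta if main else np.nan,
            "ci_low": main.ci_low if main else np.nan,
            "ci_high": main.ci_high if main else np.nan,
            "q_pval": sens.q_pval if sens else np.nan,
            "egger_intercept_pval": sens.egger_intercept_pval if sens else np.nan,
            "bonferroni_alpha": alpha,
            "passes_bonferroni": bool(main and main.pval < alpha),
            "error": p.error or "",
        })
    return pd.DataFrame(rows)


def _estimates_long(pairs) -> pd.DataFrame:
    rows = []
    for p in pairs:
        for method, est in p.estimates.items():
            rows.append({
                "exposure": p.exposure, "outcome": p.outcome, "step": p.step,
                "method": method, "pval": est.pval, "beta": est.beta,
                "se": est.se, "ci_low": est.ci_low, "ci_high": est.ci_high,
                "n_snps": est.n_snps,
            })
    return pd.DataFrame(rows)


def run_two_step(plan: AnalysisPlan, outdir=None) -> ReportBundle:
    """Run the full two-step analysis described by `plan`.

    Step 1 analyzes exposure -> each outcome; step 2 analyzes exposure ->
    each mediator and each mediator -> each outcome.  Mediation is run for
    every mediator-outcome pair passing the nominal gate, combining the
    step-1 total with the exposure->mediator and mediator->outcome fits.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    exposure = _load(plan.exposure, "exposure")
    mediators = [_load(m, f"mediator{i + 1}")
                 for i, m in enumerate(plan.mediators)]
    outcomes = [_load(o, f"outcome{i + 1}") for i, o in enumerate(plan.outcomes)]

    if plan.step2_tests:
        computed = max(1, len(mediators) * (1 + len(outcomes)))
        if plan.step2_tests != computed:
            logger.info(
                "step-2 Bonferroni denominator set to %d (plan override); "
                "pairwise test count is %d", plan.step2_tests, computed)

    tasks = [(exposure, o, 1) for o in outcomes]
    tasks += [(exposure, m, 2) for m in mediators]
    tasks += [(m, o, 2) for m in mediators for o in outcomes]

    pairs = []
    for i, (exp, out, step) in enumerate(tasks):
        seed = _sub_seed(plan.seed, i)
        pairs.append(analyze_pair(exp, out, plan, step, seed, outdir))
    if pairs and all(p.error for p in pairs):
        raise PipelineError("every exposure-outcome pair failed")

    # mediation on gated mediator -> outcome pairs
    by_pair = {(p.exposure, p.outcome): p for p in pairs}
    med_results = []
    m2 = plan._step2_m()
    candidates, labels = [], []
    for m in mediators:
        for o in outcomes:
            p = by_pair.get((m.trait, o.trait))
            est = p.estimates.get("ivw-re") if p and not p.error else None
            if est is not None:
                candidates.append(est)
                labels.append((m.trait, o.trait))
    for gate in mediation_gate(candidates, alpha=plan.alpha, m_tests=m2,
                               labels=labels):
        m_trait, o_trait = gate.label
        p_total = by_pair.get((exposure.trait, o_trait))
        p_a = by_pair.get((exposure.trait, m_trait))
        if not p_total or p_total.error or not p_a or p_a.error:
            logger.warning("mediation for %s via %s skipped: missing fits",
                           o_trait, m_trait)
            continue
        try:
            res = two_step_mediation(p_total.estimates["ivw-re"],
                                     p_a.estimates["ivw-re"], gate.estimate)
        except MRError as exc:
            logger.warning("mediation for %s via %s failed: %s",
                           o_trait, m_trait, exc)
            continue
        med_results.append({"mediator": m_trait, "outcome": o_trait,
                            "bonferroni_significant": gate.bonferroni_significant,
                            "result": res})

    report = _report_rows(pairs, plan)
    est_long = _estimates_long(pairs)
    if outdir is not None:
        report.to_csv(outdir / "report.tsv", sep="\t", index=False, na_rep="NA")
        est_long.to_csv(outdir / "estimates.tsv", sep="\t", index=False,
                        na_rep="NA")
        if med_results:
            pd.DataFrame([{
                "mediator": r["mediator"], "outcome": r["outcome"],
                "bonferroni_significant": r["bonferroni_significant"],
                "total": r["result"].total, "a": r["result"].a,
                "b": r["result"].b, "mediated": r["result"].mediated,
                "direct": r["result"].direct,
                "proportion_pct": r["result"].proportion_pct,
            } for r in med_results]).to_csv(
                outdir / "mediation.tsv", sep="\t", index=False)
    return ReportBundle(pairs=pairs, report=report, estimates_long=est_long,
                        mediation=med_results, plan=plan)


def scatter_plot(pair: PairResult, path) -> None:
    """Simple instrument scatter (gamma vs Gamma) with the fitted IVW line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = pair.harmonized.retained
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(r["gamma"], r["Gamma"], xerr=r["se_gamma"], yerr=r["se_Gamma"],
                fmt="o", ms=3, lw=0.5, alpha=0.7)
    main = pair.estimates.get("ivw-re")
    if main:
        xs = np.linspace(0, r["gamma"].max() * 1.05, 10)
        ax.plot(xs, main.beta * xs, "r-", label=f"IVW slope {main.beta:.3g}")
        ax.legend()
    ax.set_xlabel(f"SNP effect on {pair.exposure}")
    ax.set_ylabel(f"SNP effect on {pair.outcome}")
    ax.axhline(0, color="grey", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
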