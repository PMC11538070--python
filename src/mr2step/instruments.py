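"""Instrument selection: significance and strength filters, LD clumping.

Instruments are selected with the conventional three criteria for
summary-data MR: genome-wide significance (p < 5e-8, strict), instrument
strength (single-SNP F > 10, strict), and approximate pairwise independence
(greedy clumping: r^2 < 0.001 within 1 Mb of each index variant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoInstrumentsError
from .io import SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure trait.

    ``df`` carries the canonical summary-stat columns plus ``f_stat``;
    ``selection_log`` counts rows removed at each criterion.
    """

    trait: str
    df: pd.DataFrame
    selection_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)


def f_statistic(beta, se):
    """Single-SNP approximation of the first-stage F statistic, (beta/se)^2.

    Accepts scalars or arrays; ``se`` must be strictly positive.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be strictly positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def select_instruments(table: SummaryStats, p_threshold: float = 5e-8,
                       f_threshold: float = 10.0) -> InstrumentSet:
    """Filter a summary-stats table to significant, strong instruments.

    Retains rows with ``pval < p_threshold`` and ``(beta/se)^2 > f_threshold``
    (both strict).  Clumping is applied separately by :func:`clump`.
    """
    df = table.df.copy()
    df["f_stat"] = f_statistic(df["beta"].to_numpy(), df["se"].to_numpy())
    pass_p = df["pval"] < p_threshold
    pass_f = df["f_stat"] > f_threshold
    log = {
        "input": len(df),
        "removed_pval": int((~pass_p).sum()),
        "removed_f_stat": int((pass_p & ~pass_f).sum()),
    }
    df = df.loc[pass_p & pass_f].reset_index(drop=True)
    log["retained"] = len(df)
    logger.info("instrument selection for %r: %s", table.trait, log)
    if df.empty:
        raise NoInstrumentsError(
            f"no instruments for {table.trait!r}: nothing passes "
            f"p<{p_threshold} and F>{f_threshold}")
    return InstrumentSet(trait=table.trait, df=df, selection_log=log)


def read_ld_table(path) -> dict:
    """Read a 3-column tab-delimited pairwise r^2 table (snp_a, snp_b, r2)."""
    raw = pd.read_csv(path, sep="\t", header=0)
    ld = {}
    for a, b, r2 in raw.itertuples(index=False):
        ld[frozenset((str(a), str(b)))] = float(r2)
    return ld


def clump(instruments: InstrumentSet, window_bp: int = 1_000_000,
          r2_threshold: float = 0.001, ld: dict | None = None) -> InstrumentSet:
    """Greedy p-value clumping.

    Repeatedly takes the lowest-p unassigned SNP as index and removes every
    other unassigned SNP on the same chromosome within ``window_bp`` whose
    r^2 with the index is >= ``r2_threshold``.  ``ld`` maps frozensets of two
    snp_ids to r^2; a pair absent from a supplied table is treated as
    independent (r^2 = 0).  With ``ld=None`` every same-chromosome SNP inside
    the window is removed (conservative distance-only pruning).  Ties on p
    are broken by (chrom, pos).
    """
    df = instruments.df
    if df.empty:
        return InstrumentSet(instruments.trait, df.copy(),
                             dict(instruments.selection_log))
    order = df.sort_values(
        ["pval", "chrom", "pos"], kind="mergesort").index.to_numpy()
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(dtype=float)
    snp = df["snp_id"].to_numpy()

    removed = np.zeros(len(df), dtype=bool)
    kept = np.zeros(len(df), dtype=bool)
    for i in order:
        if removed[i]:
            continue
        kept[i] = True
        near = (~removed & ~kept & (chrom == chrom[i])
                & (np.abs(pos - pos[i]) <= window_bp))
        for j in np.flatnonzero(near):
            if ld is None:
                r2 = 1.0
            else:
                r2 = ld.get(frozenset((snp[i], snp[j])), 0.0)
            if r2 >= r2_threshold:
                removed[j] = True

    log = dict(instruments.selection_log)
    log["removed_clumping"] = int(removed.sum())
    log["retained"] = int(kept.sum())
    logger.info("clumping for %r: removed %d, retained %d",
                instruments.trait, log["removed_clumping"], log["retained"])
    return InstrumentSet(trait=instruments.trait,
                         df=df.loc[kept].reset_index(drop=True),
                         selection_log=log)
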