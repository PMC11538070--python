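"""Allele harmonization of outcome effects onto exposure instruments.

For every instrument the outcome record is aligned so both effects refer to
the exposure's effect allele.  Orientation swaps negate the outcome beta,
strand flips are resolved by complementing the outcome alleles, and
palindromic SNPs (A/T, C/G) are oriented by allele frequency when both
frequencies are informative — otherwise dropped.  The exposure side is never
altered, so effect signs stay interpretable per exposure-increasing allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NoHarmonizableInstrumentsError
from .instruments import InstrumentSet
from .io import SummaryStats

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Possible per-SNP harmonization outcomes.
ACTIONS = ("kept", "flipped", "dropped-palindromic",
           "dropped-incompatible", "dropped-missing")

RETAINED_ACTIONS = ("kept", "flipped")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be told from alleles."""
    return COMPLEMENT[effect_allele] == other_allele


@dataclass
class HarmonizedSet:
    """Aligned exposure/outcome effect pairs for one trait pair.

    ``df`` has one row per instrument with columns ``snp_id, gamma, se_gamma,
    Gamma, se_Gamma, eaf_exposure, eaf_outcome, action``; gamma is the
    SNP-exposure effect, Gamma the aligned SNP-outcome effect.  Dropped
    instruments keep their row (with NaN outcome fields) so the action
    bookkeeping is complete.
    """

    exposure_label: str
    outcome_label: str
    df: pd.DataFrame

    @property
    def retained(self) -> pd.DataFrame:
        return self.df[self.df["action"].isin(RETAINED_ACTIONS)]

    def __len__(self) -> int:
        return len(self.retained)

    @property
    def action_counts(self) -> dict:
        counts = self.df["action"].value_counts().to_dict()
        return {a: int(counts.get(a, 0)) for a in ACTIONS}


def _ambiguous(eaf: float, window: float) -> bool:
    return np.isnan(eaf) or (0.5 - window) <= eaf <= (0.5 + window)


def harmonize(exposure: InstrumentSet, outcome: SummaryStats,
              palindrome_eaf_window: float = 0.08) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    Parameters
    ----------
    exposure : InstrumentSet
        Selected instruments; orientation is taken as the reference.
    outcome : SummaryStats
        Outcome GWAS, indexed by snp_id.
    palindrome_eaf_window : float
        Half-width of the ambiguity band around eaf 0.5 inside which a
        palindromic SNP cannot be frequency-oriented and is dropped.
    """
    out = outcome.df.set_index("snp_id")
    records = []
    for row in exposure.df.itertuples(index=False):
        rec = {
            "snp_id": row.snp_id,
            "gamma": row.beta, "se_gamma": row.se,
            "Gamma": np.nan, "se_Gamma": np.nan,
            "eaf_exposure": row.eaf, "eaf_outcome": np.nan,
            "action": None,
        }
        if row.snp_id not in out.index:
            rec["action"] = "dropped-missing"
            records.append(rec)
            continue
        o = out.loc[row.snp_id]
        ea_x, oa_x = row.effect_allele, row.other_allele
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        beta_o, se_o, eaf_o = float(o["beta"]), float(o["se"]), float(o["eaf"])
        eaf_x = float(row.eaf) if row.eaf == row.eaf else np.nan

        if is_palindromic(ea_x, oa_x):
            if {ea_o, oa_o} != {ea_x, oa_x}:
                rec["action"] = "dropped-incompatible"
            elif (_ambiguous(eaf_x, palindrome_eaf_window)
                  or _ambiguous(eaf_o, palindrome_eaf_window)):
                rec["action"] = "dropped-palindromic"
            elif (eaf_x < 0.5) == (eaf_o < 0.5):
                # same minor/major status: outcome effect allele is the
                # exposure effect allele regardless of reported strand
                rec.update(action="kept", Gamma=beta_o, se_Gamma=se_o,
                           eaf_outcome=eaf_o)
            else:
                rec.update(action="flipped", Gamma=-beta_o, se_Gamma=se_o,
                           eaf_outcome=1.0 - eaf_o if eaf_o == eaf_o else np.nan)
        else:
            pair_o = {ea_o, oa_o}
            if pair_o != {ea_x, oa_x}:
                ea_o, oa_o = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
                pair_o = {ea_o, oa_o}
            if pair_o != {ea_x, oa_x}:
                rec["action"] = "dropped-incompatible"
            elif ea_o == ea_x:
                rec.update(action="kept", Gamma=beta_o, se_Gamma=se_o,
                           eaf_outcome=eaf_o)
            else:
                rec.update(action="flipped", Gamma=-beta_o, se_Gamma=se_o,
                           eaf_outcome=1.0 - eaf_o if eaf_o == eaf_o else np.nan)
        records.append(rec)

    df = pd.DataFrame.from_records(records)
    h = HarmonizedSet(exposure_label=exposure.trait,
                      outcome_label=outcome.trait, df=df)
    logger.info("harmonized %r vs %r: %s", exposure.trait, outcome.trait,
                h.action_counts)
    if len(h) == 0:
        raise NoHarmonizableInstrumentsError(
            f"no harmonizable instruments for {exposure.trait!r} vs "
            f"{outcome.trait!r}: {h.action_counts}")
    return h


def harmonized_from_frame(df: pd.DataFrame, exposure_label: str = "",
                          outcome_label: str = "") -> HarmonizedSet:
    """Build a HarmonizedSet from a frame already carrying aligned effects.

    Convenience for reading back a written harmonized table or for tests
    constructing (gamma, Gamma) pairs directly; rows without an ``action``
    column are marked ``kept``.
    """
    df = df.copy()
    if "action" not in df.columns:
        df["action"] = "kept"
    for col in ("eaf_exposure", "eaf_outcome"):
        if col not in df.columns:
            df[col] = np.nan
    return HarmonizedSet(exposure_label=exposure_label,
                         outcome_label=outcome_label, df=df)
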