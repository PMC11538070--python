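"""Reading, validating, and writing GWAS summary statistics.

The canonical on-disk format is tab-delimited text with a header row and the
columns ``snp_id, chrom, pos, effect_allele, other_allele, eaf, beta, se,
pval, n``.  Missing values (``eaf`` and ``n`` are the only optional fields)
are encoded as ``NA``.  Positions are 1-based base pairs.  Alleles are
restricted to single bases A/C/G/T; rows that violate an invariant are
dropped with a logged count rather than aborting the read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: Columns a column map must cover at minimum.
MANDATORY_COLUMNS = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pval"]

VALID_ALLELES = frozenset("ACGT")


@dataclass
class SummaryStats:
    """Per-SNP association statistics for one trait.

    Attributes
    ----------
    df : pandas.DataFrame
        Canonical columns (see :data:`CANONICAL_COLUMNS`); one row per SNP,
        ``snp_id`` unique, ``se`` positive, ``effect_allele != other_allele``.
    trait : str
        Free-text trait label.
    n_dropped : int
        Rows removed during validation.
    """

    df: pd.DataFrame
    trait: str = ""
    n_dropped: int = 0
    drop_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, trait: str = "") -> "SummaryStats":
        """Coerce a raw frame to canonical form, dropping invalid rows."""
        df = df.copy()
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                if col in MANDATORY_COLUMNS:
                    raise ConfigurationError(f"missing mandatory column: {col!r}")
                df[col] = np.nan
        df = df[CANONICAL_COLUMNS]

        df["snp_id"] = df["snp_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str).replace({"nan": "", "<NA>": ""})
        df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
        df["other_allele"] = df["other_allele"].astype(str).str.upper()
        for col in ("eaf", "beta", "se", "pval"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
        df["n"] = pd.to_numeric(df["n"], errors="coerce").astype("Int64")

        drop_log: dict[str, int] = {}

        def _drop(mask: pd.Series, reason: str) -> None:
            nonlocal df
            k = int(mask.sum())
            if k:
                drop_log[reason] = drop_log.get(reason, 0) + k
                df = df.loc[~mask]

        _drop(~df["effect_allele"].isin(VALID_ALLELES)
              | ~df["other_allele"].isin(VALID_ALLELES), "non_acgt_allele")
        _drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
        _drop(df["se"].isna() | (df["se"] <= 0), "nonpositive_se")
        _drop(df["beta"].isna(), "missing_beta")
        _drop(df["pval"].isna() | (df["pval"] <= 0) | (df["pval"] > 1), "invalid_pval")
        _drop(df["pos"].notna() & (df["pos"] < 0), "negative_pos")
        _drop(df["snp_id"].duplicated(keep="first"), "duplicate_snp_id")

        # eaf is optional: out-of-range values become missing rather than fatal
        bad_eaf = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
        if bad_eaf.any():
            drop_log["eaf_set_missing"] = int(bad_eaf.sum())
            df.loc[bad_eaf, "eaf"] = np.nan

        n_dropped = sum(v for k, v in drop_log.items() if k != "eaf_set_missing")
        if n_dropped:
            logger.info("dropped %d invalid row(s) for trait %r: %s",
                        n_dropped, trait, drop_log)
        return cls(df=df.reset_index(drop=True), trait=trait,
                   n_dropped=n_dropped, drop_log=drop_log)


def read_summary_stats(path, column_map: dict | None = None, trait: str = "",
                       sep: str = "\t") -> SummaryStats:
    """Read a delimited summary-statistics file.

    Parameters
    ----------
    path : str or path-like
        Delimited text file with a header row.
    column_map : dict, optional
        Mapping from canonical field name to the column name in the file.
        Must cover at least :data:`MANDATORY_COLUMNS`.  ``None`` means the
        file already uses canonical names.
    trait : str
        Label attached to the returned table.
    sep : str
        Field delimiter (default tab).
    """
    try:
        raw = pd.read_csv(path, sep=sep, na_values=["NA"], dtype={"chrom": str},
                          float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty summary-statistics file: {path}") from exc
    if raw.empty:
        raise InputError(f"summary-statistics file has no data rows: {path}")

    if column_map is not None:
        for key in MANDATORY_COLUMNS:
            if key not in column_map:
                raise ConfigurationError(f"column_map does not cover mandatory field {key!r}")
        for key, col in column_map.items():
            if col not in raw.columns:
                raise ConfigurationError(
                    f"column {col!r} (mapped from {key!r}) not present in {path}")
        raw = raw.rename(columns={col: key for key, col in column_map.items()})
    else:
        for key in MANDATORY_COLUMNS:
            if key not in raw.columns:
                raise ConfigurationError(f"missing mandatory column: {key!r}")
    return SummaryStats.from_frame(raw, trait=trait)


def write_summary_stats(table: SummaryStats, path) -> None:
    """Write a table in the canonical tab-delimited format.

    Floats are written with 17 significant digits so a read-back reproduces
    them exactly; missing cells are encoded ``NA``.
    """
    table.df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")
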