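import numpy as np
import pandas as pd
import pytest

from mr2step.harmonize import harmonized_from_frame
from mr2step.io import SummaryStats


def make_stats(rows, trait="trait"):
    """Build a SummaryStats from a list of row dicts (canonical fields)."""
    return SummaryStats.from_frame(pd.DataFrame(rows), trait=trait)


def pair_to_harmonized(exposure, outcome):
    """Directly pair generator tables that share SNPs and orientation."""
    return harmonized_from_frame(pd.DataFrame({
        "snp_id": exposure.df["snp_id"].to_numpy(),
        "gamma": exposure.df["beta"].to_numpy(),
        "se_gamma": exposure.df["se"].to_numpy(),
        "Gamma": outcome.df["beta"].to_numpy(),
        "se_Gamma": outcome.df["se"].to_numpy(),
    }))


def make_harmonized(gamma, Gamma, se_gamma=None, se_Gamma=None):
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    if se_gamma is None:
        se_gamma = np.full_like(gamma, 0.01)
    if se_Gamma is None:
        se_Gamma = np.full_like(Gamma, 0.01)
    return harmonized_from_frame(pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(len(gamma))],
        "gamma": gamma, "se_gamma": np.broadcast_to(se_gamma, gamma.shape),
        "Gamma": Gamma, "se_Gamma": np.broadcast_to(se_Gamma, Gamma.shape),
    }))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
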