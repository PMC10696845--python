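import numpy as np
import pandas as pd
import pytest

from prsphewas.gwasio import SUMSTATS_COLUMNS, SummaryStats


def make_sumstats(rows, trait="trait", cohort="cohort") -> SummaryStats:
    """Build SummaryStats from (snp, chrom, pos, ea, oa, eaf, beta, se, p, n)."""
    table = pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)
    return SummaryStats(trait, cohort, table)


def mri_from_pair(exposure: SummaryStats, outcome: SummaryStats) -> pd.DataFrame:
    """MR input from a generator pair already on the same effect alleles."""
    e, o = exposure.table, outcome.table
    return pd.DataFrame({
        "snp_id": e["snp_id"], "eaf": e["eaf"],
        "beta_exposure": e["beta"], "se_exposure": e["se"],
        "p_exposure": e["p"], "n_exposure": e["n"],
        "beta_outcome": o["beta"], "se_outcome": o["se"],
        "p_outcome": o["p"], "n_outcome": o["n"],
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
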