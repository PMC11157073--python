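import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrkit.datatypes import (
    HARMONIZED_COLUMNS,
    SUMMARY_COLUMNS,
    HarmonizedInstrumentSet,
    SummaryStatsTable,
)

settings.register_profile(
    "mrkit",
    settings(derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]),
)
settings.load_profile("mrkit")


def make_table(rows, name="trait", trait_type="continuous") -> SummaryStatsTable:
    """Build a SummaryStatsTable from dicts, filling optional fields."""
    full = []
    for i, r in enumerate(rows):
        rec = {
            "variant_id": f"rs{i + 1}",
            "chrom": "1",
            "pos": 1000 + i * 1000,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": np.nan,
            "beta": 0.1,
            "se": 0.02,
            "pvalue": 1e-8,
            "n": np.nan,
        }
        rec.update(r)
        full.append(rec)
    return SummaryStatsTable(name, trait_type, pd.DataFrame(full)[SUMMARY_COLUMNS])


def make_hset(g, sx, G, sy, ids=None, exposure="exp", outcome="out") -> HarmonizedInstrumentSet:
    g = np.asarray(g, float)
    df = pd.DataFrame(
        {
            "variant_id": ids if ids is not None else [f"rs{i + 1}" for i in range(g.size)],
            "beta_exposure": g,
            "se_exposure": np.asarray(sx, float),
            "beta_outcome": np.asarray(G, float),
            "se_outcome": np.asarray(sy, float),
        }
    )
    df["f_stat"] = (df["beta_exposure"] / df["se_exposure"]) ** 2
    return HarmonizedInstrumentSet(exposure, outcome, df[HARMONIZED_COLUMNS])


def random_hset(rng, J=20, theta=0.3):
    """A generic noisy instrument set for oracle-equivalence checks."""
    g = rng.normal(0.1, 0.05, J)
    g[np.abs(g) < 0.01] = 0.05
    sx = rng.uniform(0.005, 0.02, J)
    sy = rng.uniform(0.005, 0.03, J)
    G = theta * g + rng.normal(0, 1, J) * sy
    return make_hset(g, sx, G, sy)


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture
def hset_factory():
    return make_hset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
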