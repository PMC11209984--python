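import numpy as np
import pandas as pd
import pytest

from sdscan.pipeline import default_demo_config
from sdscan.simdata import COUNT_COLUMNS, SimParams, simulate_pools


@pytest.fixture(scope="session")
def demo_layout():
    """3 x 2-Mb genome with a 100-kb SDR (chr2) and 53-kb Y insertion (chr3)."""
    return default_demo_config("unused", seed=1).layout


@pytest.fixture(scope="session")
def demo_sites(demo_layout):
    """One seeded pooled-count table for the demo scenario (~36k sites)."""
    return simulate_pools(demo_layout, SimParams(seed=1))


def make_sites(records):
    """Build a pooled-counts frame from (chrom, pos, m_counts6, f_counts6)."""
    rows = []
    for chrom, pos, m, f in records:
        rows.append([chrom, pos, "A", *m, *f])
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", *COUNT_COLUMNS])


@pytest.fixture
def rng():
    return np.random.default_rng(20240626)
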