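import numpy as np
import pandas as pd
import pytest

from lightmeth.methylation import MethylomeTrack
from lightmeth.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study small enough for per-test reuse."""
    return SimConfig(
        seed=5,
        genome_length=250_000,
        n_genes=60,
        n_tes=40,
        n_dmrs_planted=8,
        n_degs_planted=12,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


def make_track(rows, condition=None):
    """Track from (chrom, pos, strand, meth, unmeth, context) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "meth", "unmeth", "context"]
    )
    return MethylomeTrack(df, condition)


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)
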