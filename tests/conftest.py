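import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mchh_islands import Methylome, SimConfig, simulate_species

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_methylome(rows):
    """rows: (chrom, pos, strand, context, n_meth, n_total)."""
    return Methylome(
        pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
        )
    )


@pytest.fixture(scope="session")
def default_sim():
    """One simulated species at the default study-like conditions."""
    return simulate_species(SimConfig(seed=11))


@pytest.fixture(scope="session")
def null_sim():
    """A species with no planted islands, exact-binomial counts."""
    cfg = SimConfig(
        seed=5, island_fraction=0.0, gbm_fraction=0.0, te_fraction=0.0,
        binomial_counts=True,
    )
    return simulate_species(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
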