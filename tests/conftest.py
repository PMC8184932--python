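import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hicnb import simulate
from hicnb.genome import make_bins

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world():
    """500-bin, 1 Mb-range contact table simulated from the null model."""
    table, truth = simulate.simulate_contacts(seed=101, n_bins=500, d_max=1_000_000)
    return table, truth


@pytest.fixture(scope="session")
def small_world_fit(small_world):
    from hicnb.background import two_step_fit

    table, truth = small_world
    fit = two_step_fit(table, truth.features, seed=101, min_subsample=20_000)
    return table, truth, fit


@pytest.fixture()
def tiny_bins():
    return make_bins({"chr1": 50_000, "chr2": 30_000}, binsize=10_000)


@pytest.fixture(scope="session")
def replicate_sets():
    """3 vs 3 replicate tables on a 400-bin world, no planted differences."""
    tables, cond_of, truth, _ = simulate.simulate_replicates(
        seed=77, n_replicates=3, n_bins=400, d_max=400_000)
    return tables, cond_of, truth
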