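import numpy as np
import pandas as pd
import pytest

from indets import CommunityTable, PlotGeo, SyntheticConfig, simulate_dataset


def make_table(abund, statuses=None, genera=None, plot_ids=None, species_ids=None):
    """Build a CommunityTable from a plain nested list of counts."""
    ab = np.asarray(abund, dtype=np.int64)
    n_plots, n_species = ab.shape
    plot_ids = plot_ids or [f"p{i}" for i in range(n_plots)]
    species_ids = species_ids or [f"s{j}" for j in range(n_species)]
    statuses = statuses or ["identified"] * n_species
    genera = genera or [f"g{j}" for j in range(n_species)]
    meta = pd.DataFrame(
        {"status": statuses, "genus": genera},
        index=pd.Index(species_ids, name="species_id"),
    )
    return CommunityTable(tuple(plot_ids), tuple(species_ids), ab, meta)


@pytest.fixture(scope="session")
def small_dataset():
    """Small spatial metacommunity with rarity-biased identification loss."""
    cfg = SyntheticConfig(
        n_plots=15, stems_per_plot=150, pool_stems=20_000, seed=11
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def small_geo(small_dataset):
    return small_dataset[1]


def random_table(rng, n_plots=6, n_species=12, max_count=9):
    """Random dense-ish community table with no all-zero rows/columns."""
    while True:
        ab = rng.integers(0, max_count + 1, size=(n_plots, n_species))
        ab[rng.random(ab.shape) < 0.4] = 0
        if (ab.sum(axis=0) > 0).all() and (ab.sum(axis=1) > 0).all():
            return make_table(ab)
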