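import pandas as pd
import pytest
from hypothesis import settings

from invacf.synthetic_world import WorldConfig, generate_world, world_to_csv, read_world_csv

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_world():
    """An 8-country world reused across tests (trade, records, threats)."""
    return generate_world(WorldConfig(seed=2, n_countries=8, n_species=800))


@pytest.fixture(scope="session")
def small_world_dir(small_world, tmp_path_factory):
    directory = tmp_path_factory.mktemp("world")
    world_to_csv(small_world, directory)
    return directory


@pytest.fixture(scope="session")
def small_world_data(small_world_dir):
    return read_world_csv(small_world_dir)


@pytest.fixture(scope="session")
def norandom_world():
    """A world with random effects and price noise switched off."""
    return generate_world(
        WorldConfig(
            seed=5,
            n_countries=6,
            n_species=600,
            re_sd={"importer_period": 0.0, "exporter_period": 0.0},
            price_noise_sd=0.0,
            confounder_scale=0.0,
        )
    )


@pytest.fixture(scope="session")
def small_fit(small_world):
    """Mixed-model fit on the small world's latent panel."""
    from invacf import nbglmm

    return nbglmm.fit(small_world.latent_panel)


def toy_panel():
    """A tiny deterministic panel for unit tests (2 countries x 15 decades)."""
    rows = []
    decades = range(1879, 2020, 10)
    for k, d in enumerate(decades):
        rows.append(("A", "B", d, 1000.0 * (k + 1), 500.0, 40, 30, k % 3))
        rows.append(("B", "A", d, 2000.0 * (k + 1), 500.0, 35, 40, (k + 1) % 2))
    return pd.DataFrame(
        rows, columns=["e", "i", "decade_end", "TR", "D", "S_e", "S_i", "AS"]
    )
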