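import pytest

import regmap as rm
from regmap.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down dataset for unit tests (fast, same structure)."""
    return SimulationConfig(
        seed=11,
        n_genes=60,
        n_planted_elements=40,
        n_fragments=5000,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    ds = small_dataset
    fragment_sets = {
        lib: rm.fragments_from_sam_text(text, lib)
        for lib, text in ds.sam_texts.items()
    }
    return rm.run_pipeline(fragment_sets, ds.genes, ds.genome, track=ds.track)


@pytest.fixture(scope="session")
def default_dataset():
    """The generator at its default study conditions, fixed seed."""
    return simulate(SimulationConfig(seed=17))


@pytest.fixture(scope="session")
def default_pipeline(default_dataset):
    ds = default_dataset
    fragment_sets = {
        lib: rm.fragments_from_sam_text(text, lib)
        for lib, text in ds.sam_texts.items()
    }
    return rm.run_pipeline(
        fragment_sets, ds.genes, ds.genome, track=ds.track
    )
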