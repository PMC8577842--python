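import numpy as np
import pandas as pd
import pytest

from starrcall.catalog import AmpliconCatalog
from starrcall.simulate import SimulationConfig, simulate_counts, simulate_truth


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-amplicon spiked simulation shared across tests."""
    config = SimulationConfig(n_amplicons=300, seed=11)
    catalog, truth = simulate_truth(config)
    counts, samples = simulate_counts(catalog, truth, config)
    return config, catalog, truth, counts, samples


@pytest.fixture()
def tiny_catalog():
    """Four hand-built amplicons on two chromosomes."""
    table = pd.DataFrame(
        {
            "amplicon_id": ["a1", "a2", "a3", "a4"],
            "chrom": ["chr1", "chr1", "chr2", "chr2"],
            "start": [100, 1000, 100, 1000],
            "end": [400, 1300, 400, 1300],
            "group": ["GWAS", "LD", "FBDHS", "PutEnh"],
            "gc": [0.4, 0.5, 0.6, 0.55],
            "ascertained_enhancer": [False, False, True, True],
        }
    )
    return AmpliconCatalog(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
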