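import numpy as np
import pandas as pd
import pytest

from meristemdiff import SimulationConfig, simulate_dataset
from meristemdiff.counts import CountMatrix


def make_count_matrix(arr, sample_names=None, species="x", tissue="root") -> CountMatrix:
    """Wrap a plain array as a CountMatrix with minimal metadata."""
    arr = np.asarray(arr)
    cols = sample_names or [f"s{i + 1}" for i in range(arr.shape[1])]
    counts = pd.DataFrame(arr, index=[f"g{i + 1}" for i in range(arr.shape[0])], columns=cols)
    meta = pd.DataFrame(
        {"species": species, "tissue": tissue, "replicate": range(1, len(cols) + 1)},
        index=pd.Index(cols, name="sample_id"),
    )
    return CountMatrix(counts=counts, sample_meta=meta)


#: compact configuration for fast functional tests (not the study conditions)
SMALL_CONFIG = SimulationConfig(
    seed=7,
    n_genes_per_species=3000,
    n_go_terms=100,
    go_size_range=(2, 200),
    n_ortholog_pairs=200,
    n_de_go_terms=4,
    de_go_min_genes=15,
    library_size=1_000_000,
    n_divergent_orthologs=20,
)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions (12k genes/species, NB dispersion 0.05)."""
    return simulate_dataset(SimulationConfig(seed=11))
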