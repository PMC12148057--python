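import numpy as np
import pandas as pd
import pytest

from scadvisor.backends import make_replay_backend
from scadvisor.dataio import CellDataset, GeneSetCollection
from scadvisor.synth import SynthConfig, build_fixture_store, generate_counts


@pytest.fixture
def tiny_ds() -> CellDataset:
    """3 cells x 4 genes, hand-enumerable."""
    counts = np.array(
        [
            [5, 0, 2, 1],
            [0, 0, 0, 0],
            [3, 1, 0, 4],
        ]
    )
    return CellDataset.from_counts(counts, ["GA", "GB", "GC", "GD"])


@pytest.fixture(scope="session")
def synth_ds() -> CellDataset:
    return generate_counts(SynthConfig(n_cells=150, n_genes=300, seed=7))


@pytest.fixture(scope="session")
def fixture_store() -> dict:
    return build_fixture_store()


@pytest.fixture(scope="session")
def replay_cfg(fixture_store):
    return make_replay_backend(fixture_store)


@pytest.fixture
def marker_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster": ["0", "0", "0", "1", "1"],
            "gene": ["A", "B", "C", "D", "E"],
            "avg_log2FC": [2.0, 1.0, 0.5, 3.0, 0.1],
            "p_val_adj": [1e-5, 1e-4, 0.2, 1e-6, 1e-3],
        }
    )


@pytest.fixture
def gene_sets() -> GeneSetCollection:
    return GeneSetCollection(
        sets={
            "SET_A": {"A", "B", "C"},
            "SET_B": {"D", "E", "F", "G"},
        }
    )
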