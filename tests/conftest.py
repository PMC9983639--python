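import numpy as np
import pandas as pd
import pytest

from strictscreen import ExpressionStore, SimulationConfig, simulate


@pytest.fixture()
def tiny_store() -> ExpressionStore:
    """4 cells x 3 genes, two cell types, hand-checkable values."""
    values = np.array(
        [
            [2.0, 0.0, 1.0],
            [4.0, 0.0, 3.0],
            [1.0, 2.0, 0.0],
            [3.0, 6.0, 0.0],
        ]
    )
    return ExpressionStore.from_arrays(
        values,
        gene_ids=["Sod1", "Fus", "Tardbp"],
        cell_ids=["c1", "c2", "c3", "c4"],
        cell_types={"c1": "A", "c2": "A", "c3": "B", "c4": "B"},
    )


@pytest.fixture(scope="session")
def sim_default():
    """One draw from the generator at its default study conditions."""
    return simulate(SimulationConfig(seed=20240901))


@pytest.fixture(scope="session")
def sim_null():
    """Exchangeable null draw: no markers, one dispersion, no depth spread."""
    return simulate(SimulationConfig(seed=20240902).null())


def random_store(rng: np.random.Generator, n_cells: int, n_genes: int, n_types: int) -> ExpressionStore:
    """Small dense random store for brute-force oracle comparisons."""
    values = rng.gamma(2.0, 1.0, size=(n_cells, n_genes))
    genes = [f"g{i}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    labels = pd.Series([f"T{rng.integers(n_types)}" for _ in range(n_cells)], index=cells)
    return ExpressionStore.from_arrays(values, genes, cells, labels)
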