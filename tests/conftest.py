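import numpy as np
import pandas as pd
import pytest

from dehop import ExpressionMatrix, SimConfig, WellTable, simulate

# reduced study layout for fast unit tests: same structure as the
# default configuration, scaled down
SMALL_TYPES = (("MC", 40, 15), ("DC", 30, 15), ("HC", 20, 15), ("KC", 20, 15))


def small_config(**overrides) -> SimConfig:
    base = dict(
        n_genes=800,
        cell_types=SMALL_TYPES,
        n_i7=12,
        n_i5=16,
        n_empty=8,
        n_qc_fail=4,
        seed=123,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_truth():
    """Default (read-sampling, global-model) small library."""
    return simulate(small_config())


@pytest.fixture(scope="session")
def small_truth_exact():
    """Deterministic expected-value small library (no read sampling)."""
    return simulate(small_config(reads_per_cell=None))


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        genes=pd.Index(["g1", "g2", "g3"]),
        cells=pd.Index(["c1", "c2", "c3", "c4"]),
        values=np.array(
            [
                [10.0, 0.0, 20.0, 1.0],
                [0.0, 0.0, 0.0, 0.0],
                [4.0, 6.0, 2.0, 0.5],
            ]
        ),
    )


@pytest.fixture
def tiny_wells() -> WellTable:
    return WellTable(
        pd.DataFrame(
            {
                "cell_id": ["c1", "c2", "c3", "c4"],
                "pool_id": ["p1"] * 4,
                "i7_index": ["r1", "r1", "r2", "r2"],
                "i5_index": ["c1", "c2", "c1", "c2"],
                "status": ["cell", "cell", "cell", "empty"],
                "cell_type": ["MC", "MC", "DC", None],
            }
        )
    )


def random_matrix(rng, n_genes=30, n_cells=12) -> ExpressionMatrix:
    values = rng.gamma(0.6, 50.0, size=(n_genes, n_cells))
    values[rng.random(values.shape) < 0.3] = 0.0
    return ExpressionMatrix(
        genes=pd.Index([f"g{i}" for i in range(n_genes)]),
        cells=pd.Index([f"c{j}" for j in range(n_cells)]),
        values=values,
    )
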