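import numpy as np
import pytest

import ccitensor as ct


@pytest.fixture
def tiny_expr():
    """2 genes x 4 cells with easy hand-checkable values."""
    return ct.ExpressionMatrix(
        [[1.0, 3.0, 5.0, 2.0], [0.0, 2.0, 4.0, 6.0]],
        ["gL", "gR"],
        ["c1", "c2", "c3", "c4"],
    )


@pytest.fixture
def tiny_labels():
    return ct.CellTypeLabels({"c1": "A", "c2": "A", "c3": "B", "c4": "B"})


@pytest.fixture
def small_dataset():
    """Seeded simulated dataset at desk scale with one planted CCI type."""
    cfg = ct.SimulationConfig(
        n_celltypes=3,
        cci_style="many-to-many",
        n_cci_types=1,
        threshold_name="E10",
        n_genes=200,
        n_cells_per_type=15,
        n_lr_pairs=30,
        seed=42,
    )
    return ct.simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
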