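import numpy as np
import pandas as pd
import pytest

from arcquant.synthetic import arc_expression_model, generate_subtype_benchmark


@pytest.fixture(scope="session")
def clean_benchmark():
    """Planted-subtype probe simulation with no speckle: the quantification
    pipeline must reproduce its truth table exactly."""
    return generate_subtype_benchmark(
        n_cells=300, image_size=(256, 256), seed=7,
        model=arc_expression_model(speckle_rate=0.0))


@pytest.fixture(scope="session")
def noisy_benchmark():
    """Planted-subtype probe simulation at the stated noise level
    (background speckle on, small-object filter needed downstream)."""
    return generate_subtype_benchmark(n_cells=700, image_size=(384, 384), seed=11)


@pytest.fixture
def four_cell_fixture():
    """Two A-cells 1 px apart plus two isolated cells: the A-A interaction
    permutation null is exhaustively enumerable (6 label placements)."""
    cells = pd.DataFrame({
        "cell_id": [1, 2, 3, 4],
        "image_id": 0,
        "x": [0.0, 1.0, 20.0, 40.0],
        "y": [0.0, 0.0, 0.0, 0.0],
        "type": ["A", "A", "B", "B"],
    })
    labels = pd.Series(cells["type"].to_numpy(), index=cells["cell_id"].to_numpy())
    return cells, labels
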