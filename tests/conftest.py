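import numpy as np
import pytest

from spotmil import BagAssignment, CellTable, SpotCounts


@pytest.fixture
def toy_counts() -> SpotCounts:
    """4 spots x 3 genes on a small grid, radius 5."""
    counts = np.array(
        [
            [3, 0, 1],
            [0, 5, 2],
            [2, 2, 0],
            [1, 0, 4],
        ]
    )
    xy = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
    return SpotCounts(
        counts=counts,
        spot_ids=np.array([f"s{i}" for i in range(4)], dtype=object),
        gene_ids=np.array(["gA", "gB", "gC"], dtype=object),
        slide_id="toy",
        spot_xy=xy,
        spot_radius=5.0,
    )


@pytest.fixture
def toy_cells() -> CellTable:
    return CellTable(
        cell_ids=np.array([f"c{i}" for i in range(6)], dtype=object),
        slide_id="toy",
        cell_xy=np.array(
            [[1.0, 1.0], [9.0, 1.0], [0.0, 9.0], [11.0, 11.0], [5.0, 5.0], [30.0, 30.0]]
        ),
    )


@pytest.fixture
def toy_bags() -> BagAssignment:
    return BagAssignment({0: np.array([0]), 1: np.array([1]), 2: np.array([2]), 3: np.array([3, 4])})
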