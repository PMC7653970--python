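import numpy as np
import pytest

from discoverym import DiscoveryMatrix

# Worked 8-participant example: 10 problems discovered, 18 detections,
# two singleton problems (columns 7 and 9), all columns distinct.
WORKED_8x10 = np.array(
    [
        [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 1, 1, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 1, 1, 1, 1, 0, 0, 0],
        [1, 0, 0, 0, 0, 0, 0, 1, 0, 0],
        [0, 0, 0, 1, 0, 0, 0, 1, 1, 0],
        [0, 1, 0, 0, 0, 0, 0, 0, 0, 1],
        [0, 0, 0, 0, 1, 0, 0, 0, 0, 1],
        [0, 0, 1, 0, 0, 1, 0, 0, 0, 0],
    ],
    dtype=np.int8,
)


@pytest.fixture
def worked_matrix() -> DiscoveryMatrix:
    """The 8x10 worked example (n=8, j=10, 18 detections)."""
    return DiscoveryMatrix(WORKED_8x10)


@pytest.fixture
def two_by_two() -> DiscoveryMatrix:
    """The tiny 2x2 identity-pattern matrix used in the permutation-count
    worked example (truncation of [[0,0,1],[1,0,0]])."""
    return DiscoveryMatrix([[1, 0], [0, 1]])


@pytest.fixture
def worked_csv(tmp_path):
    path = tmp_path / "worked.csv"
    with open(path, "w") as fh:
        for row in WORKED_8x10:
            fh.write(",".join(str(int(v)) for v in row) + "\n")
    return path
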