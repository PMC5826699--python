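import sys
from pathlib import Path

import numpy as np
import pytest

from occuprior import DetectionHistory

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def toy3() -> DetectionHistory:
    """The 3-site toy dataset used across likelihood and MLE checks."""
    return DetectionHistory([0, 2, 5], [5, 5, 5])


@pytest.fixture
def toy10() -> DetectionHistory:
    """Fixed 10-site dataset with an interior MLE."""
    return DetectionHistory(
        [0, 1, 2, 0, 3, 1, 0, 2, 1, 4], np.full(10, 10)
    )


@pytest.fixture
def grid_fixtures() -> list[DetectionHistory]:
    """Small no-covariate datasets for grid-oracle MLE checks (<= 20 sites)."""
    return [
        DetectionHistory([0, 2, 5], [5, 5, 5]),
        DetectionHistory([0, 1, 2, 0, 3, 1, 0, 2, 1, 4], np.full(10, 10)),
        DetectionHistory(
            [1, 0, 0, 4, 2, 0, 1, 3, 0, 2, 1, 0, 2, 0, 1, 5, 0, 1, 2, 0],
            np.full(20, 8),
        ),
    ]
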