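import numpy as np
import pytest

from f1ci import ConfusionCounts, ProbabilityTable, normalize

#: 3x3 worked example, rows = predicted, columns = true, n = 100
TABLE1_COUNTS = np.array([[2, 2, 2], [5, 70, 2], [0, 2, 15]])


@pytest.fixture
def table1_counts() -> ConfusionCounts:
    return ConfusionCounts(TABLE1_COUNTS, ("class_1", "class_2", "class_3"))


@pytest.fixture
def table1_pt(table1_counts) -> ProbabilityTable:
    return normalize(table1_counts)


def random_table(rng: np.random.Generator, r: int, low: int = 5, high: int = 80):
    """A strictly positive r x r probability table from integer counts."""
    counts = rng.integers(low, high, size=(r, r))
    return ProbabilityTable(counts / counts.sum())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
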