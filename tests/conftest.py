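import numpy as np
import pytest

from microassembly.io_tables import CountTable, TaxonomyMap


@pytest.fixture
def tiny_table():
    """3 taxa x 2 samples toy table."""
    return CountTable([[3, 0], [1, 4], [2, 2]], ["t1", "t2", "t3"], ["A", "B"])


@pytest.fixture
def random_table():
    """Moderately sparse 40 taxa x 12 samples table, fixed seed."""
    rng = np.random.default_rng(42)
    counts = rng.negative_binomial(1, 0.05, size=(40, 12))
    counts[rng.random(counts.shape) < 0.3] = 0
    counts[0] += 1  # keep every sample non-empty
    return CountTable(counts, [f"t{i}" for i in range(40)], [f"s{j}" for j in range(12)])


@pytest.fixture
def taxonomy():
    return TaxonomyMap(
        {
            "t1": ("Archaea", "Crenarchaeota", None, None, None, None),
            "t2": ("Archaea", "Crenarchaeota", None, None, None, None),
            "t3": ("Archaea", "Euryarchaeota", None, None, None, None),
        }
    )
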