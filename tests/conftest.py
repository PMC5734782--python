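import numpy as np
import pytest

from betaci import CountTable, GroupMap


@pytest.fixture
def tiny_table() -> CountTable:
    """2 taxa × 2 samples with counts ((1, 2), (3, 4))."""
    return CountTable(("t1", "t2"), ("s1", "s2"), np.array([[1, 2], [3, 4]]))


@pytest.fixture
def random_table_factory():
    """Factory for small random count tables (no all-zero samples)."""

    def make(n_taxa=12, n_samples=8, seed=0, max_count=50) -> CountTable:
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, max_count, size=(n_taxa, n_samples))
        counts[rng.integers(0, n_taxa), :] += 1  # keep every sample non-empty
        return CountTable(
            tuple(f"t{i}" for i in range(n_taxa)),
            tuple(f"s{j}" for j in range(n_samples)),
            counts,
        )

    return make


@pytest.fixture
def two_group_map() -> GroupMap:
    return GroupMap({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})
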