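import numpy as np
import pytest
from hypothesis import settings

from ecoassembly.core import CommunityTable, read_newick_string

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture
def balanced_tree():
    """((A:1,B:1):1,(C:1,D:1):1); -- the 4-tip hand-worked fixture."""
    return read_newick_string("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def small_table():
    counts = np.array(
        [
            [10, 0, 3],
            [5, 8, 0],
            [0, 2, 7],
            [5, 10, 10],
        ]
    )
    return CommunityTable(
        otu_ids=["A", "B", "C", "D"],
        sample_ids=["s1", "s2", "s3"],
        counts=counts,
        sample_groups={"s1": "wet", "s2": "wet", "s3": "dry"},
    )


@pytest.fixture
def table_factory():
    """Random table builder: table_factory(n_otus, n_samples, seed)."""

    def make(n_otus=20, n_samples=6, seed=0, groups=("g1", "g2"), max_count=50):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, max_count, size=(n_otus, n_samples))
        # no empty samples or all-zero rows by construction
        counts[0, :] += 1
        sample_ids = [f"s{j}" for j in range(n_samples)]
        sample_groups = {s: groups[j % len(groups)] for j, s in enumerate(sample_ids)}
        return CommunityTable(
            otu_ids=[f"o{i}" for i in range(n_otus)],
            sample_ids=sample_ids,
            counts=counts,
            sample_groups=sample_groups,
        )

    return make
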