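import pandas as pd
import pytest

from ecoassembly import CommunityMatrix
from ecoassembly.data_io import read_newick
from ecoassembly.synthetic_data import preset_scenarios, simulate_chronosequence

TINY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def tiny_tree():
    return read_newick(TINY_NEWICK)


@pytest.fixture
def tiny_community():
    data = pd.DataFrame(
        [[5, 0, 1], [0, 2, 2]], index=["s1", "s2"], columns=["A", "B", "C"]
    )
    return CommunityMatrix(data, kind="counts")


@pytest.fixture
def taxonomy_community():
    data = pd.DataFrame(
        [[3, 4, 2, 1], [1, 1, 5, 2]], index=["s1", "s2"],
        columns=["o1", "o2", "o3", "o4"],
    )
    taxonomy = pd.Series(
        {
            "o1": "d__B;p__P1;c__C1;o__O1;f__F;g__G1",
            "o2": "d__B;p__P1;c__C1;o__O1;f__F;g__G2",
            "o3": "d__B;p__P1;c__C1;o__O2;f__H;g__G3",
            "o4": "d__B;p__P1;c__C1;o__O2;;g__G4",  # no family assignment
        }
    )
    return CommunityMatrix(data, kind="counts", taxonomy=taxonomy)


@pytest.fixture(scope="session")
def selection_dataset():
    """One strongly env-structured synthetic chronosequence, reused across
    tests that only need realistic community/tree/env structure."""
    return simulate_chronosequence(preset_scenarios(seed=2)["variable_selection"])


def random_community_and_tree(rng, n_samples=8, n_taxa=12):
    """Small random instance: counts matrix + random tree over its taxa."""
    from ecoassembly.synthetic_data import simulate_tree

    tree = simulate_tree(n_taxa, seed=int(rng.integers(2**31)))
    taxa = [t.name for t in tree.tips()]
    counts = rng.integers(0, 20, size=(n_samples, n_taxa))
    for i in range(n_samples):  # no empty samples
        if counts[i].sum() == 0:
            counts[i, rng.integers(n_taxa)] = 1
    m = CommunityMatrix(
        pd.DataFrame(counts, index=[f"s{i}" for i in range(n_samples)], columns=taxa),
        kind="counts",
    )
    return m, tree
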