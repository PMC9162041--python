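import numpy as np
import pandas as pd
import pytest

from miaf import parse_newick, simulate_tree, CommunityModel

FIG1_NEWICK = "(((OTU1:1,OTU2:1)OTU7:1,OTU3:1)OTU6:1,(OTU4:1,OTU5:1)OTU8:1)OTU9;"


@pytest.fixture
def fig1_tree():
    """Five-leaf rooted tree: root OTU9 -> (OTU6 -> (OTU7 -> (1,2), 3), OTU8 -> (4,5))."""
    return parse_newick(FIG1_NEWICK)


@pytest.fixture
def fig1_counts():
    return pd.DataFrame(
        [[1, 2, 3, 4, 5]],
        columns=["OTU1", "OTU2", "OTU3", "OTU4", "OTU5"],
        index=["s1"],
    )


@pytest.fixture(scope="session")
def small_study():
    """A reusable 20-leaf community with 40 samples for pipeline tests."""
    rng = np.random.default_rng(42)
    tree = simulate_tree(20, 42)
    model = CommunityModel.default(20, 43)
    from miaf import simulate_abundances

    X, reads = simulate_abundances(model, 40, 44)
    counts = pd.DataFrame(
        reads, columns=tree.leaf_labels, index=[f"S{i}" for i in range(40)]
    )
    Y = rng.binomial(1, 0.5, 40).astype(float)
    Z = rng.standard_normal((40, 2))
    return tree, counts, Y, Z
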