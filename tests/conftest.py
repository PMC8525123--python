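import numpy as np
import pandas as pd
import pytest

from assemblage.io import CommunityTable, Dataset, harmonize, parse_newick

#: 4-tip balanced tree used for all hand-computable phylogenetic fixtures
BALANCED_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def balanced_tree():
    return parse_newick(BALANCED_NEWICK)


def make_table(counts, sample_ids=None, asv_ids=None, days=None, groups=None, taxonomy=None):
    counts = np.asarray(counts)
    n, m = counts.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    asv_ids = asv_ids or [chr(ord("A") + j) for j in range(m)]
    meta = pd.DataFrame(
        {
            "group": groups or ["G1"] * n,
            "day": days or [0] * n,
            "replicate": list(range(1, n + 1)),
        },
        index=sample_ids,
    )
    tax = pd.Series(
        taxonomy or [f"d;p;c;o;f;g__{a};s" for a in asv_ids], index=asv_ids
    )
    return CommunityTable(pd.DataFrame(counts, index=sample_ids, columns=asv_ids), meta, tax)


@pytest.fixture
def toy_table():
    return make_table([[5, 0, 3, 1], [2, 2, 0, 1], [0, 4, 4, 0]])


@pytest.fixture
def balanced_dataset(balanced_tree):
    table = make_table([[5, 1, 3, 1], [2, 2, 1, 1], [1, 4, 4, 2]])
    return harmonize(table, balanced_tree)
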