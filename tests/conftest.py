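import numpy as np
import pandas as pd
import pytest

from ecoassembly.containers import OtuTable
from ecoassembly.io import tree_from_newick

# caterpillar tree with distinct, hand-checkable branch lengths
CATERPILLAR = "((((A:1,B:2):1,C:3):1,D:4):1,E:5):0;"
CATERPILLAR_TIPS = ["A", "B", "C", "D", "E"]


@pytest.fixture
def caterpillar_tree():
    return tree_from_newick(CATERPILLAR)


def brute_force_patristic(tree, tips):
    """Independent path-sum oracle: distance = depth(a) + depth(b) - 2*depth(lca)."""
    def depth(node):
        d = 0.0
        while node.parent is not None:
            d += node.length
            node = node.parent
        return d

    out = np.zeros((len(tips), len(tips)))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            if i == j:
                continue
            na, nb = tree.find(a), tree.find(b)
            lca = tree.lowest_common_ancestor([na, nb])
            out[i, j] = depth(na) + depth(nb) - 2 * depth(lca)
    return out


def mc_se_of_sd(values, n_draws: int) -> float:
    """Monte-Carlo standard error of a sample SD of ``n_draws`` iid draws
    from the exact distribution ``values`` (fourth-moment formula, no
    normality assumption)."""
    v = np.asarray(values, dtype=float)
    var = v.var()
    m4 = ((v - v.mean()) ** 4).mean()
    return float(np.sqrt(max(m4 - var**2, 0.0) / (4 * var) / n_draws))


def make_table(counts, sample_ids=None, otu_ids=None) -> OtuTable:
    counts = np.asarray(counts)
    n, p = counts.shape
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    otu_ids = otu_ids or [f"OTU_{j + 1}" for j in range(p)]
    return OtuTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids))
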