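import numpy as np
import pandas as pd
import pytest

import divtime as dt

# the 3-tip worked tree used throughout: MRCA(A,B) at 10 Myr, root at 40 Myr
T1 = "((A:10,B:10):30,C:40);"
T1_POLY = "((A:10,B:10,X:10):30,C:40);"


@pytest.fixture
def t1():
    return dt.parse_chronogram(T1)


@pytest.fixture
def t1_poly():
    return dt.parse_chronogram(T1_POLY)


@pytest.fixture
def t1_taxa():
    return dt.TaxonTable(pd.DataFrame([
        dict(species=s, genus="Genus1", family="Fam1", order="Ord1",
             status="native")
        for s in "ABC"
    ]))


@pytest.fixture
def random_tree():
    """Factory: seeded Yule tree with n tips (labels t1..tn)."""

    def _make(n_tips=20, seed=0, birth=1.0, death=0.0):
        return dt.simulate_bd_chronogram(
            dt.BDParams.constant(birth, death, n_tips=n_tips, seed=seed)
        )

    return _make


def mrca_age(tree, labels):
    """Independent oracle: MRCA age of a tip set via root paths."""
    tips = {t.label: t for t in tree.tips()}

    def path(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out[::-1]  # root first

    paths = [path(tips[l]) for l in labels]
    mrca = None
    for level in zip(*paths):
        if all(n is level[0] for n in level):
            mrca = level[0]
        else:
            break
    return mrca.age
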