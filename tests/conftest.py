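import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from taxafun.containers import (
    CountTable,
    GenomeContentMatrix,
    PathwayHierarchy,
    TaxonomicProfile,
)


@pytest.fixture
def two_leaf_tree() -> TreeNode:
    return TreeNode.read(io.StringIO("(A:1,B:1);"))


@pytest.fixture
def small_tree() -> TreeNode:
    return TreeNode.read(io.StringIO("((A:1,B:2):0.5,(C:3,D:1):0.25);"))


@pytest.fixture
def small_profile() -> TaxonomicProfile:
    return TaxonomicProfile(np.array(["A", "B", "C", "D"], dtype=object),
                            np.array([0.4, 0.3, 0.2, 0.1]))


@pytest.fixture
def small_content() -> GenomeContentMatrix:
    cn = pd.DataFrame(
        [[2.0, 0.0, 1.0, 1.0],
         [0.0, 2.0, 1.0, 1.0],
         [1.0, 1.0, 0.0, 1.0],
         [3.0, 0.0, 0.0, 1.0]],
        index=["A", "B", "C", "D"],
        columns=["F1", "F2", "F3", "F4"],
    )
    rrna = pd.Series([1.0, 2.0, 1.0, 4.0], index=cn.index)
    return GenomeContentMatrix(cn, rrna=rrna)


@pytest.fixture
def small_hierarchy() -> PathwayHierarchy:
    return PathwayHierarchy.from_pairs(
        [("F1", "P1"), ("F2", "P1"), ("F2", "P2"), ("F3", "P2"), ("F4", "P1")]
    )


@pytest.fixture
def count_table() -> CountTable:
    counts = pd.DataFrame(
        [[3000, 2000, 500, 0],
         [6000, 100, 200, 700],
         [2000, 1000, 500, 500]],
        index=["S1", "S2", "S3"],
        columns=["A", "B", "C", "D"],
    )
    taxonomy = pd.Series(
        {
            "A": "k__Bacteria; p__Firmicutes",
            "B": "k__Bacteria; p__Bacteroidetes",
            "C": "k__Bacteria; c__Chloroplast; o__Streptophyta",
            "D": "k__Bacteria; p__Proteobacteria",
        }
    )
    return CountTable(counts, taxonomy=taxonomy)


def brute_force_weighted_unifrac(p: dict, q: dict, tree: TreeNode,
                                 normalized: bool = True) -> float:
    """Independent per-branch oracle: explicit subtree sums via tip sets."""
    raw = 0.0
    for node in tree.postorder(include_self=False):
        tips = {node.name} if node.is_tip() else {t.name for t in node.tips()}
        a = sum(p.get(t, 0.0) for t in tips)
        b = sum(q.get(t, 0.0) for t in tips)
        raw += (node.length or 0.0) * abs(a - b)
    if not normalized:
        return raw
    denom = 0.0
    for tip in tree.tips():
        depth = 0.0
        node = tip
        while node.parent is not None:
            depth += node.length or 0.0
            node = node.parent
        denom += depth * (p.get(tip.name, 0.0) + q.get(tip.name, 0.0))
    return raw / denom if denom else 0.0


def enumerate_rooted_topologies(leaves: tuple) -> list:
    """All rooted binary topologies over labeled leaves, as newick strings."""
    if len(leaves) == 1:
        return [leaves[0]]
    out = []
    first, rest = leaves[0], leaves[1:]
    # split: subsets of rest joining `first` on the left side (avoid mirror dups)
    for mask in range(2 ** len(rest) - 1):
        left = [first] + [t for i, t in enumerate(rest) if mask >> i & 1]
        right = [t for i, t in enumerate(rest) if not mask >> i & 1]
        for lt in enumerate_rooted_topologies(tuple(left)):
            for rt in enumerate_rooted_topologies(tuple(right)):
                out.append(f"({lt},{rt})")
    return out
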