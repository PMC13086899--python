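import numpy as np
import pandas as pd
import pytest

from neuroallometry import PhyloTree, SimulationConfig, simulate_dataset, simulate_tree


@pytest.fixture
def tree3():
    """3-tip ultrametric tree, all depths 1."""
    return PhyloTree.from_newick("((B:0.5,C:0.5):0.5,A:1.0);")


@pytest.fixture
def tree4():
    """Balanced 4-tip tree with two cherries."""
    return PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def tree15():
    """Fixed 15-tip ultrametric pure-birth tree."""
    return simulate_tree(15, seed=42)


def star_tree(n: int, depth: float = 1.0) -> PhyloTree:
    tips = ",".join(f"s{i}:{depth}" for i in range(n))
    return PhyloTree.from_newick(f"({tips});")


@pytest.fixture
def default_dataset():
    """One synthetic study dataset at generator defaults."""
    return simulate_dataset(SimulationConfig(seed=7))


def brute_force_vcv(tree: PhyloTree):
    """Independent covariance oracle: explicit root-to-tip edge paths.

    For each tip, collect the set of edges on its root path; the
    covariance of a pair is the summed length of the edges the two
    paths share.
    """
    dtree = tree._tree
    paths = {}
    for leaf in dtree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append((id(node), node.edge.length))
            node = node.parent_node
        paths[leaf.taxon.label] = dict(edges)
    labels = tree.tip_labels
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = set(paths[a]) & set(paths[b])
            C[i, j] = sum(paths[a][e] for e in shared)
    return labels, C
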