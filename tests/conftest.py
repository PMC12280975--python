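"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own algorithms: random
trees are generated by direct newick-string construction, and the
covariance oracle intersects explicit root-to-tip edge sets.
"""

import dendropy
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# ----------------------------------------------------------------------
# independent random-tree generator (direct newick construction)

def random_newick(rng: np.random.Generator, n_tips: int,
                  ultrametric: bool = False) -> str:
    """Random binary tree as a newick string, built by recursive splitting."""
    labels = [f"t{i}" for i in range(n_tips)]
    rng.shuffle(labels)

    if ultrametric:
        def build(tips, height):
            if len(tips) == 1:
                return f"{tips[0]}:{height:.10f}"
            k = int(rng.integers(1, len(tips)))
            child_h = height * rng.uniform(0.2, 0.8)
            left = build(tips[:k], child_h)
            right = build(tips[k:], child_h)
            return f"({left},{right}):{height - child_h:.10f}"
        body = build(labels, 1.0)
        # strip the root edge length
        return f"{body.rsplit(':', 1)[0]};"

    def build(tips):
        if len(tips) == 1:
            return f"{tips[0]}:{rng.uniform(0.05, 2.0):.10f}"
        k = int(rng.integers(1, len(tips)))
        return (f"({build(tips[:k])},{build(tips[k:])})"
                f":{rng.uniform(0.0, 2.0):.10f}")
    inner = build(labels)
    return f"{inner.rsplit(':', 1)[0]};"


# ----------------------------------------------------------------------
# edge-set-intersection covariance oracle

def vcv_oracle(newick: str) -> tuple[list[str], np.ndarray]:
    """V[i, j] as the summed length of edges shared by root-to-tip paths."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    paths = {}
    for leaf in tree.leaf_node_iter():
        edges = {}
        node = leaf
        while node.parent_node is not None:
            edges[id(node.edge)] = node.edge.length or 0.0
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    n = len(labels)
    V = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = set(paths[a]) & set(paths[b])
            V[i, j] = sum(paths[a][e] for e in shared)
    return labels, V


def tip_depth_oracle(newick: str) -> dict[str, float]:
    labels, V = vcv_oracle(newick)
    return {lab: V[i, i] for i, lab in enumerate(labels)}


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_927)


@pytest.fixture
def three_tip_tree():
    from phylodom import read_newick
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_tip_tree():
    from phylodom import read_newick
    return read_newick("((A:0.3,B:0.3):0.7,(C:0.6,(D:0.2,E:0.2):0.4):0.4);")
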