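"""Shared fixtures: hand-built trees, a small synthetic dataset, templates."""

import dendropy
import numpy as np
import pytest

from jawmorph.phylo import TimeTree
from jawmorph.synthdata import SimConfig, jaw_template, simulate_dataset


def tree_from_newick(nwk, youngest_age=0.0):
    t = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    return TimeTree(t, youngest_age=youngest_age)


@pytest.fixture(scope="session")
def hand_tree():
    """((A:1,B:1):1,C:2); root at age 2, tips at 0."""
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def four_tip_tree():
    return tree_from_newick("(((A:1,B:1):1,C:2):1,D:3);")


@pytest.fixture(scope="session")
def template():
    return jaw_template()


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-taxon synthetic dataset reused across read-only tests."""
    return simulate_dataset(SimConfig(n_tips=40, seed=2024))


def all_rooted_topologies(tips):
    """All rooted binary labelled tree shapes over the given tips, as nested
    tuples; (2n-3)!! shapes via sequential tip addition to every edge."""
    if len(tips) == 1:
        return [tips[0]]
    out = []
    for sub in all_rooted_topologies(tips[:-1]):
        for t in _insert_everywhere(sub, tips[-1]):
            out.append(t)
    return out


def _insert_everywhere(tree, tip):
    yield (tree, tip)  # new root above the old one
    if isinstance(tree, tuple):
        left, right = tree
        for l2 in _insert_everywhere(left, tip):
            yield (l2, right)
        for r2 in _insert_everywhere(right, tip):
            yield (left, r2)


def topology_to_newick(tree, depth=0):
    """Nested tuples -> newick with deterministic, slightly varied branch
    lengths (so no two nodes share an age)."""
    counter = [0]

    def rec(node):
        counter[0] += 1
        bl = 1.0 + 0.13 * counter[0]
        if isinstance(node, tuple):
            return f"({rec(node[0])},{rec(node[1])}):{bl:.2f}"
        return f"{node}:{bl:.2f}"

    if isinstance(tree, tuple):
        return f"({rec(tree[0])},{rec(tree[1])});"
    return f"{tree};"
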