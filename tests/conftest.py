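"""Shared fixtures and random-tree helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from skbio import TreeNode

from phylomekit.treecore import parse_newick


def random_topology(labels, rng: np.random.Generator) -> TreeNode:
    """Random rooted binary topology by sequential insertion."""
    order = list(labels)
    rng.shuffle(order)
    tree = TreeNode()
    tree.extend([TreeNode(name=order[0]), TreeNode(name=order[1])])
    for name in order[2:]:
        edges = list(tree.traverse(include_self=False))
        node = edges[int(rng.integers(len(edges)))]
        parent = node.parent
        parent.remove(node)
        joint = TreeNode()
        joint.extend([node, TreeNode(name=name)])
        parent.append(joint)
    return tree


def with_random_lengths(tree: TreeNode, rng: np.random.Generator) -> TreeNode:
    for node in tree.traverse(include_self=False):
        node.length = float(rng.uniform(0.05, 0.5))
    return tree


@pytest.fixture(scope="session")
def five_taxon_tree() -> TreeNode:
    return parse_newick(
        "((A:0.1,B:0.2):0.05,(C:0.3,(D:0.1,E:0.25):0.1):0.07);"
    )


@pytest.fixture(scope="session")
def simulated_phylome():
    """One moderate phylome with planted events, shared across tests."""
    from phylomekit.synthetic_data import SimulationConfig, simulate_phylome

    cfg = SimulationConfig(
        n_species=8, n_families=60, dup_rate=0.3, loss_rate=0.0,
        sampling_prob=1.0, seed=7,
    )
    phylome, truth = simulate_phylome(cfg)
    return cfg, phylome, truth
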