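"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from psgls import Phylogeny


def phylogeny_from_newick(newick: str) -> Phylogeny:
    return Phylogeny(tree=dendropy.Tree.get(data=newick, schema="newick"))


def shared_path_oracle(phy: Phylogeny, taxa_order: list[str]) -> np.ndarray:
    """Brute-force Sigma: intersect explicit root-to-tip edge sets.

    Independent of the production route (patristic distances): for each
    tip the chain of edges up to the root is materialized, and the shared
    path length of a pair is the summed length of the edges their chains
    have in common.
    """
    paths: dict[str, dict[int, float]] = {}
    for leaf in phy.tree.leaf_node_iter():
        chain: dict[int, float] = {}
        node = leaf
        while node.parent_node is not None:
            chain[id(node.edge)] = float(node.edge.length or 0.0)
            node = node.parent_node
        paths[leaf.taxon.label] = chain
    n = len(taxa_order)
    sigma = np.zeros((n, n))
    for i, a in enumerate(taxa_order):
        for j, b in enumerate(taxa_order):
            shared = set(paths[a]) & set(paths[b])
            sigma[i, j] = sum(paths[a][e] for e in shared)
    return sigma


def random_integer_tree(rng: np.random.Generator, n_tips: int) -> Phylogeny:
    """Random topology with integer branch lengths (exact arithmetic)."""
    from psgls import simulate_tree

    phy = simulate_tree(n_tips, seed=int(rng.integers(2**31)))
    for edge in phy.tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = int(rng.integers(1, 6))
    return phy


@pytest.fixture
def small_tree() -> Phylogeny:
    """The worked three-tip example: ((A:1,B:1):1,C:2)."""
    return phylogeny_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180411)
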