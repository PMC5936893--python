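"""Trees and the phylogenetic covariance structure.

A rooted ultrametric tree with branch lengths in time units induces the
Brownian-motion trait covariance: the covariance of two tips is the depth
of their most recent common ancestor (the shared root-to-tip path length),
and the variance of a tip is its root-to-tip depth.  This module reads
tree samples (Newick / NEXUS) and converts each tree into that matrix,
plus the unit-diagonal normalization the regression model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloCovariance",
    "Phylogeny",
    "assert_ultrametric",
    "normalize_covariance",
    "phylo_covariance_matrix",
    "read_trees",
]


@dataclass
class Phylogeny:
    """A rooted tree with labeled tips and nonnegative branch lengths."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label if leaf.taxon else "" for leaf in self.tree.leaf_node_iter()]
        if len(labels) < 2:
            raise ValueError("a phylogeny needs at least 2 tips")
        if any(not lab for lab in labels):
            raise ValueError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", real_value_format_specifier=".6g").strip()


@dataclass
class PhyloCovariance:
    """Taxon-ordered shared-path-length matrix and root-to-tip depths."""

    taxa: list[str]
    sigma: np.ndarray
    depths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.depths is None:
            self.depths = np.diag(self.sigma).copy()
        self.depths = np.asarray(self.depths, dtype=float)


def read_trees(path: str, schema: str | None = None) -> list[Phylogeny]:
    """Read a tree sample from a Newick or NEXUS file, in file order.

    All trees must share an identical tip-label set; a mismatch is an
    error rather than a silent prune.  ``schema`` is inferred from the
    file extension when omitted (.nex/.nexus -> nexus, otherwise newick).
    """
    if schema is None:
        schema = "nexus" if str(path).lower().endswith((".nex", ".nexus", ".nxs")) else "newick"
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unsupported schema {schema!r}")
    try:
        tree_list = dendropy.TreeList.get(path=str(path), schema=schema)
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "Multiple occurrences of the same taxa" in msg:
            raise ValueError(f"duplicate tip labels in {path}") from exc
        raise ValueError(f"failed to parse {path} as {schema}: {msg}") from exc
    if len(tree_list) == 0:
        raise ValueError(f"no trees found in {path}")
    phylos = [Phylogeny(tree=t) for t in tree_list]
    ref = set(phylos[0].tips)
    for i, phy in enumerate(phylos[1:], start=2):
        if set(phy.tips) != ref:
            raise ValueError(f"tree {i} has a different tip set from tree 1")
    return phylos


def _root_depths(phy: Phylogeny) -> dict[str, float]:
    phy.tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {leaf.taxon.label: float(leaf.root_distance) for leaf in phy.tree.leaf_node_iter()}


def phylo_covariance_matrix(
    phy: Phylogeny, taxa_order: list[str] | None = None
) -> PhyloCovariance:
    """Shared root-to-MRCA path lengths between every tip pair.

    sigma[i, j] is the depth of the most recent common ancestor of tips i
    and j measured from the root, computed as (h_i + h_j - d_ij) / 2 from
    the patristic distance d_ij; the diagonal holds the root-to-tip
    depths h.
    """
    tips = phy.tips
    if taxa_order is None:
        taxa_order = sorted(tips)
    if sorted(taxa_order) != sorted(tips):
        raise ValueError("taxa_order is not a permutation of the tree's tips")
    depth_of = _root_depths(phy)
    pdm = phy.tree.phylogenetic_distance_matrix()
    taxon_of = {leaf.taxon.label: leaf.taxon for leaf in phy.tree.leaf_node_iter()}
    n = len(taxa_order)
    sigma = np.zeros((n, n))
    for i, a in enumerate(taxa_order):
        sigma[i, i] = depth_of[a]
        for j in range(i + 1, n):
            b = taxa_order[j]
            d = pdm.patristic_distance(taxon_of[a], taxon_of[b])
            shared = 0.5 * (depth_of[a] + depth_of[b] - d)
            sigma[i, j] = sigma[j, i] = max(shared, 0.0)
    return PhyloCovariance(taxa=list(taxa_order), sigma=sigma)


def normalize_covariance(pc: PhyloCovariance) -> PhyloCovariance:
    """Rescale to unit diagonal: sigma*[i,j] = sigma[i,j] / sqrt(h_i h_j).

    For an ultrametric tree (constant depth h) this is exactly sigma / h;
    the global scale is absorbed into the GLS variance sigma2.  Idempotent.
    """
    if np.any(pc.depths <= 0):
        raise ValueError("all root-to-tip depths must be positive to normalize")
    scale = np.sqrt(np.outer(pc.depths, pc.depths))
    sigma = pc.sigma / scale
    np.fill_diagonal(sigma, 1.0)
    return PhyloCovariance(taxa=list(pc.taxa), sigma=sigma, depths=np.ones(len(pc.taxa)))


def assert_ultrametric(phy: Phylogeny, tol: float = 1e-6) -> bool:
    """True iff all root-to-tip depths agree within relative tolerance."""
    depths = np.array(list(_root_depths(phy).values()))
    dmax = depths.max()
    if dmax == 0:
        return True
    return bool((dmax - depths.min()) <= tol * dmax)
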