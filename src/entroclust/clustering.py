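"""Distance-matrix clustering of genomes and Newick serialization.

Agglomerative linkage (UPGMA by default, complete and single selectable)
produces a rooted ultrametric dendrogram whose merge heights are the
inter-cluster distances; leaf-to-root depth is half the final merge height so
that two genomes at distance d sit on a cherry with branches d/2 each.
Neighbor joining produces an unrooted tree. Input label order never affects
the result: labels are sorted lexicographically before linkage, which also
makes tie-breaking deterministic across platforms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .distance import DistanceMatrix

LINKAGE_METHODS = ("average", "complete", "single")
METHODS = LINKAGE_METHODS + ("nj",)


class ClusteringError(ValueError):
    """Raised for invalid clustering inputs."""


@dataclass(frozen=True)
class ClusterTree:
    """A genome tree with branch lengths, backed by a dendropy Tree.

    ``rooted`` is True for agglomerative dendrograms and False for neighbor
    joining. ``merges`` (linkage methods only) records the merge sequence as
    (cluster1, cluster2, height, size) rows, heights being inter-cluster
    distances as in R's hclust.
    """

    tree: dendropy.Tree
    leaves: tuple[str, ...]
    method: str
    rooted: bool
    merges: pd.DataFrame | None = None

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (rooted trees)."""
        out = {}
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out


def _scipy_to_dendropy(z: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = to_tree(z)

    def build(scinode, parent_height: float, parent: dendropy.Node) -> None:
        height = scinode.dist / 2.0
        child = parent.new_child(edge_length=parent_height - height)
        if scinode.is_leaf():
            child.taxon = taxa.get_taxon(labels[scinode.id])
        else:
            build(scinode.left, height, child)
            build(scinode.right, height, child)

    root_height = root.dist / 2.0
    tree.seed_node.edge.length = None
    if root.is_leaf():  # single genome; not reachable via hierarchical_cluster
        tree.seed_node.taxon = taxa.get_taxon(labels[root.id])
    else:
        build(root.left, root_height, tree.seed_node)
        build(root.right, root_height, tree.seed_node)
    tree.is_rooted = True
    return tree


def _merge_table(z: np.ndarray, labels: Sequence[str]) -> pd.DataFrame:
    n = len(labels)

    def name(idx: int) -> str:
        return labels[idx] if idx < n else f"C{idx - n + 1}"

    rows = [
        {
            "cluster1": name(int(a)),
            "cluster2": name(int(b)),
            "height": h,
            "size": int(s),
        }
        for a, b, h, s in z
    ]
    return pd.DataFrame(rows)


def _nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    # dendropy's distance-matrix reader takes delimited text; labels are
    # sanitized the same way as for PHYLIP export
    labels = [l.replace("\t", " ") for l in dm.labels]
    buf = io.StringIO()
    buf.write("." + "\t" + "\t".join(labels) + "\n")
    for lab, row in zip(labels, dm.values):
        buf.write(lab + "\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter="\t")
    tree = pdm.nj_tree()
    tree.is_rooted = False
    # NJ can produce slightly negative branch lengths; clamp to zero
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


def hierarchical_cluster(dm: DistanceMatrix, method: str = "average") -> ClusterTree:
    """Build a genome tree from a distance matrix.

    ``method`` is one of ``average`` (UPGMA, default), ``complete``,
    ``single`` or ``nj`` (neighbor joining, unrooted). The matrix is
    reordered to lexicographic label order first, so the result is
    independent of input order and ties resolve deterministically.
    """
    if method not in METHODS:
        raise ClusteringError(f"unknown method {method!r}; choose from {METHODS}")
    if len(dm.labels) < 2:
        raise ClusteringError("need at least 2 genomes to cluster")
    dm = dm.reorder(sorted(dm.labels))
    if method == "nj":
        if len(dm.labels) < 3:
            raise ClusteringError("neighbor joining needs at least 3 genomes")
        tree = _nj_tree(dm)
        return ClusterTree(tree=tree, leaves=dm.labels, method=method, rooted=False)
    z = linkage(squareform(dm.values, checks=False), method=method)
    tree = _scipy_to_dendropy(z, dm.labels)
    return ClusterTree(
        tree=tree,
        leaves=dm.labels,
        method=method,
        rooted=True,
        merges=_merge_table(z, dm.labels),
    )


def to_newick(ct: ClusterTree) -> str:
    """Serialize a tree to Newick with branch lengths; labels quoted as needed."""
    return ct.tree.as_string(
        schema="newick", preserve_spaces=True, suppress_rooting=True
    ).strip() + "\n"


def from_newick(text: str, rooted: bool = True, method: str = "unknown") -> ClusterTree:
    """Parse a Newick string back into a ClusterTree."""
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    tree.is_rooted = rooted
    leaves = tuple(sorted(lf.taxon.label for lf in tree.leaf_node_iter()))
    return ClusterTree(tree=tree, leaves=leaves, method=method, rooted=rooted)


def _clade_sets(ct: ClusterTree) -> set[frozenset[str]]:
    all_leaves = frozenset(ct.leaves)
    sets: set[frozenset[str]] = {frozenset([l]) for l in ct.leaves}
    sets.add(all_leaves)
    for node in ct.tree.preorder_node_iter():
        if node.is_leaf() or node is ct.tree.seed_node:
            continue
        tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sets.add(tips)
        if not ct.rooted:
            # in an unrooted tree each edge defines a split; either side counts
            sets.add(all_leaves - tips)
    return sets


def bipartition_check(ct: ClusterTree, groups: Sequence[Sequence[str]]) -> bool:
    """True iff every group is a clade (monophyletic) in the tree.

    ``groups`` must partition the leaf set exactly. For unrooted trees a
    group counts as a clade when some edge separates it from the rest.
    """
    flat = [l for g in groups for l in g]
    if sorted(flat) != sorted(ct.leaves):
        raise ClusteringError("groups do not partition the leaf set")
    clades = _clade_sets(ct)
    return all(frozenset(g) in clades for g in groups)
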