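"""Distance-based phylogeny over SH3 domains and the cut into specificity families.

Two trees matter in this analysis: one from the full domain alignment and one
from the interface-restricted alignment.  Distances are p-distances (mismatch
fraction over columns where neither record gaps), trees are neighbor joining
(exact on additive matrices), and a k-family partition is obtained by cutting
the k−1 longest branches of the interface tree.

Neighbor joining itself is delegated to scikit-bio; this module owns the
distance model, validation, deterministic family cutting and Newick/PHYLIP
plumbing.
"""

from __future__ import annotations

import io
import warnings

import networkx as nx
import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .interface_msa import GAP, Alignment


def p_distance(a: str, b: str) -> float:
    """Mismatch fraction over columns where neither sequence has a gap."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    compared = mismatches = 0
    for ca, cb in zip(a, b):
        if ca == GAP or cb == GAP:
            continue
        compared += 1
        if ca != cb:
            mismatches += 1
    if compared == 0:
        raise ValueError("zero comparable (gap-free) sites; p-distance undefined")
    return mismatches / compared


def alignment_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Symmetric p-distance matrix over all alignment records."""
    ids = aln.ids
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(aln.sequence(ids[i]), aln.sequence(ids[j]))
            m[i, j] = m[j, i] = d
    return DistanceMatrix(m, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths are clamped to zero.

    Requires at least three taxa.  On an additive matrix the tree's
    path-length metric reproduces the input distances exactly.
    """
    if dm.shape[0] < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {dm.shape[0]}")
    tree = nj(dm)
    clamped = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to zero", stacklevel=2)
    return tree

def tree_path_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length metric of a tree (the additive-matrix oracle)."""
    return tree.tip_tip_distances()


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Unrooted split set: for each edge, the smaller-or-canonical leaf side."""
    all_tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if 1 < len(side) < len(all_tips) - 1:
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_phylip(dm: DistanceMatrix, path) -> None:
    """PHYLIP square distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for rid in dm.ids:
            row = " ".join(f"{dm[rid, cid]:.6f}" for cid in dm.ids)
            fh.write(f"{rid[:50]:<12s}{row}\n")


def read_phylip(path) -> DistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline())
        ids, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(np.asarray(rows), ids)


def cut_into_families(tree: TreeNode, k: int) -> dict[str, int]:
    """Partition leaves into k families by cutting the k−1 longest branches.

    Internal branches are ranked before terminal ones (cutting between clades
    is preferred; terminal cuts are only needed when k approaches the leaf
    count).  Within each group branches are ordered by length descending, with
    ties broken by the lexicographically smallest leaf name below the branch,
    so the cut is deterministic.  Returns leaf id -> family label (1-based,
    numbered by smallest member id).
    """
    tips = list(tree.tips())
    n = len(tips)
    if not 1 <= k <= n:
        raise ValueError(f"family count k={k} outside [1, {n}]")

    g = nx.Graph()
    edges = []  # (is_terminal, -length, tiebreak, child_node)
    for node in tree.traverse(include_self=True):
        if node.parent is None:
            continue
        length = node.length or 0.0
        below = sorted(t.name for t in node.tips()) or [node.name]
        edges.append((node.is_tip(), -length, below[0], node))
        g.add_edge(id(node.parent), id(node))

    tip_ids = {id(t) for t in tips}

    def tip_groups() -> int:
        return sum(
            1 for comp in nx.connected_components(g) if comp & tip_ids
        )

    # Greedy: accept a cut only if it actually splits a leaf group, so k
    # groups are always reachable (terminal cuts give singletons at worst).
    for cut in sorted(edges):
        if tip_groups() >= k:
            break
        node = cut[3]
        g.remove_edge(id(node.parent), id(node))
        if not (
            nx.node_connected_component(g, id(node)) & tip_ids
            and nx.node_connected_component(g, id(node.parent)) & tip_ids
        ):
            g.add_edge(id(node.parent), id(node))  # cut stranded a no-leaf side

    node_of = {id(t): t.name for t in tips}
    families: list[list[str]] = []
    for comp in nx.connected_components(g):
        members = sorted(node_of[nid] for nid in comp if nid in node_of)
        if members:
            families.append(members)
    families.sort(key=lambda m: m[0])
    assignment = {}
    for label, members in enumerate(families, start=1):
        for m in members:
            assignment[m] = label
    return assignment
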