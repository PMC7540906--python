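"""Tree-based taxonomy: the order-cluster tree-quality metric, rOTU order
assignment by tree placement, and feeding-type transfer from the nearest
reference species.

The tree-quality metric counts, for each nematode order, the number of
maximal clades on a rooted cladogram whose leaves all belong to that order:
a perfectly resolved order forms one cluster (monophyly); fragmentation
shows up as extra clusters.  rOTU query leaves and the outgroup break
purity.  Orders represented by a single reference species are reported but
flagged as omitted from comparisons, since their count is 1 by construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "ClusterReport",
    "count_order_clusters",
    "assign_rotu_order",
    "assign_feeding_type",
    "compare_concatenations",
]

#: Leaf labels that are not reference orders and always break clade purity.
NON_ORDER_LABELS = {"rOTU", "outgroup"}


@dataclass
class ClusterReport:
    table: pd.DataFrame          # order, n_species, n_clusters, max_cluster_size, omitted
    memberships: dict[str, list[list[str]]]  # order -> list of leaf-name clusters


def count_order_clusters(
    tree: TreeNode,
    labels: dict[str, str],
) -> ClusterReport:
    """Count maximal single-order clades on a rooted tree.

    ``labels`` maps every leaf name to an order, ``"rOTU"`` or
    ``"outgroup"``.  For order X, a cluster is a maximal clade whose leaf
    set consists solely of X-labeled leaves; a pure clade containing the
    root counts as one cluster.
    """
    for t in tree.tips():
        if t.name not in labels:
            raise ValueError(f"unlabeled leaf {t.name!r}")

    purity: dict[int, str | None] = {}
    for node in tree.postorder():
        if node.is_tip():
            purity[id(node)] = labels[node.name]
        else:
            kinds = {purity[id(c)] for c in node.children}
            purity[id(node)] = kinds.pop() if len(kinds) == 1 else None

    memberships: dict[str, list[list[str]]] = {}
    for node in tree.preorder():
        lab = purity[id(node)]
        if lab is None or lab in NON_ORDER_LABELS:
            continue
        parent = node.parent
        if parent is not None and purity[id(parent)] == lab:
            continue  # not maximal
        memberships.setdefault(lab, []).append(
            sorted(t.name for t in (node.tips() if not node.is_tip() else [node]))
        )

    order_sizes = Counter(
        lab for lab in labels.values() if lab not in NON_ORDER_LABELS
    )
    rows = []
    for order in sorted(order_sizes):
        clusters = memberships.get(order, [])
        rows.append((
            order,
            order_sizes[order],
            len(clusters),
            max((len(c) for c in clusters), default=0),
            order_sizes[order] == 1,
        ))
    table = pd.DataFrame(rows, columns=[
        "order", "n_species", "n_clusters", "max_cluster_size", "omitted",
    ])
    return ClusterReport(table, memberships)


def assign_rotu_order(
    tree: TreeNode,
    rotu_leaf: str,
    labels: dict[str, str],
) -> tuple[str, int]:
    """Assign an order to a query (rOTU) leaf by walking to progressively
    larger ancestral clades.

    The first ancestral clade containing reference leaves decides: a
    unanimous reference order is assigned directly; a mixed clade assigns
    its majority order, with ties deferred to the next ancestor (a root-level
    tie is broken alphabetically).  Returns (order, supporting clade size).
    """
    if not any(labels.get(t.name) not in NON_ORDER_LABELS for t in tree.tips()):
        raise ValueError("tree has no reference leaves")
    node = tree.find(rotu_leaf)
    while node.parent is not None:
        node = node.parent
        refs = [labels[t.name] for t in node.tips()
                if labels.get(t.name) not in NON_ORDER_LABELS]
        if not refs:
            continue
        counts = Counter(refs)
        best = counts.most_common()
        if len(best) == 1 or best[0][1] > best[1][1]:
            return best[0][0], len(refs)
        if node.parent is None:  # root-level tie
            top = best[0][1]
            return sorted(o for o, c in best if c == top)[0], len(refs)
    raise ValueError(f"no informative ancestor for {rotu_leaf!r}")


def assign_feeding_type(
    tree: TreeNode,
    rotu_leaf: str,
    annotation: dict[str, str],
    reference_leaves: list[str] | None = None,
) -> tuple[str, str, float]:
    """Transfer the feeding code of the reference leaf at minimum patristic
    distance (ties broken by the lexicographically smaller leaf label).

    Returns (feeding code, nearest reference leaf, patristic distance).
    """
    tips = {t.name for t in tree.tips()}
    refs = [r for r in (reference_leaves or sorted(annotation)) if r in tips]
    if not refs:
        raise ValueError("no annotated reference leaves in tree")
    missing = [r for r in refs if r not in annotation]
    if missing:
        raise ValueError(f"missing feeding annotation for {missing[0]!r}")
    query = tree.find(rotu_leaf)
    best: tuple[float, str] | None = None
    for r in sorted(refs):
        dist = query.distance(tree.find(r))
        if best is None or dist < best[0] - 1e-12:
            best = (float(dist), r)
    return annotation[best[1]], best[1], best[0]


def compare_concatenations(
    trees: dict[str, tuple[TreeNode, dict[str, str]]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster counts per order across region sets.

    ``trees`` maps a region-set name (e.g. ``"R1_2"``) to a (rooted tree,
    leaf labels) pair.  Returns (orders x region-set matrix of n_clusters,
    same-shaped matrix of max cluster sizes).
    """
    n_frames, m_frames = [], []
    for name, (tree, labels) in trees.items():
        rep = count_order_clusters(tree, labels).table.set_index("order")
        n_frames.append(rep["n_clusters"].rename(name))
        m_frames.append(rep["max_cluster_size"].rename(name))
    n_mat = pd.concat(n_frames, axis=1)
    m_mat = pd.concat(m_frames, axis=1)
    return n_mat, m_mat
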