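"""Independent brute-force oracles used to validate the package's
implementations.  Everything here is deliberately naive and kept separate
from the code paths it checks."""

from __future__ import annotations

import itertools

import numpy as np
from skbio import TreeNode

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def brute_force_match(seq: str, pattern: str) -> list[int]:
    """Character-by-character degenerate scan."""
    hits = []
    m = len(pattern)
    for p in range(len(seq) - m + 1):
        if all(seq[p + k] in IUPAC[pattern[k]] for k in range(m)):
            hits.append(p)
    return hits


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook quadratic edit-distance DP."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


# ---------------------------------------------------------------------------
# Exhaustive unrooted-topology enumeration for the NJ oracle.


def enumerate_topologies(taxa: list[str]) -> list[list[tuple]]:
    """All unrooted binary topologies over ``taxa`` as edge lists.

    Nodes are taxon names (leaves) or integers (internal).  Built by
    inserting each taxon onto every edge of every smaller topology:
    1, 3, 15, 105 topologies for 3-6 taxa.
    """
    assert len(taxa) >= 3
    base = [[("i0", taxa[0]), ("i0", taxa[1]), ("i0", taxa[2])]]
    counter = 1
    for t in taxa[3:]:
        nxt = []
        for edges in base:
            for k in range(len(edges)):
                u, v = edges[k]
                new = f"i{counter}x{k}"
                grown = edges[:k] + edges[k + 1:]
                grown = grown + [(u, new), (new, v), (new, t)]
                nxt.append(grown)
        counter += 1
        base = nxt
    return base


def _paths(edges: list[tuple], taxa: list[str]) -> np.ndarray:
    """0/1 incidence of each edge on each leaf-pair path."""
    adj: dict = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    pairs = list(itertools.combinations(taxa, 2))
    mat = np.zeros((len(pairs), len(edges)))
    for row, (a, b) in enumerate(pairs):
        stack = [(a, None, [])]
        while stack:
            node, prev, used = stack.pop()
            if node == b:
                mat[row, used] = 1.0
                break
            for nb, eidx in adj[node]:
                if nb != prev:
                    stack.append((nb, node, used + [eidx]))
    return mat


def least_squares_topology(dm, taxa: list[str]) -> set[frozenset]:
    """Among all topologies, the one whose least-squares branch-length fit
    minimizes the squared error to the distance matrix; returned as its
    non-trivial bipartition set."""
    d = np.array([dm[a, b] for a, b in itertools.combinations(taxa, 2)])
    best = (np.inf, None)
    for edges in enumerate_topologies(taxa):
        mat = _paths(edges, taxa)
        lengths, *_ = np.linalg.lstsq(mat, d, rcond=None)
        sse = float(((mat @ lengths - d) ** 2).sum())
        if sse < best[0] - 1e-12:
            best = (sse, edges)
    return topology_bipartitions(best[1], taxa)


def topology_bipartitions(edges: list[tuple], taxa: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions (canonical smaller side) of an edge list."""
    out = set()
    full = frozenset(taxa)
    for k, (u, v) in enumerate(edges):
        adj: dict = {}
        for idx, (a, b) in enumerate(edges):
            if idx == k:
                continue
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        side = set()
        stack = [u]
        seen = {u}
        while stack:
            n = stack.pop()
            if isinstance(n, str) and n in full:
                side.add(n)
            for nb in adj.get(n, []):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(side)
        other = full - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


def random_additive_tree(taxa: list[str], rng: np.random.Generator):
    """Random unrooted binary topology with positive branch lengths and its
    implied (additive) distance matrix."""
    topos = enumerate_topologies(taxa)
    edges = topos[rng.integers(len(topos))]
    lengths = rng.uniform(0.5, 3.0, size=len(edges))
    adj: dict = {}
    for (u, v), L in zip(edges, lengths):
        adj.setdefault(u, []).append((v, L))
        adj.setdefault(v, []).append((u, L))
    dist = {}
    for a in taxa:
        stack = [(a, None, 0.0)]
        while stack:
            node, prev, acc = stack.pop()
            if isinstance(node, str) and node != a:
                dist[(a, node)] = acc
            for nb, L in adj[node]:
                if nb != prev:
                    stack.append((nb, node, acc + L))
    n = len(taxa)
    mat = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i != j:
                mat[i, j] = dist[(a, b)]
    mat = (mat + mat.T) / 2.0  # remove float accumulation asymmetry
    return edges, mat


# ---------------------------------------------------------------------------
# Cluster-count brute force.


def random_labeled_tree(n_leaves: int, orders: list[str],
                        rng: np.random.Generator) -> tuple[TreeNode, dict]:
    """Random rooted binary tree with random order labels on leaves."""
    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        nodes.append(TreeNode(children=[a, b]))
    tree = nodes[0]
    labels = {f"L{i}": orders[int(rng.integers(len(orders)))]
              for i in range(n_leaves)}
    return tree, labels


def brute_force_order_clusters(tree: TreeNode, labels: dict,
                               non_orders: set[str]) -> dict[str, int]:
    """Count maximal single-order clades by examining every node's tip set
    from scratch (no purity propagation)."""
    def tipset(node):
        return [t.name for t in node.tips()] if not node.is_tip() else [node.name]

    counts: dict[str, int] = {}
    for node in tree.traverse(include_self=True):
        tips = tipset(node)
        labs = {labels[t] for t in tips}
        if len(labs) != 1:
            continue
        lab = next(iter(labs))
        if lab in non_orders:
            continue
        parent = node.parent
        if parent is not None and len({labels[t] for t in tipset(parent)}) == 1:
            continue
        counts[lab] = counts.get(lab, 0) + 1
    return counts
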