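"""Distance-based phylogenies: pairwise distances, neighbor joining,
column-resampling bootstrap, and outgroup rooting.

Distances use pairwise deletion (columns holding a gap or N in either
sequence are skipped for that pair) under either the raw proportion of
differing sites (p-distance) or the Jukes-Cantor correction
d = -(3/4) ln(1 - (4/3) p), the simplest single-parameter substitution
model.  Neighbor joining is the classic Saitou-Nei agglomeration with the
Studier-Keppler Q-criterion; ties in Q are broken on the lowest (i, j)
index pair and negative branch lengths are clamped to zero with the deficit
transferred to the sibling edge, so output is deterministic.  Bootstrap
supports are counts (out of B replicates) of replicate trees containing the
same bipartition, stored on internal nodes and written as internal newick
labels.
"""

from __future__ import annotations

import logging

import numpy as np
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "pairwise_distance",
    "neighbor_joining",
    "bootstrap_support",
    "root_at_outgroup",
    "bipartitions",
]

_VALID = set("ACGT-N")


def _encode(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    for lab, s in seqs.items():
        bad = set(s.upper()) - _VALID
        if bad:
            raise ValueError(f"{lab}: invalid characters {sorted(bad)}")
    mat = np.frombuffer(
        "".join(seqs[l].upper() for l in labels).encode(), dtype=np.uint8
    ).reshape(len(labels), -1)
    return labels, mat


def _dist_from_matrix(mat: np.ndarray, labels: list[str],
                      model: str, saturation_cap: float) -> DistanceMatrix:
    n = mat.shape[0]
    gap = (mat == ord("-")) | (mat == ord("N"))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(gap[i] | gap[j])
            nv = int(valid.sum())
            if nv == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            p = float((mat[i, valid] != mat[j, valid]).sum()) / nv
            if model == "p":
                dij = p
            else:  # jukes-cantor
                dij = (-0.75 * np.log(1.0 - 4.0 * p / 3.0)
                       if p < 0.75 else saturation_cap)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(d, labels)


def pairwise_distance(
    seqs: dict[str, str],
    model: str = "jc",
    saturation_cap: float = 5.0,
) -> DistanceMatrix:
    """Distance matrix over aligned sequences ({A,C,G,T,-,N}).

    ``model``: ``"p"`` (proportion of differing sites) or ``"jc"``
    (Jukes-Cantor).  A saturated pair (p >= 3/4) is assigned
    ``saturation_cap`` under JC.
    """
    if model not in ("p", "jc"):
        raise ValueError(f"unknown model {model!r}")
    labels, mat = _encode(seqs)
    return _dist_from_matrix(mat, labels, model, saturation_cap)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating
    root node).  On an additive distance matrix the generating topology and
    branch lengths are recovered exactly."""
    d = np.asarray(dm.data, dtype=float)
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.ids]

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        # Negative length -> 0; deficit moved to the sibling edge so the
        # path length between the two joined taxa is preserved.
        if li < 0:
            lj += li
            logger.debug("clamped negative branch %.4g", li)
            li = 0.0
        if lj < 0:
            li += lj
            logger.debug("clamped negative branch %.4g", lj)
            lj = 0.0
        return li, max(lj, 0.0)

    while len(nodes) > 3:
        n = d.shape[0]
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major: lowest (i, j) on ties
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        li, lj = clamp_pair(li, lj)
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.empty((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    a.length, b.length, c.length = float(la), float(lb), float(lc)
    return TreeNode(children=[a, b, c])


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Canonical internal-edge bipartitions (smaller side, ties by sorted
    labels) of a tree, excluding trivial single-tip splits."""
    full = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = full - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(canon)
    return out


def bootstrap_support(
    seqs: dict[str, str],
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "jc",
    saturation_cap: float = 5.0,
) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement ``n_replicates`` times (one
    column-index draw per replicate, shared by every pair, so results do not
    depend on leaf input order); the support of an internal edge is the
    number of replicate trees containing the same bipartition.  Supports are
    stored on internal nodes (``support`` attribute and node name).
    ``n_replicates=0`` returns the tree without supports.
    """
    ordered = {k: seqs[k] for k in sorted(seqs)}
    labels, mat = _encode(ordered)
    base = neighbor_joining(_dist_from_matrix(mat, labels, model, saturation_cap))
    if n_replicates <= 0:
        return base
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    ncol = mat.shape[1]
    for _ in range(n_replicates):
        idx = rng.integers(0, ncol, size=ncol)
        rep = neighbor_joining(
            _dist_from_matrix(mat[:, idx], labels, model, saturation_cap)
        )
        for bp in bipartitions(rep):
            counts[bp] = counts.get(bp, 0) + 1
    full = frozenset(labels)
    for node in base.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = full - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        node.support = counts.get(canon, 0)
        node.name = str(node.support)
    return base


def root_at_outgroup(tree: TreeNode, outgroup_label: str) -> TreeNode:
    """Root on the outgroup's pendant edge (at its midpoint); the ingroup
    topology is unchanged."""
    try:
        tip = tree.find(outgroup_label)
    except Exception as exc:
        raise ValueError(f"outgroup {outgroup_label!r} not in tree") from exc
    if not tip.is_tip():
        raise ValueError(f"outgroup {outgroup_label!r} is not a leaf")
    if tip.length is None or tip.length == 0:
        rooted = tree.root_at(tip.parent, reset=True, branch_attrs=[])
    else:
        rooted = tree.root_at(tip, above=tip.length / 2.0, reset=True,
                              branch_attrs=[])
    return rooted
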