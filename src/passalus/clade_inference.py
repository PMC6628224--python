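"""Distance-based two-clade inference: neighbor-joining, midpoint rooting,
basal bipartition, and column-bootstrap support for the basal split.

The goal of this module is a *reproducible* partition of sequences into the
two deepest lineages, not a full phylogenetic analysis: distances (p or K2P)
feed Saitou-Nei neighbor-joining, the unrooted tree is midpoint-rooted, and
the two subtrees of the root define the clades.  The majority clade is
labelled ``A``.  Support for the basal split is the fraction of
column-resampled bootstrap replicates whose basal bipartition matches the
full-data one.

Trees are :class:`skbio.TreeNode` objects, so newick serialisation and
traversal come from scikit-bio.  Neighbor-joining itself is implemented here
because the partition contract requires a fixed deterministic tie-break
(lexicographically smallest id pair among minimal-Q candidates); negative
branch-length estimates are clamped to zero.
"""

from __future__ import annotations

import logging
import math
from typing import Literal, Mapping

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .alignment_io import Alignment
from .diversity_stats import (
    Metric,
    NoComparableSitesError,
    SaturationError,
    _encode,
    diversity_summary,
    k2p_distance,
    p_distance,
)

__all__ = [
    "distance_matrix",
    "nj_tree",
    "midpoint_root",
    "basal_bipartition",
    "split_bootstrap",
    "assign_clades",
]

logger = logging.getLogger(__name__)


def distance_matrix(aln: Alignment, metric: Metric = "p") -> DistanceMatrix:
    """Pairwise distance matrix over all sequences.

    K2P saturation on any pair raises :class:`SaturationError` naming the
    pair.  p-distances are computed with a vectorised one-hot matrix product
    (identical to per-pair :func:`p_distance` calls, tested as such).
    """
    n = aln.n_sequences
    if n < 2:
        raise ValueError("distance matrix needs >= 2 sequences")
    if metric == "p":
        d = _p_distance_matrix(aln)
    else:
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    d[i, j] = d[j, i] = k2p_distance(aln.sequences[i], aln.sequences[j])
                except SaturationError as e:
                    raise SaturationError(
                        f"K2P saturation between {aln.ids[i]!r} and {aln.ids[j]!r}: {e}"
                    ) from None
    return DistanceMatrix(d, ids=list(aln.ids))


def _p_distance_matrix(aln: Alignment) -> np.ndarray:
    enc = _encode(aln)  # (n, L), 0 = undetermined
    det = (enc > 0).astype(np.float32)
    onehot = np.stack([(enc == c) for c in range(1, 5)], axis=2).astype(np.float32)
    n, L, _ = onehot.shape
    matches = onehot.reshape(n, L * 4) @ onehot.reshape(n, L * 4).T
    comp = det @ det.T
    if np.any(comp[~np.eye(n, dtype=bool)] == 0):
        i, j = np.argwhere((comp == 0) & ~np.eye(n, dtype=bool))[0]
        raise NoComparableSitesError(
            f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        d = (comp - matches) / comp
    np.fill_diagonal(d, 0.0)
    return ((d + d.T) / 2).astype(float)  # exact symmetry


def nj_tree(dm: DistanceMatrix, strict: bool = False) -> TreeNode:
    """Saitou-Nei neighbor-joining over a distance matrix.

    Joins the pair minimising Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k
    d(j,k); ties are broken by the lexicographically smallest (id, id) pair,
    where a cluster is identified by its smallest leaf id.  Branch lengths
    use the standard formulas; negative estimates are clamped to 0 (logged).
    Returns an unrooted tree (trifurcating root).  With fewer than 3 taxa a
    trivial tree is returned unless ``strict`` is true.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        if strict:
            raise ValueError("neighbor joining needs >= 3 taxa")
        if n == 1:
            return TreeNode(name=ids[0])
        half = float(dm[0, 1]) / 2.0
        return TreeNode(children=[TreeNode(name=ids[0], length=half), TreeNode(name=ids[1], length=half)])

    D = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    labels: list[str] = list(ids)  # smallest leaf id per cluster

    def _clamp(x: float) -> float:
        if x < 0:
            logger.debug("clamping negative NJ branch length %.4g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        pairs = {(int(i), int(j)) for i, j in cand if i < j}
        i, j = min(pairs, key=lambda p: tuple(sorted((labels[p[0]], labels[p[1]]))))
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = _clamp(li), _clamp(lj)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        new_label = min(labels[i], labels[j])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [new_label]

    # resolve the final three clusters around an unrooted (trifurcating) root
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = _clamp(0.5 * (d01 + d02 - d12))
    l1 = _clamp(0.5 * (d01 + d12 - d02))
    l2 = _clamp(0.5 * (d02 + d12 - d01))
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = length
    return TreeNode(children=list(nodes))


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Delegates to scikit-bio's midpoint rooting.  A tree whose tip-to-tip
    distances are all zero has no defined midpoint; in that case the root is
    placed on the first child edge and a warning is logged.
    """
    t = tree.copy()
    tips = list(t.tips())
    if len(tips) < 2:
        return t
    if len(tips) == 2 and len(t.children) == 2:
        total = (t.children[0].length or 0.0) + (t.children[1].length or 0.0)
        for c in t.children:
            c.length = total / 2.0
        return t
    total = sum((n.length or 0.0) for n in t.traverse() if n is not t)
    if total == 0.0:
        logger.warning("all pairwise distances zero; rooting on first child edge")
        return _split_child_edge(t, t.children[0])
    rooted = t.root_at_midpoint()
    if len(rooted.children) != 2:
        # midpoint coincides with an internal node; split the adjacent edge
        # leading towards the lexicographically smallest tip (deterministic)
        child = min(
            rooted.children,
            key=lambda c: min(tip.name for tip in c.tips(include_self=True)),
        )
        rooted = _split_child_edge(rooted, child)
    return rooted


def _split_child_edge(root: TreeNode, child: TreeNode) -> TreeNode:
    """Re-root by inserting a new root halfway along ``child``'s edge."""
    root.remove(child)
    half = (child.length or 0.0) / 2.0
    child.length = half
    root.length = half
    return TreeNode(children=[child, root])


def basal_bipartition(tree: TreeNode) -> dict[str, str]:
    """Clade labels ``{leaf id -> 'A' | 'B'}`` from the two subtrees of the root.

    The larger clade is labelled ``A`` (ties: the clade containing the
    lexicographically smallest leaf id).  The root must be binary.
    """
    if len(tree.children) != 2:
        raise ValueError(f"root has {len(tree.children)} children; expected 2 (rooted tree)")
    sides = [sorted(tip.name for tip in child.tips(include_self=True)) for child in tree.children]
    key = lambda leaves: (-len(leaves), leaves[0])
    sides.sort(key=key)
    out = {leaf: "A" for leaf in sides[0]}
    out.update({leaf: "B" for leaf in sides[1]})
    return out


def assign_clades(aln: Alignment, metric: Metric = "p") -> tuple[dict[str, str], TreeNode]:
    """Distance matrix -> NJ -> midpoint root -> basal bipartition.

    Returns the labels and the rooted tree.
    """
    tree = midpoint_root(nj_tree(distance_matrix(aln, metric)))
    return basal_bipartition(tree), tree


def _partition(labels: Mapping[str, str]) -> frozenset[frozenset[str]]:
    sides: dict[str, set[str]] = {}
    for leaf, clade in labels.items():
        sides.setdefault(clade, set()).add(leaf)
    return frozenset(frozenset(s) for s in sides.values())


def split_bootstrap(
    aln: Alignment,
    metric: Metric = "p",
    replicates: int = 1000,
    seed: int | None = None,
) -> float:
    """Column-bootstrap support for the full-data basal bipartition.

    Alignment columns are resampled with replacement; support is the fraction
    of replicates whose basal bipartition equals the full-data one.
    Replicates where distances are undefined (no comparable sites, K2P
    saturation) count as non-matching.  Returns ``nan`` when the alignment
    has no variation (the split is then undefined).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if diversity_summary(aln).segregating_sites == 0:
        return math.nan
    reference = _partition(assign_clades(aln, metric)[0])
    rng = np.random.default_rng(seed)
    hits = 0
    L = aln.length
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        res = Alignment(
            aln.ids, tuple("".join(seq[c] for c in cols) for seq in aln.sequences)
        )
        try:
            labels, _ = assign_clades(res, metric)
        except (NoComparableSitesError, SaturationError):
            continue
        if _partition(labels) == reference:
            hits += 1
    return hits / replicates
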