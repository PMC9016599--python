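"""Distance-based tree inference and tree-comparison metrics.

The internal inference engine is neighbor-joining on Jukes–Cantor-corrected
distances. This keeps the calibration machinery self-contained and fast at
desk scale; the calibration API also accepts externally inferred trees, so
maximum-likelihood estimates can be substituted when available.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .align import MISSING, Alignment
from .errors import NoSharedSitesError

__all__ = [
    "DistanceMatrix",
    "jc_distance_matrix",
    "nj_tree",
    "rf_distance",
    "tree_length_error",
    "tree_length",
    "stemminess_of_tree",
]

#: Observed proportion-difference cap: p-hat at or above this is truncated so
#: the JC correction stays finite for saturated pairs (the 3/4 divergence
#: limit would otherwise yield infinite distances).
P_DISTANCE_CAP = 0.749


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with taxon labels."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if not np.isfinite(m).all() or (m < 0).any():
            raise ValueError("distances must be finite and non-negative")


def jc_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Jukes–Cantor distances ``d = -3/4 ln(1 - 4 p/3)`` over shared sites.

    The proportion of differences for each pair is computed over sites where
    both sequences have a non-missing state, and capped at
    :data:`P_DISTANCE_CAP` so saturated pairs receive a large finite distance.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least two taxa")
    states = aln.states
    present = states != MISSING
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n - 1):
        shared = present[i] & present[i + 1 :]
        n_shared = shared.sum(axis=1)
        if (n_shared == 0).any():
            j = i + 1 + int(np.nonzero(n_shared == 0)[0][0])
            raise NoSharedSitesError(
                f"taxa {aln.taxa[i]!r} and {aln.taxa[j]!r} share no sites"
            )
        diff = ((states[i] != states[i + 1 :]) & shared).sum(axis=1)
        p_hat = np.minimum(diff / n_shared, P_DISTANCE_CAP)
        d[i, i + 1 :] = -0.75 * np.log1p(-4.0 * p_hat / 3.0)
    d = d + d.T
    return DistanceMatrix(aln.taxa, d)


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining (Saitou–Nei criterion, Studier–Keppler updates).

    Deterministic: among tied minima of the Q criterion the lowest-index
    pair is joined. Negative estimated branch lengths are clamped to zero.
    The returned tree is unrooted (trifurcating seed node).
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(list(dist.labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for taxon in tns:
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
    D = dist.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        Q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # first minimum = lowest (i, j) row-major
        ai, aj = divmod(flat, r)
        if ai > aj:
            ai, aj = aj, ai
        dij = sub[ai, aj]
        vi = 0.5 * dij + (rowsum[ai] - rowsum[aj]) / (2.0 * (r - 2))
        vj = dij - vi
        parent = dendropy.Node()
        ni, nj_ = nodes[active[ai]], nodes[active[aj]]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = max(vi, 0.0)
        nj_.edge.length = max(vj, 0.0)
        # Studier–Keppler distance update to the new node
        gi, gj = active[ai], active[aj]
        new_d = 0.5 * (D[gi, :] + D[gj, :] - dij)
        D = np.vstack([D, new_d])
        new_col = np.append(new_d, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    # connect the last three nodes to a central (unrooted) vertex
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    center = dendropy.Node()
    lengths = (
        0.5 * (dab + dac - dbc),
        0.5 * (dab + dbc - dac),
        0.5 * (dac + dbc - dab),
    )
    for node, length in zip((nodes[a], nodes[b], nodes[c]), lengths):
        center.add_child(node)
        node.edge.length = max(length, 0.0)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def _common_namespace(t1: dendropy.Tree, t2: dendropy.Tree):
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    set1 = {leaf.taxon.label for leaf in a.leaf_node_iter()}
    set2 = {leaf.taxon.label for leaf in b.leaf_node_iter()}
    if set1 != set2:
        raise ValueError("trees have different tip sets")
    for t in (a, b):
        t.is_rooted = False
        t.encode_bipartitions()
    return a, b


def rf_distance(
    t1: dendropy.Tree, t2: dendropy.Tree, normalized: bool = False
) -> float:
    """Unrooted Robinson–Foulds distance (bipartition symmetric difference).

    ``normalized=True`` divides by ``2 (n - 3)``, the maximum for two fully
    resolved unrooted trees on n tips.
    """
    a, b = _common_namespace(t1, t2)
    n = len({leaf.taxon.label for leaf in a.leaf_node_iter()})
    if n < 4:
        raise ValueError("Robinson-Foulds comparison needs >= 4 tips")
    rf = float(treecompare.symmetric_difference(a, b))
    if normalized:
        rf /= 2.0 * (n - 3)
    return rf


def tree_length(tree: dendropy.Tree) -> float:
    return float(
        sum(e.length or 0.0 for e in tree.preorder_edge_iter())
    )


def tree_length_error(estimated: dendropy.Tree, true: dendropy.Tree) -> float:
    """Signed proportional error: (estimated length - true length) / true."""
    lt = tree_length(true)
    if lt <= 0:
        raise ValueError("true tree length must be positive")
    return (tree_length(estimated) - lt) / lt


def stemminess_of_tree(tree: dendropy.Tree) -> float:
    """Proportion of total tree length on internal branches."""
    internal = external = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length or 0.0
        if node.is_leaf():
            external += length
        else:
            internal += length
    total = internal + external
    if total <= 0:
        raise ValueError("tree has zero total length")
    return internal / total
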