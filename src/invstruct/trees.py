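"""Phylogenetic utilities: neighbor joining, Robinson–Foulds distances,
LD-informed window selection and split-time calibration of node ages.

Windowed maximum-likelihood trees are consumed as newick; tree
topology similarity across windows (Robinson–Foulds) serves as a proxy
for linkage disequilibrium, and the windows topologically closest to
the right-most window (nearest the KANSL1 duplication) are selected
for dating.  Node ages are calibrated linearly against a fixed split
time (orangutan split 18.13 mya, human–chimpanzee split 7.74 mya).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "CalibrationPoint",
    "ORANGUTAN_SPLIT_MYA",
    "HUMAN_CHIMP_SPLIT_MYA",
    "nj_tree",
    "rf_distance",
    "rf_matrix",
    "read_trees",
    "select_ld_windows",
    "calibrate_node_ages",
    "rf_mds",
]

log = logging.getLogger(__name__)

#: default calibration ages in millions of years
ORANGUTAN_SPLIT_MYA = 18.13
HUMAN_CHIMP_SPLIT_MYA = 7.74


@dataclass(frozen=True)
class CalibrationPoint:
    """A clade (leaf label set) pinned to a known age in mya."""

    clade: frozenset[str]
    age_mya: float

    def __post_init__(self) -> None:
        if self.age_mya <= 0:
            raise ValueError("calibration age must be positive")
        if not self.clade:
            raise ValueError("calibration clade must be non-empty")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(matrix: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor joining on a symmetric distance matrix.

    Standard Q-criterion agglomeration (Saitou & Nei); ties in Q are
    broken deterministically toward the pair with the lowest original
    taxon indices; negative branch lengths are clamped to zero and
    logged.  Returns an unrooted dendropy tree.
    """
    D = np.asarray(matrix, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("matrix shape inconsistent with labels")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in labels]
    # active entries: (original-order key, node)
    keys = list(range(n))
    next_key = n
    D = D.copy()
    active = list(range(n))  # indices into rows of D

    def clamp(x: float, where: str) -> float:
        if x < 0:
            log.info("clamping negative branch length %.4g at %s", x, where)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # deterministic tie-break: lowest (key_i, key_j) among minima
        pairs = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((keys[active[i]], keys[active[j]]))), (i, j))
            for i, j in pairs
        )[1]
        i, j = sorted(best)
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li = clamp(li, f"join({keys[ai]},{keys[aj]})")
        lj = clamp(lj, f"join({keys[ai]},{keys[aj]})")
        parent = dendropy.Node()
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])
        nodes[ai].edge.length = li
        nodes[aj].edge.length = lj
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for pos, ak in enumerate(active):
            if ak in (ai, aj):
                continue
            new_row[ak] = 0.5 * (D[ai, ak] + D[aj, ak] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(next_key)
        next_key += 1
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    # resolve the final three-taxon star by the three-point formulas
    x, y, z = active
    root = dendropy.Node()
    lx = clamp(0.5 * (D[x, y] + D[x, z] - D[y, z]), "final star")
    ly = clamp(0.5 * (D[x, y] + D[y, z] - D[x, z]), "final star")
    lz = clamp(0.5 * (D[x, z] + D[y, z] - D[x, y]), "final star")
    for node, length in ((nodes[x], lx), (nodes[y], ly), (nodes[z], lz)):
        root.add_child(node)
        node.edge.length = length
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

def _check_leafsets(t1: dendropy.Tree, t2: dendropy.Tree) -> None:
    l1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    l2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError(
            f"trees have different leaf sets: {sorted(l1 ^ l2)} not shared"
        )


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted, unnormalized Robinson–Foulds distance.

    The size of the symmetric difference between the two trees'
    nontrivial bipartition sets; polytomies are allowed.  Trees must
    share a taxon namespace and an identical leaf set.
    """
    from dendropy.calculate import treecompare

    if t1.taxon_namespace is not t2.taxon_namespace:
        raise ValueError("trees must share a TaxonNamespace")
    _check_leafsets(t1, t2)
    return int(treecompare.symmetric_difference(t1, t2, is_bipartitions_updated=False))


def rf_normalized(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """RF distance divided by its maximum 2(n-3) for binary n-leaf trees."""
    n = sum(1 for _ in t1.leaf_node_iter())
    if n <= 3:
        return 0.0
    return rf_distance(t1, t2) / (2.0 * (n - 3))


def read_trees(paths, taxon_namespace: dendropy.TaxonNamespace | None = None):
    """Read newick trees (one per windowed phylogeny) on a shared namespace."""
    tns = taxon_namespace or dendropy.TaxonNamespace()
    return [
        dendropy.Tree.get(path=str(p), schema="newick", taxon_namespace=tns)
        for p in paths
    ]


def rf_matrix(trees) -> np.ndarray:
    n = len(trees)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = rf_distance(trees[i], trees[j])
    return out


def select_ld_windows(
    rf: np.ndarray, k: int = 1, anchor: int | None = None
) -> list[int]:
    """Pick the anchor window plus the k windows topologically closest to it.

    The anchor defaults to the right-most (last) window — the one
    nearest the KANSL1 duplication.  Ties in RF distance are broken
    toward the window genomically nearer the anchor.  Asking for
    k >= n-1 returns every window with a warning.
    """
    rf = np.asarray(rf, dtype=float)
    n = rf.shape[0]
    if rf.shape != (n, n) or n < 2:
        raise ValueError("need a square RF matrix over >= 2 windows")
    a = (n - 1) if anchor is None else anchor
    if k >= n:
        log.warning("k=%d >= %d windows; returning all", k, n)
        return list(range(n))
    others = [w for w in range(n) if w != a]
    # sort by (distance, genomic distance to anchor, index): deterministic
    others.sort(key=lambda w: (rf[a, w], abs(a - w), w))
    return sorted([a] + others[:k])


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_node_ages(
    tree: dendropy.Tree,
    calibration: CalibrationPoint,
    depth_tolerance: float = 0.1,
) -> dict[int, float]:
    """Assign node ages (mya) by linear scaling against a calibration clade.

    Each internal node's height is its mean path length to descendant
    leaves; ages scale so the calibration clade's MRCA sits exactly at
    the calibration age.  Assumes an approximately clock-like tree:
    relative spread of root-to-tip depths beyond ``depth_tolerance`` is
    logged, not fatal.  Returns {id(node) -> age}; node ``age``
    attributes are also set (leaves at 0).
    """
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if not calibration.clade <= leaves:
        raise ValueError("calibration clade labels missing from tree")
    # MRCA via leaf sets (dendropy's mrca() deroots unrooted trees,
    # which would silently change node depths)
    mrca = None
    best = len(leaves) + 1
    for nd in tree.postorder_node_iter():
        below = {l.taxon.label for l in nd.leaf_iter()}
        if calibration.clade <= below and len(below) < best:
            mrca, best = nd, len(below)
    if mrca is None:
        raise ValueError("calibration clade has no MRCA in this tree")

    depths = _root_to_tip_depths(tree)
    spread = (max(depths) - min(depths)) / max(max(depths), 1e-300)
    if spread > depth_tolerance:
        log.warning(
            "root-to-tip depths vary by %.1f%%; tree is not clock-like, "
            "calibrated ages are approximate", 100 * spread,
        )

    heights = {id(nd): _mean_height(nd) for nd in tree.preorder_node_iter()}
    cal_height = heights[id(mrca)]
    if cal_height <= 0:
        raise ValueError("calibration node has zero height; cannot scale")
    factor = calibration.age_mya / cal_height
    ages = {}
    for nd in tree.preorder_node_iter():
        age = heights[id(nd)] * factor
        nd.age = age
        ages[id(nd)] = age
    return ages


def _mean_height(node: dendropy.Node) -> float:
    """Mean path length from ``node`` down to its descendant leaves."""
    total, count = _sum_paths(node)
    return total / count


def _sum_paths(node: dendropy.Node) -> tuple[float, int]:
    if node.is_leaf():
        return 0.0, 1
    total, count = 0.0, 0
    for child in node.child_nodes():
        t, c = _sum_paths(child)
        edge = child.edge.length or 0.0
        total += t + c * edge
        count += c
    return total, count


def _root_to_tip_depths(tree: dendropy.Tree) -> list[float]:
    depths = []
    for leaf in tree.leaf_node_iter():
        d, nd = 0.0, leaf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        depths.append(d)
    return depths


# ---------------------------------------------------------------------------
# ordination of the RF matrix
# ---------------------------------------------------------------------------

def rf_mds(rf: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical multidimensional scaling of an RF distance matrix.

    Embeds windows in k dimensions so Euclidean distances approximate
    the RF distances (double-centered Gram eigendecomposition, axes
    ordered by eigenvalue; negative eigenvalues truncated to zero).
    """
    D = np.asarray(rf, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)[None, :]
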