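"""Distance-based phylogeny: p-distances with pairwise deletion,
neighbor-joining with deterministic tie-breaking, bootstrap supports on
bipartitions, and anchored subfamily assignment.

The p-distance between two aligned sequences is the proportion of
mismatched sites among the sites where both carry a non-gap residue
(pairwise deletion).  Neighbor-joining follows the Saitou-Nei Q-criterion;
on additive distance matrices it recovers the generating topology and path
lengths exactly.  Bootstrap support of an internal edge is the fraction of
column-resampled replicate trees containing the same bipartition of the
taxon set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "SubfamilyAssignment",
    "p_distance",
    "nj_tree",
    "bootstrap_support",
    "assign_subfamilies",
]

logger = logging.getLogger(__name__)

GAP_CHARS = {"-", "."}


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


@dataclass
class TreeNode:
    """Node of a (rooted representation of an) unrooted tree."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored in a rooted representation plus edge supports.

    ``supports`` maps a bipartition (frozenset of tip names on the child
    side of an internal edge) to a support fraction in [0, 1].
    """

    root: TreeNode
    supports: dict[frozenset[str], float] = field(default_factory=dict)

    @property
    def tip_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each keyed by its smaller (or
        lexicographically first, on ties) side."""
        all_tips = frozenset(self.tip_names)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                below = below | walk(child)
                side = frozenset(leaf.name for leaf in child.leaves())
                out.add(_canonical_side(side, all_tips))
            return below

        walk(self.root)
        # trivial bipartitions (single tip / all-but-one) carry no signal
        return {
            b for b in out if 1 < len(b) < len(all_tips) - 1
        }

    def clade_sides(self) -> set[frozenset[str]]:
        """Both sides of every non-trivial edge (candidate clades of the
        unrooted tree)."""
        all_tips = frozenset(self.tip_names)
        sides: set[frozenset[str]] = set()
        for b in self.bipartitions():
            sides.add(b)
            sides.add(all_tips - b)
        return sides

    def newick(self) -> str:
        """Newick string with supports as internal-node labels."""
        all_tips = frozenset(self.tip_names)

        def fmt(node: TreeNode, length: float | None) -> str:
            if node.is_leaf():
                s = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                side = frozenset(leaf.name for leaf in node.leaves())
                sup = self.supports.get(_canonical_side(side, all_tips))
                s = f"({inner}){'' if sup is None else f'{sup:.3f}'}"
            if length is not None:
                s += f":{length:.6f}"
            return s

        return fmt(self.root, None) + ";"


def _canonical_side(side: frozenset[str], all_tips: frozenset[str]) -> frozenset[str]:
    other = all_tips - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: tuple(sorted(s)))


@dataclass
class SubfamilyAssignment:
    labels: dict[str, str]  # tip -> subfamily label or "orphan"
    clade_size: dict[str, int]
    clade_support: dict[str, float]
    mixed: dict[str, list[str]] = field(default_factory=dict)


def p_distance(aligned: dict[str, str] | list[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gap sites."""
    items = list(aligned.items()) if isinstance(aligned, dict) else list(aligned)
    if len(items) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(items[0][1])
    if any(len(s) != length for _, s in items):
        raise ValueError("aligned sequences have unequal lengths")
    labels = [lab for lab, _ in items]
    arr = np.array([list(s) for _, s in items])
    nongap = ~np.isin(arr, list(GAP_CHARS))
    n = len(items)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = nongap[i] & nongap[j]
            nv = int(valid.sum())
            if nv == 0:
                raise ValueError(
                    f"no shared non-gap sites between {labels[i]!r} and {labels[j]!r}"
                )
            mism = int((arr[i][valid] != arr[j][valid]).sum())
            d[i, j] = d[j, i] = mism / nv
    return DistanceMatrix(labels=labels, d=d)


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining (Saitou-Nei) with lexicographic tie-breaking on the
    index pair minimising Q.  Negative branch lengths are clamped to zero
    (and logged)."""
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in matrix.labels]
    d = matrix.d.astype(float).copy()
    active = list(range(n))

    def clamp(x: float, a: str, b: str) -> float:
        if x < 0:
            logger.debug("clamped negative NJ branch length %.3g on %s-%s", x, a, b)
            return 0.0
        return x

    while len(active) > 2:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li = clamp(li, str(i), str(j))
        lj = clamp(lj, str(j), str(i))
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # reuse slot i for the new cluster
        for k in active:
            if k in (i, j):
                continue
            dk = (d[i, k] + d[j, k] - d[i, j]) / 2
            d[i, k] = d[k, i] = dk
        nodes[i] = parent
        active.remove(j)

    i, j = active
    root = nodes[i]
    length = clamp(d[i, j], str(i), str(j))
    if root.is_leaf():
        root, i, j = nodes[j], j, i
        if root.is_leaf():  # n == 2 cannot happen (guarded above)
            raise AssertionError
    root.children.append((nodes[j], length))
    return PhyloTree(root=root)


def bootstrap_support(
    aligned: dict[str, str],
    n_replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree from the full alignment with bootstrap supports attached.

    Columns are resampled with replacement; support of an edge is the
    fraction of replicate NJ trees containing the same bipartition.
    Deterministic for a fixed seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels = list(aligned)
    seqs = [aligned[lab] for lab in labels]
    length = len(seqs[0])
    tree = nj_tree(p_distance(aligned))
    target = tree.bipartitions()
    counts = {b: 0 for b in target}
    rng = np.random.default_rng(seed)
    arr = np.array([list(s) for s in seqs])
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        sample = arr[:, cols]
        rep_aligned = {lab: "".join(sample[k]) for k, lab in enumerate(labels)}
        rep_tree = nj_tree(p_distance(rep_aligned))
        for b in rep_tree.bipartitions():
            if b in counts:
                counts[b] += 1
    tree.supports = {b: counts[b] / n_replicates for b in target}
    return tree


def assign_subfamilies(
    tree: PhyloTree,
    reference_labels: dict[str, str],
    min_support: float = 0.5,
) -> SubfamilyAssignment:
    """Assign each unlabeled tip the label of the smallest supported clade
    containing it whose reference tips carry exactly one label.

    Candidate clades are both sides of every internal edge.  A tip inside
    supported clades that all mix reference labels gets "orphan" and the
    mixed labels are reported as diagnostics.  When the tree carries no
    supports every edge is treated as supported.
    """
    if not reference_labels:
        raise ValueError("need at least one labeled reference tip")
    all_tips = frozenset(tree.tip_names)
    sides = sorted(tree.clade_sides(), key=lambda s: (len(s), tuple(sorted(s))))

    def support_of(side: frozenset[str]) -> float:
        if not tree.supports:
            return 1.0
        return tree.supports.get(_canonical_side(side, all_tips), 0.0)

    labels: dict[str, str] = {}
    clade_size: dict[str, int] = {}
    clade_support: dict[str, float] = {}
    mixed: dict[str, list[str]] = {}
    for tip in sorted(all_tips):
        if tip in reference_labels:
            labels[tip] = reference_labels[tip]
            continue
        assigned = False
        for side in sides:
            if tip not in side:
                continue
            refs = {reference_labels[t] for t in side if t in reference_labels}
            if not refs:
                continue
            sup = support_of(side)
            if sup < min_support:
                continue
            if len(refs) == 1:
                labels[tip] = next(iter(refs))
                clade_size[tip] = len(side)
                clade_support[tip] = sup
                assigned = True
                break
            mixed.setdefault(tip, sorted(refs))
        if not assigned:
            labels[tip] = "orphan"
    return SubfamilyAssignment(
        labels=labels, clade_size=clade_size, clade_support=clade_support, mixed=mixed
    )
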