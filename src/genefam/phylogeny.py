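"""Distance-based phylogeny: p-distances, neighbor-joining, bootstrap,
and class assignment of unlabeled leaves from labeled reference leaves.

The tree inference follows the Saitou-Nei agglomeration exactly, with two
pinned conventions so that results are bit-reproducible: ties in the
Q-criterion are broken toward the lowest index pair, and negative branch
lengths (a known NJ artifact) are clamped to zero with the deficit
transferred to the sibling branch.  Bootstrap supports are the percentage
of column-resampled replicate trees containing each internal bipartition
of the full-data tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over named taxa."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValidationError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix must have zero diagonal")
        if np.any(v < 0):
            raise ValidationError("distances must be non-negative")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.values[i, j])


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; the NJ root is a trifurcation."""

    name: str | None = None
    length: float = 0.0  # length of the edge to the parent
    support: float | None = None  # bootstrap %, internal nodes only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())


@dataclass
class PhyloTree:
    """Unrooted tree (rooted representation at a basal trifurcation)."""

    root: TreeNode
    resolved: bool = True  # False when input distances were degenerate

    @property
    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial splits as {side, complement} pairs of leaf-name sets."""
        all_leaves = self.leaf_names
        splits = set()

        def walk(node: TreeNode) -> None:
            for child in node.children:
                side = child.leaf_names()
                other = all_leaves - side
                if len(side) >= 2 and len(other) >= 2:
                    splits.add(frozenset({side, other}))
                walk(child)

        walk(self.root)
        return splits

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            sup = "" if node.support is None else f"{node.support:.0f}"
            return f"({inner}){sup}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


# ---------------------------------------------------------------------------
# Distances


def p_distance_matrix(msa: dict[str, str]) -> DistanceMatrix:
    """Pairwise p-distances under complete deletion.

    Columns containing a gap in *any* sequence are removed globally; the
    distance is then the fraction of mismatching retained columns.
    """
    taxa = list(msa)
    if len(taxa) < 2:
        raise ValidationError("need at least two sequences")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValidationError("aligned sequences must have equal length")
    arr = np.array([list(msa[t]) for t in taxa])
    keep = ~np.any(arr == "-", axis=0)
    if not keep.any():
        raise ValidationError("complete deletion removed every column")
    arr = arr[:, keep]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(arr[i] != arr[j])
    return DistanceMatrix(taxa=taxa, values=d)


# ---------------------------------------------------------------------------
# Neighbor-joining


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor-joining with deterministic tie-breaking.

    The minimal-Q pair with the lowest (i, j) index order is joined at
    each step; pendant lengths use the standard three-point formulas and
    negative lengths are clamped to zero with the amount transferred to
    the sibling edge.  The final three lineages join at an unrooted
    trifurcation.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValidationError("neighbor-joining needs at least three taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    d = dm.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or q[a, b] < q[best] - 1e-12:
                    best = (a, b)
        a, b = best
        dab = sub[a, b]
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        # clamp negatives, transferring length to the sibling edge
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        i, j = active[a], active[b]
        child_a, child_b = nodes[i], nodes[j]
        child_a.length, child_b.length = la, lb
        new = TreeNode(children=[child_a, child_b])
        nodes.append(new)
        k = len(nodes) - 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for c in active:
            if c in (i, j):
                continue
            d[k, c] = d[c, k] = 0.5 * (d[i, c] + d[j, c] - dab)
        active = [c for c in active if c not in (i, j)] + [k]

    # join the last three lineages at a trifurcating root
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    for node, length in zip(root.children, (li, lj, lk)):
        node.length = max(length, 0.0)
    return PhyloTree(root=root)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_supports(
    msa: dict[str, str], n_replicates: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Alignment columns are resampled with replacement ``n_replicates``
    times; the support of each internal bipartition of the full-data tree
    is the percentage of replicate trees that contain it.  Reproducible
    for a fixed seed.  Degenerate alignments (all sequences identical)
    return an arbitrary resolution flagged ``resolved=False``.
    """
    rng = np.random.default_rng(seed)
    full_dm = p_distance_matrix(msa)
    tree = nj_tree(full_dm)
    if np.allclose(full_dm.values, 0.0):
        tree.resolved = False
    target = tree.bipartitions()
    counts = {split: 0 for split in target}
    taxa = list(msa)
    arr = np.array([list(msa[t]) for t in taxa])
    n_cols = arr.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        sample = arr[:, cols]
        rep_msa = {t: "".join(sample[i]) for i, t in enumerate(taxa)}
        try:
            rep_tree = nj_tree(p_distance_matrix(rep_msa))
        except ValidationError:  # all columns gapped in this resample
            continue
        rep_splits = rep_tree.bipartitions()
        for split in target:
            if split in rep_splits:
                counts[split] += 1

    def annotate(node: TreeNode) -> None:
        for child in node.children:
            side = child.leaf_names()
            other = tree.leaf_names - side
            if len(side) >= 2 and len(other) >= 2:
                split = frozenset({side, other})
                child.support = 100.0 * counts[split] / n_replicates
            annotate(child)

    annotate(tree.root)
    return tree


# ---------------------------------------------------------------------------
# Class assignment


def assign_classes(
    tree: PhyloTree, reference_labels: dict[str, str]
) -> dict[str, str]:
    """Assign each unlabeled leaf the class of its smallest unanimous clade.

    For a query leaf, every tree edge defines a leaf set containing the
    query; these sets are scanned from smallest to largest and the first
    size at which any labeled reference appears decides: if all labels
    seen at that size agree the query gets that class, otherwise (mixed
    clade, or equidistant conflicting clades) ``"unclassified"``.
    """
    if not reference_labels:
        raise ValidationError("no labeled reference leaves supplied")
    leaves = tree.leaf_names
    missing = set(reference_labels) - leaves
    if missing:
        raise ValidationError(f"reference id(s) not in tree: {sorted(missing)}")

    # leaf sets on the child side of every edge, plus their complements
    sides: list[frozenset[str]] = []

    def walk(node: TreeNode) -> None:
        for child in node.children:
            side = child.leaf_names()
            sides.append(side)
            sides.append(leaves - side)
            walk(child)

    walk(tree.root)

    assignments: dict[str, str] = {}
    for query in sorted(leaves - set(reference_labels)):
        by_size: dict[int, list[frozenset[str]]] = {}
        for s in sides:
            if query in s:
                by_size.setdefault(len(s), []).append(s)
        assignments[query] = "unclassified"
        for size in sorted(by_size):
            labels: set[str] = set()
            for clade in by_size[size]:
                labels |= {
                    reference_labels[m] for m in clade if m in reference_labels
                }
            if labels:
                if len(labels) == 1:
                    assignments[query] = labels.pop()
                break
    return assignments


def class_report(assignments: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": k, "assigned_class": v} for k, v in sorted(assignments.items())]
    )
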