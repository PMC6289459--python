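"""Alignment summarisation: consensus, NJ-sorted rows, difference matrix.

This automates the spreadsheet workflow a primer designer would otherwise do
by hand: build a consensus of the aligned target segments, order the rows by
a neighbor-joining tree so related taxa sit together, and render a matrix
showing only the positions where each row departs from the consensus. The
tree exists solely to order rows for readability — no support values, no
model-corrected distances.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .iupac import GAP, IUPAC_SETS, code_for
from .refpanel import Alignment

__all__ = [
    "DistanceMatrix",
    "Tree",
    "TreeNode",
    "DifferenceMatrix",
    "consensus",
    "p_distance_matrix",
    "neighbor_joining",
    "difference_matrix",
]


def consensus(a: Alignment) -> str:
    """Per-column majority character; ties become the covering IUPAC code.

    Gaps are ignored in the counts; an all-gap column yields ``-``. Ties
    among ambiguity codes resolve to the code covering the union of the tied
    characters' base sets.
    """
    if len(a) == 0:
        raise ValueError("empty alignment")
    out = []
    for j in range(a.length):
        counts = Counter(c for c in a.column(j) if c != GAP)
        if not counts:
            out.append(GAP)
            continue
        top = max(counts.values())
        tied = sorted(c for c, n in counts.items() if n == top)
        if len(tied) == 1:
            out.append(tied[0])
        else:
            union: set[str] = set()
            for c in tied:
                union |= IUPAC_SETS[c]
            out.append(code_for(union))
    return "".join(out)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")


def p_distance_matrix(a: Alignment) -> DistanceMatrix:
    """Pairwise proportion of differing columns between alignment rows.

    Columns where either row carries a gap or an ambiguity code are skipped;
    a pair with zero comparable columns gets distance 0 with a warning.
    """
    if len(a) < 2:
        raise ValueError("need at least 2 rows")
    labels = a.ids
    n = len(labels)
    d = np.zeros((n, n))
    rows = [a.rows[l] for l in labels]
    for i in range(n):
        for j in range(i + 1, n):
            comparable = diffs = 0
            for x, y in zip(rows[i], rows[j]):
                if x in "ACGT" and y in "ACGT":
                    comparable += 1
                    diffs += x != y
            if comparable == 0:
                warnings.warn(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}; "
                    "distance set to 0"
                )
                dist = 0.0
            else:
                dist = diffs / comparable
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d)


@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    min_index: int = 0  # smallest original leaf index under this node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def newick_part(self) -> str:
        if self.is_leaf:
            return self.label or ""
        inner = ",".join(f"{c.newick_part()}:{l:.6f}" for c, l in self.children)
        return f"({inner})"


@dataclass
class Tree:
    """Unrooted NJ tree, stored rooted at the final join for serialization."""

    root: TreeNode
    labels: list[str]
    negative_branches_clamped: bool = False

    def to_newick(self) -> str:
        return self.root.newick_part() + ";"

    def leaf_order(self) -> list[str]:
        """Deterministic row order: depth-first from the last join, children
        visited by smallest contained original leaf index."""
        order: list[str] = []

        def visit(node: TreeNode) -> None:
            if node.is_leaf:
                order.append(node.label)  # type: ignore[arg-type]
                return
            for child, _ in sorted(node.children, key=lambda cl: cl[0].min_index):
                visit(child)

        visit(self.root)
        return order


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with a deterministic tie-break.

    At each step the pair minimising the Q-criterion is joined; among equal Q
    values the lexicographically smallest label pair wins. Negative
    branch-length estimates are clamped to 0 and flagged on the tree.
    ``n == 2`` returns the trivial two-leaf tree by convention; ``n < 2`` is
    an error.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    nodes = [
        TreeNode(label=lab, min_index=i) for i, lab in enumerate(dm.labels)
    ]
    # pair_label: for the tie-break, the sorted (label_i, label_j) tuple
    labels = list(dm.labels)
    d = dm.d.astype(float).copy()
    active = list(range(n))

    if n == 2:
        half = clamp(d[0, 1] / 2)
        root = TreeNode(children=[(nodes[0], half), (nodes[1], half)], min_index=0)
        return Tree(root, labels, clamped)

    while len(active) > 2:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[i, j]
        li = clamp(dij / 2 + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(dij - (dij / 2 + (r[i] - r[j]) / (2 * (m - 2))))
        new = TreeNode(
            children=[(nodes[i], li), (nodes[j], lj)],
            min_index=min(nodes[i].min_index, nodes[j].min_index),
        )
        # distances from the new node to every other active node
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (d[i, k] + d[j, k] - dij) / 2
        nodes[i] = new
        labels[i] = min(labels[i], labels[j])  # representative for tie-breaks
        active.remove(j)

    i, j = active
    final = clamp(d[i, j])
    # attach the two remaining subtrees at the last-joined node
    root = TreeNode(
        children=[(nodes[i], final / 2), (nodes[j], final / 2)],
        min_index=min(nodes[i].min_index, nodes[j].min_index),
    )
    return Tree(root, list(dm.labels), clamped)


@dataclass
class DifferenceMatrix:
    """Consensus-anchored difference view of an alignment.

    Row 0 is the consensus; data rows appear in tree leaf order with ``.``
    wherever the row agrees with the consensus and the observed character
    elsewhere.
    """

    consensus: str
    order: list[str]
    cells: list[str]  # one dotted string per ordered row

    def to_tsv(self) -> str:
        lines = ["consensus\t" + "\t".join(self.consensus)]
        for rid, row in zip(self.order, self.cells):
            lines.append(rid + "\t" + "\t".join(row))
        return "\n".join(lines) + "\n"


def difference_matrix(a: Alignment, order: list[str]) -> DifferenceMatrix:
    """Render *a* as differences from its consensus, rows in *order*.

    *order* must be a permutation of the alignment's row ids (normally a
    :meth:`Tree.leaf_order`).
    """
    if sorted(order) != sorted(a.ids):
        raise ValueError("order is not a permutation of the alignment row ids")
    cons = consensus(a)
    cells = []
    for rid in order:
        row = a.rows[rid]
        cells.append("".join("." if c == k else c for c, k in zip(row, cons)))
    return DifferenceMatrix(cons, list(order), cells)
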