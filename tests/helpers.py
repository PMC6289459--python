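"""Shared independent oracles and small builders for the test suite."""

import datetime as dt
import itertools
from math import comb

import numpy as np
import pandas as pd

from gofish.detect import CONFIRMED, DetectionMatrix


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the two-sided p-value."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {x: comb(r1, x) * comb(n - r1, c1 - x) / denom for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def detection_matrix_from_bools(values: pd.DataFrame, dates=None, sites=None):
    n = len(values.index)
    dates = dates or [dt.date(2017, 4, 1) + dt.timedelta(days=7 * i) for i in range(n)]
    sites = sites or ["east"] * n
    samples = pd.DataFrame(
        {"sample_id": list(values.index), "date": dates, "site": sites}
    )
    prov = values.map(lambda v: CONFIRMED if v else "negative")
    return DetectionMatrix(values, prov, samples)


def splits(tree) -> set:
    """Nontrivial bipartition halves of an unrooted tree."""
    leaves = frozenset(tree.labels)
    out = set()

    def visit(node):
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset()
        for child, _ in node.children:
            sub = visit(child)
            if 1 < len(sub) < len(leaves) - 1:
                out.add(min(sub, leaves - sub, key=sorted))
            below |= sub
        return below

    visit(tree.root)
    return out


ALL_QUARTETS = [
    (("t0", "t1"), ("t2", "t3")),
    (("t0", "t2"), ("t1", "t3")),
    (("t0", "t3"), ("t1", "t2")),
]


def quartet_distances(topology, lengths):
    """Path-length matrix for a 4-taxon tree with pendant edges a-d and an
    internal edge, under the given sister-pair topology."""
    a, b, c, d, e = lengths
    dd = {
        ("A", "B"): a + b,
        ("A", "C"): a + e + c,
        ("A", "D"): a + e + d,
        ("B", "C"): b + e + c,
        ("B", "D"): b + e + d,
        ("C", "D"): c + d,
    }
    (p, q), (r, s) = topology
    relabel = {p: "A", q: "B", r: "C", s: "D"}
    labels = sorted(relabel)
    m = np.zeros((4, 4))
    for i, j in itertools.combinations(range(4), 2):
        x, y = sorted((relabel[labels[i]], relabel[labels[j]]))
        m[i, j] = m[j, i] = dd[(x, y)]
    return labels, m


def least_squares_topology(labels, d):
    """Brute-force oracle: least-squares edge fit over all 3 quartet
    topologies; returns the best topology's sister pairs."""
    best = None
    pairs = list(itertools.combinations(range(4), 2))
    for topo in ALL_QUARTETS:
        (p, q), (r, s) = topo
        relabel = {p: 0, q: 1, r: 2, s: 3}
        rows, rhs = [], []
        for i, j in pairs:
            role_i, role_j = relabel[labels[i]], relabel[labels[j]]
            row = [0.0] * 5
            row[role_i] = 1.0
            row[role_j] = 1.0
            if {role_i, role_j} not in ({0, 1}, {2, 3}):
                row[4] = 1.0
            rows.append(row)
            rhs.append(d[i, j])
        arr = np.array(rows)
        sol, *_ = np.linalg.lstsq(arr, np.array(rhs), rcond=None)
        resid = float(np.sum((arr @ sol - np.array(rhs)) ** 2))
        if best is None or resid < best[0]:
            best = (resid, topo)
    return frozenset(frozenset(p) for p in best[1])


def five_taxon_tree_distances(rng):
    """Random additive 5-taxon distances from a random binary join order."""
    import random

    labels = [f"t{i}" for i in range(5)]
    r = random.Random(int(rng.integers(1 << 30)))
    edges = []
    parts = [[l] for l in labels]
    while len(parts) > 1:
        i, j = sorted(r.sample(range(len(parts)), 2))
        left, right = parts[i], parts[j]
        edges.append((set(left), r.uniform(0.05, 0.4)))
        edges.append((set(right), r.uniform(0.05, 0.4)))
        parts[i] = left + right
        del parts[j]
    m = np.zeros((5, 5))
    for a, b in itertools.combinations(range(5), 2):
        total = sum(
            ln for leafset, ln in edges if (labels[a] in leafset) != (labels[b] in leafset)
        )
        m[a, b] = m[b, a] = total
    true_splits = {
        min(frozenset(ls), frozenset(labels) - frozenset(ls), key=sorted)
        for ls, _ in edges
        if 1 < len(ls) < 4
    }
    return labels, m, true_splits
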