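"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: exhaustive enumeration
where the package uses dynamic programming or agglomeration, so agreement is
evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices


def brute_force_alignment_score(a: str, b: str, matrix_name: str = "BLOSUM62",
                                gap_open: float = 10.0,
                                gap_extend: float = 0.5) -> float:
    """Maximum global alignment score by enumerating every gapped pairing.

    Affine convention matching the implementation under test: a gap run of
    length L costs gap_open + gap_extend * (L - 1).
    """
    mat = substitution_matrices.load(matrix_name)

    def score(cols) -> float:
        total = 0.0
        prev_gap_a = prev_gap_b = False
        for x, y in cols:
            if x == "-":
                total -= gap_extend if prev_gap_a else gap_open
            elif y == "-":
                total -= gap_extend if prev_gap_b else gap_open
            else:
                total += mat[x, y]
            prev_gap_a, prev_gap_b = x == "-", y == "-"
        return total

    best = -math.inf

    def rec(i: int, j: int, cols: list) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score(cols))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best


# ---------------------------------------------------------------------------
# exhaustive unrooted-topology enumeration and minimum evolution

def enumerate_unrooted_topologies(labels: list[str]):
    """All unrooted binary topologies on the labels, as adjacency dicts
    (leaves are label strings, internal nodes are ints)."""
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")

    def clone(adj):
        return {k: set(v) for k, v in adj.items()}

    base = {0: {labels[0], labels[1], labels[2]},
            labels[0]: {0}, labels[1]: {0}, labels[2]: {0}}
    trees = [base]
    next_internal = 1
    for leaf in labels[3:]:
        grown = []
        for adj in trees:
            edges = {frozenset((u, v)) for u in adj for v in adj[u]}
            for edge in edges:
                u, v = tuple(edge)
                new = clone(adj)
                w = next_internal
                new[u].discard(v)
                new[v].discard(u)
                new[w] = {u, v, leaf}
                new[u].add(w)
                new[v].add(w)
                new[leaf] = {w}
                grown.append(new)
        next_internal += 1
        trees = grown
    return trees


def _tree_paths(adj, labels):
    """Pairwise edge-index paths: incidence matrix over the tree's edges."""
    edges = sorted({frozenset((u, v)) for u in adj for v in adj[u]},
                   key=lambda e: sorted(map(str, e)))
    edge_index = {e: i for i, e in enumerate(edges)}
    pairs = list(itertools.combinations(sorted(labels), 2))
    A = np.zeros((len(pairs), len(edges)))
    for row, (x, y) in enumerate(pairs):
        # DFS path from x to y
        stack = [(x, [])]
        seen = {x}
        while stack:
            node, path = stack.pop()
            if node == y:
                for e in path:
                    A[row, edge_index[e]] = 1.0
                break
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, path + [frozenset((node, nxt))]))
    return A, pairs


def minimum_evolution_topology(labels, dmat: np.ndarray):
    """Exhaustive minimum-evolution search: OLS branch lengths on every
    topology, minimal total tree length wins. Returns its bipartitions."""
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    best = None
    for adj in enumerate_unrooted_topologies(labels):
        A, pairs = _tree_paths(adj, labels)
        d_vec = np.array([dmat[index[x], index[y]] for x, y in pairs])
        lengths, *_ = np.linalg.lstsq(A, d_vec, rcond=None)
        total = lengths.sum()
        if best is None or total < best[0] - 1e-12:
            best = (total, adj)
    return tree_bipartitions(best[1], labels)


def tree_bipartitions(adj, labels) -> set[frozenset]:
    """Non-trivial bipartitions of an adjacency tree, canonicalized as the
    side not containing the alphabetically first label."""
    ref = min(labels)
    out = set()
    internal_edges = [frozenset((u, v)) for u in adj for v in adj[u]
                      if isinstance(u, int) and isinstance(v, int)]
    for edge in set(internal_edges):
        u, v = tuple(edge)
        # leaves on v's side when the edge is cut
        stack, seen, side = [v], {u, v}, set()
        while stack:
            node = stack.pop()
            if not isinstance(node, int):
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if 1 < len(side) < len(labels) - 1:
            canon = frozenset(side) if ref not in side else \
                frozenset(set(labels) - side)
            out.add(canon)
    return out


def random_additive_matrix(labels, rng: np.random.Generator):
    """Distance matrix additive on a random binary topology with positive
    branch lengths; returns (matrix, bipartitions of the generating tree)."""
    labels = list(labels)
    topologies = enumerate_unrooted_topologies(labels)
    adj = topologies[rng.integers(0, len(topologies))]
    A, pairs = _tree_paths(adj, labels)
    lengths = rng.uniform(0.2, 2.0, size=A.shape[1])
    d_vec = A @ lengths
    n = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    d = np.zeros((n, n))
    for (x, y), val in zip(pairs, d_vec):
        d[index[x], index[y]] = d[index[y], index[x]] = val
    return d, tree_bipartitions(adj, labels)


def permutation_test_p(group_a, group_b) -> float:
    """Exhaustive two-sided permutation p-value on the mean difference."""
    pooled = list(group_a) + list(group_b)
    n_a = len(group_a)
    observed = abs(np.mean(group_a) - np.mean(group_b))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        sel = set(idx)
        a = [pooled[i] for i in sel]
        b = [pooled[i] for i in range(len(pooled)) if i not in sel]
        count += abs(np.mean(a) - np.mean(b)) >= observed - 1e-12
        total += 1
    return count / total
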