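"""Independent reference implementations used as oracles.

These are deliberately naive and share no code with the package: a
textbook O(n*m*(n+m)) Smith-Waterman dynamic program that scans every gap
length explicitly, and a random-tree generator with a path-sum patristic
matrix for checking neighbor joining by round trip.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def blosum62_with_x() -> dict[tuple[str, str], float]:
    """Plain-dict BLOSUM62 with X scoring 0 against everything (the package's
    alphabet convention, re-derived here from the published matrix)."""
    m = substitution_matrices.load("BLOSUM62")
    letters = AMINO_ACIDS + "X"
    table = {}
    for a in letters:
        for b in letters:
            table[(a, b)] = 0.0 if "X" in (a, b) else float(m[a, b])
    return table


def sw_score_naive(
    a: str, b: str, score: dict[tuple[str, str], float], gap_open: int, gap_extend: int
) -> int:
    """Optimal local alignment score with affine gaps, w(g) = open + g*extend,
    by explicit enumeration of every gap length at every cell."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = H[i - 1, j - 1] + score[(a[i - 1], b[j - 1])]
            if i > 1:
                # gap in b (skip k residues of a): candidates H[i-k, j] - w(k)
                ks = np.arange(1, i)
                best = max(best, (H[i - ks, j] - gap_open - ks * gap_extend).max())
            if j > 1:
                ks = np.arange(1, j)
                best = max(best, (H[i, j - ks] - gap_open - ks * gap_extend).max())
            H[i, j] = max(0.0, best)
    return int(round(H.max()))


def random_unrooted_tree(
    rng: np.random.Generator, n_leaves: int, length_range: tuple[float, float] = (0.1, 2.0)
):
    """Random unrooted binary tree as an edge list [(u, v, length), ...].

    Leaves are named L0..L{n-1}; internal nodes get negative integer ids.
    Built by splitting a uniformly chosen edge for each new leaf.
    """
    assert n_leaves >= 3

    def blen() -> float:
        return float(rng.uniform(*length_range))

    next_internal = [-1]

    def new_internal() -> int:
        next_internal[0] -= 1
        return next_internal[0] + 1

    center = new_internal()
    edges = [[center, "L0", blen()], [center, "L1", blen()], [center, "L2", blen()]]
    for i in range(3, n_leaves):
        k = int(rng.integers(len(edges)))
        u, v, length = edges.pop(k)
        mid = new_internal()
        split = float(rng.uniform(0.25, 0.75))
        edges.append([u, mid, length * split])
        edges.append([mid, v, length * (1 - split)])
        edges.append([mid, f"L{i}", blen()])
    return [tuple(e) for e in edges]


def patristic_matrix(edges, leaves: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix by breadth-first search on the edge list."""
    adj: dict = {}
    for u, v, length in edges:
        adj.setdefault(u, []).append((v, length))
        adj.setdefault(v, []).append((u, length))
    n = len(leaves)
    out = np.zeros((n, n))
    for i, leaf in enumerate(leaves):
        dist = {leaf: 0.0}
        queue = [leaf]
        while queue:
            node = queue.pop()
            for nbr, length in adj[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + length
                    queue.append(nbr)
        # fill one triangle and mirror: summation order differs per BFS root,
        # so exact symmetry must be imposed, not assumed
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = dist[leaves[j]]
    return out
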