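"""Independent brute-force oracles used to validate the implementation.

These are deliberately naive re-derivations (plain-Python dynamic
programming, path-length tree distances) kept free of any package
internals beyond the scoring matrix itself.
"""

from __future__ import annotations


def gotoh_local_score(q: str, s: str, matrix, gap_open: int = 11,
                      gap_extend: int = 1) -> int:
    """Optimal affine-gap local alignment score by exhaustive DP.

    Gap of length L costs ``gap_open + (L-1)*gap_extend``; switching gap
    direction re-pays the opening penalty.
    """
    NEG = float("-inf")
    n, m = len(q), len(s)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = matrix[q[i - 1], s[j - 1]]
            M[i][j] = sub + max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1],
                                Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend,
                           Iy[i - 1][j] - gap_open)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend,
                           Ix[i][j - 1] - gap_open)
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return int(best)


def tree_path_distances(tree, labels):
    """Leaf-to-leaf path-length matrix of a Bio.Phylo tree, by label order."""
    import numpy as np

    n = len(labels)
    term = {t.name: t for t in tree.get_terminals()}
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree.distance(term[labels[i]], term[labels[j]])
    return d
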