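"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths:
alignment costs are minimised by exhaustive enumeration of all monotone
warp paths, and k-NN distances come from full pairwise distance matrices.
"""

import math

import numpy as np
from scipy.spatial.distance import cdist


def exhaustive_alignment_cost(X, Y, C):
    """Minimum penalised path cost over ALL monotone paths (DFS enumeration).

    Step costs: diagonal moves cost MED of the target cell; vertical and
    horizontal moves cost (1 + C) * MED of the target cell. The start cell
    always contributes its own MED.
    """
    M = cdist(np.atleast_2d(X), np.atleast_2d(Y))
    a, b = M.shape
    best = [math.inf]

    def dfs(i, j, cost):
        if i == a - 1 and j == b - 1:
            if cost < best[0]:
                best[0] = cost
            return
        if i + 1 < a and j + 1 < b:
            dfs(i + 1, j + 1, cost + M[i + 1, j + 1])
        if i + 1 < a:
            dfs(i + 1, j, cost + (1 + C) * M[i + 1, j])
        if j + 1 < b:
            dfs(i, j + 1, cost + (1 + C) * M[i, j + 1])

    dfs(0, 0, M[0, 0])
    return best[0]


def kth_neighbor_distances(values, k):
    """Distance of each 1-D point to its k-th nearest neighbour, by full
    pairwise |x_i - x_j| matrices."""
    v = np.asarray(values, dtype=float)
    D = np.abs(v[:, None] - v[None, :])
    D.sort(axis=1)
    return D[:, k]  # column 0 is the self-distance


def path_cells(path):
    return set(path.pairs if hasattr(path, "pairs") else path)
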