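"""Independent brute-force oracles shared between test modules."""

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")


def overlap_affine_score(a: str, b: str, open_cost=11.0, ext=1.0) -> float:
    """Affine-gap overlap (free end gaps) alignment score by exhaustive DP.

    Kept independent of the package's aligner: plain three-state Gotoh
    recursion over the full score matrix.
    """
    n, m = len(a), len(b)
    NEG = -1e12
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b, consuming a
    Y = np.full((n + 1, m + 1), NEG)  # gap in a, consuming b
    M[0, 0] = 0.0
    X[1:, 0] = 0.0  # free leading end gaps
    Y[0, 1:] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_cost, X[i - 1, j] - ext,
                          Y[i - 1, j] - open_cost)
            Y[i, j] = max(M[i, j - 1] - open_cost, Y[i, j - 1] - ext,
                          X[i, j - 1] - open_cost)
    # free trailing end gaps: best over last row and last column
    return float(max(M[n, :].max(), X[n, :].max(), Y[n, :].max(),
                     M[:, m].max(), X[:, m].max(), Y[:, m].max()))
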