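"""Independent brute-force oracles used only by the tests.

Deliberately written in a different style from the package implementation:
plain dictionaries and explicit per-cell loops, no vectorization, no shared
code.  Returns the optimal score only.
"""

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def brute_force_global_score(a: str, b: str, gap_open=-11.0, gap_extend=-1.0) -> float:
    """Affine-gap global alignment score by explicit three-state DP."""
    n, m = len(a), len(b)
    M = {(0, 0): 0.0}
    X = {}
    Y = {}
    for i in range(1, n + 1):
        X[(i, 0)] = gap_open + (i - 1) * gap_extend
        M[(i, 0)] = NEG
        Y[(i, 0)] = NEG
    for j in range(1, m + 1):
        Y[(0, j)] = gap_open + (j - 1) * gap_extend
        M[(0, j)] = NEG
        X[(0, j)] = NEG
    X[(0, 0)] = NEG
    Y[(0, 0)] = NEG
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[(i, j)] = max(M[(i - 1, j - 1)], X[(i - 1, j - 1)], Y[(i - 1, j - 1)]) + s
            X[(i, j)] = max(
                M[(i - 1, j)] + gap_open,
                X[(i - 1, j)] + gap_extend,
                Y[(i - 1, j)] + gap_open,
            )
            Y[(i, j)] = max(
                M[(i, j - 1)] + gap_open,
                X[(i, j - 1)] + gap_open,
                Y[(i, j - 1)] + gap_extend,
            )
    return max(M[(n, m)], X[(n, m)], Y[(n, m)])
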