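"""Independent DTW oracle: exhaustive enumeration of warping paths.

A warping path between series of lengths n and m is a sequence of index
pairs from (0,0) to (n-1,m-1) moving by (1,0), (0,1) or (1,1).  The
oracle enumerates every path and takes the minimum sum of squared
pointwise differences — no dynamic programming, so it is an independent
check of the DP implementation.
"""

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def all_paths(n: int, m: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """Every monotone warping path for lengths (n, m), as index tuples."""
    if n == 1 and m == 1:
        return (((0, 0),),)
    paths = []
    if n > 1 and m > 1:
        paths += [p + ((n - 1, m - 1),) for p in all_paths(n - 1, m - 1)]
    if n > 1:
        paths += [p + ((n - 1, m - 1),) for p in all_paths(n - 1, m)]
    if m > 1:
        paths += [p + ((n - 1, m - 1),) for p in all_paths(n, m - 1)]
    return tuple(paths)


def dtw_bruteforce(a, b) -> float:
    """Minimal sqrt(sum of squared diffs) over all enumerated paths."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = min(
        sum((a[i] - b[j]) ** 2 for i, j in path) for path in all_paths(a.size, b.size)
    )
    return float(np.sqrt(best))


def dtw_bruteforce_batch(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise brute-force DTW for all rows of A against all rows of B."""
    n, m = A.shape[1], B.shape[1]
    costs = np.full((A.shape[0], B.shape[0]), np.inf)
    for path in all_paths(n, m):
        c = np.zeros((A.shape[0], B.shape[0]))
        for i, j in path:
            c += (A[:, i, None] - B[None, :, j]) ** 2
        np.minimum(costs, c, out=costs)
    return np.sqrt(costs)
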