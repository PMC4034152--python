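"""Exhaustive greedy Ward implementation, independent of scipy.

At every step the within-cluster sum of squares increase is recomputed from
scratch for every candidate pair; heights follow the distance-unit
convention height = sqrt(2 * delta_SSE).  Used as the oracle for small
instances.
"""

import numpy as np


def _sse(points):
    centroid = points.mean(axis=0)
    return float(((points - centroid) ** 2).sum())


def ward_merge_sequence(X):
    """Return [(leafset_a, leafset_b, height), ...] for observations X.

    Tie-break: the candidate pair with the lexicographically smallest
    (min cluster index, max cluster index) at equal height.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                union = clusters[a] + clusters[b]
                delta = _sse(X[union]) - _sse(X[clusters[a]]) - _sse(X[clusters[b]])
                h = np.sqrt(2.0 * delta)
                if best is None or h < best[0] - 1e-12:
                    best = (h, a, b)
        h, a, b = best
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), h))
        clusters[a] = clusters[a] + clusters.pop(b)
    return merges


def scipy_merge_sequence(tree):
    """The same representation extracted from a fitted LinkageTree."""
    n = tree.n_leaves
    sets = [frozenset([i]) for i in range(n)]
    merges = []
    for a, b, h, _ in tree.Z:
        sa, sb = sets[int(a)], sets[int(b)]
        merges.append((sa, sb, float(h)))
        sets.append(sa | sb)
    return merges
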