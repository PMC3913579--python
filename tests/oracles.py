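"""Independent brute-force oracles shared across test modules."""

import itertools

import numpy as np
from scipy.spatial.distance import pdist, squareform


def brute_force_average_linkage(X: np.ndarray) -> list[frozenset]:
    """Exhaustive UPGMA on rows of X: merge order as sets of leaf indices.

    At each step the pair of clusters with the smallest unweighted average
    of all cross-cluster Euclidean leaf distances is merged.
    """
    D = squareform(pdist(X))
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(X))}
    merges = []
    next_id = len(X)
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
            if best is None or d < best[0]:
                best = (d, i, j)
        _, i, j = best
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        merges.append(frozenset(clusters[next_id]))
        next_id += 1
    return merges


def linkage_merge_sets(Z: np.ndarray, n: int) -> list[frozenset]:
    """Convert a scipy linkage matrix into the same merge-order representation."""
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (i, j, _, _) in enumerate(Z):
        members[n + k] = members[int(i)] | members[int(j)]
        out.append(members[n + k])
    return out
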