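"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the package's own code paths: union-find over all
pairs for tag clustering, explicit loops plus ``statistics.median`` for the
median-of-ratios factors.
"""

import itertools
import math
import statistics


def brute_force_partition(positions, merge_distance):
    """Transitive-closure merge: O(n^2) union-find over position pairs."""
    positions = list(positions)
    parent = list(range(len(positions)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(positions)), 2):
        if abs(positions[i] - positions[j]) < merge_distance:
            parent[find(i)] = find(j)
    groups = {}
    for i, p in enumerate(positions):
        groups.setdefault(find(i), []).append(p)
    return sorted(tuple(sorted(g)) for g in groups.values())


def oracle_size_factors(counts):
    """Median-of-ratios computed independently (loops, statistics.median)."""
    rows = [
        i for i in counts.index if all(counts.loc[i, c] > 0 for c in counts.columns)
    ]
    gms = {
        i: math.exp(
            sum(math.log(counts.loc[i, c]) for c in counts.columns) / counts.shape[1]
        )
        for i in rows
    }
    return {
        c: statistics.median(counts.loc[i, c] / gms[i] for i in rows)
        for c in counts.columns
    }
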