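"""Shared test utilities: table builders and brute-force oracles.

The oracles here are deliberately naive (double loops, union-find,
exhaustive enumeration) and independent of the library code paths they
check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from clonetrace.measurement import ObservedCellTable


def make_table(sets, generations=None) -> ObservedCellTable:
    """Observed-cell table from a list of barcode sets (one cell per set)."""
    n = len(sets)
    gens = generations if generations is not None else [0] * n
    return ObservedCellTable(
        data=pd.DataFrame(
            {
                "cell_id": np.arange(n, dtype=np.int64),
                "generation": np.asarray(gens, dtype=np.int64),
                "barcodes": [frozenset(s) for s in sets],
            }
        )
    )


def random_sets(rng, n, universe, max_size=4, allow_empty=False):
    """Random barcode sets for clustering oracles."""
    out = []
    for _ in range(n):
        lo = 0 if allow_empty else 1
        size = rng.integers(lo, max_size + 1)
        out.append(frozenset(rng.choice(universe, size=size, replace=False).tolist()))
    return out


def overlap_components(sets) -> list[int]:
    """Union-find connected components of the shares-a-barcode graph."""
    n = len(sets)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if sets[i] & sets[j]:
                parent[find(i)] = find(j)
    return [find(i) for i in range(n)]


def partitions_equal(labels_a, labels_b) -> bool:
    """True iff two labelings induce the same partition."""
    blocks_a = {}
    blocks_b = {}
    for i, (a, b) in enumerate(zip(labels_a, labels_b)):
        blocks_a.setdefault(a, set()).add(i)
        blocks_b.setdefault(b, set()).add(i)
    return set(map(frozenset, blocks_a.values())) == set(map(frozenset, blocks_b.values()))


def brute_force_pair_counts(labels_true, labels_pred):
    """O(n^2) pair classification for partition-agreement indices."""
    n = len(labels_true)
    tp = fp = fn = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_t = labels_true[i] == labels_true[j]
            same_p = labels_pred[i] == labels_pred[j]
            tp += same_t and same_p
            fp += same_p and not same_t
            fn += same_t and not same_p
    return tp, fp, fn
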