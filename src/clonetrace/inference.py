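"""Lineage reconstruction by clustering observed barcode sets.

All observed cells from all snapshots are pooled; pairwise Jaccard
dissimilarity d(X, Y) = 1 - |X∩Y| / |X∪Y| between their barcode sets feeds a
single-linkage agglomerative dendrogram, which is then cut under one of
three threshold strategies:

``any_overlap``
    threshold just below 1 — cells join a lineage if connected by a chain of
    pairs sharing at least one barcode (maximal matching of cells).
``min_d``
    threshold 0 — only cells with identical observed sets merge, realizing
    the maximal cluster count the dendrogram supports (the cell count being
    the proxy for the maximum possible number of lineages).
``true_count``
    the cut whose flat-cluster count is closest to the (externally known)
    true lineage count.

Single linkage is the only linkage consistent with the ``any_overlap``
semantics: its flat clusters at height h are exactly the connected
components of the graph with edges {d <= h}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .measurement import ObservedCellTable

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "LineageAssignment",
    "jaccard_dissimilarity",
    "build_distance_matrix",
    "single_linkage_dendrogram",
    "cut_any_overlap",
    "cut_min",
    "cut_by_target_count",
    "infer_lineages",
    "write_assignment_csv",
]

STRATEGIES = ("any_overlap", "min_d", "true_count")

# d values are rationals bounded away from 1 by >= 1/|X∪Y|, so any threshold
# in (1 - 1/n_barcodes, 1) realizes "any non-zero overlap"; a fixed epsilon
# safely below machine-representable gaps is used.
ANY_OVERLAP_THRESHOLD = 1.0 - 1e-9


def jaccard_dissimilarity(X: frozenset[int] | set[int], Y: frozenset[int] | set[int]) -> float:
    """1 - |X∩Y| / |X∪Y|; undefined (raises) when both sets are empty."""
    union = len(X | Y)
    if union == 0:
        raise ValueError("Jaccard dissimilarity undefined for two empty sets")
    return 1.0 - len(X & Y) / union


@dataclass
class DistanceMatrix:
    """Pairwise dissimilarities over the labeled observed cells.

    ``cells`` carries the (generation, cell_id) index in the deterministic
    order used by ``values``; cells with empty observed sets are excluded and
    counted in ``n_excluded``.
    """

    values: np.ndarray
    cells: pd.DataFrame
    sets: list[frozenset[int]]
    n_excluded: int


@dataclass
class Dendrogram:
    """Single-linkage merge list in scipy linkage layout (n-1 rows)."""

    merges: np.ndarray  # scipy Z matrix; empty (0, 4) for a single cell
    n_items: int

    def merge_heights(self) -> np.ndarray:
        return self.merges[:, 2] if self.merges.size else np.empty(0)

    def flat_clusters(self, threshold: float) -> np.ndarray:
        """Cluster labels (1-based) merging all pairs with d <= threshold."""
        if self.n_items == 1:
            return np.ones(1, dtype=np.int32)
        return fcluster(self.merges, t=threshold, criterion="distance")

    def cluster_count(self, threshold: float) -> int:
        if self.n_items == 1:
            return 1
        return self.n_items - int(np.sum(self.merge_heights() <= threshold))


@dataclass
class LineageAssignment:
    """Inferred cluster id per clustered cell, with provenance.

    ``labels`` aligns with ``cells``; cells whose observed set was empty are
    not present (their count is ``n_excluded`` — the "unassigned" sentinel is
    their absence from this table).
    """

    labels: np.ndarray
    cells: pd.DataFrame
    strategy: str
    threshold: float
    n_excluded: int

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)


def build_distance_matrix(table: ObservedCellTable) -> DistanceMatrix:
    """Jaccard distance matrix over all labeled cells, pooled across snapshots.

    Computed through a sparse cell × barcode incidence product so that very
    large barcode universes (B up to 1e6) stay tractable.
    """
    df = table.data
    nonempty = df["barcodes"].map(len) > 0
    n_excluded = int((~nonempty).sum())
    sub = df.loc[nonempty, ["generation", "cell_id", "barcodes"]]
    sub = sub.sort_values(["generation", "cell_id"], kind="mergesort").reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError("no labeled cells: every observed set is empty")

    sets = [frozenset(s) for s in sub["barcodes"]]
    vocab: dict[int, int] = {}
    rows, cols = [], []
    for i, s in enumerate(sets):
        for b in s:
            j = vocab.setdefault(b, len(vocab))
            rows.append(i)
            cols.append(j)
    n = len(sets)
    A = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(n, len(vocab)),
    )
    inter = np.asarray((A @ A.T).todense(), dtype=np.float64)
    sizes = np.asarray([len(s) for s in sets], dtype=np.float64)
    union = sizes[:, None] + sizes[None, :] - inter
    D = 1.0 - inter / union
    np.fill_diagonal(D, 0.0)
    # numerical guard: Jaccard values are exact rationals, clip fp noise
    np.clip(D, 0.0, 1.0, out=D)
    return DistanceMatrix(
        values=D,
        cells=sub[["generation", "cell_id"]].copy(),
        sets=sets,
        n_excluded=n_excluded,
    )


def single_linkage_dendrogram(matrix: DistanceMatrix) -> Dendrogram:
    n = matrix.values.shape[0]
    if n == 1:
        return Dendrogram(merges=np.empty((0, 4)), n_items=1)
    condensed = squareform(matrix.values, checks=False)
    Z = linkage(condensed, method="single")
    return Dendrogram(merges=Z, n_items=n)


def _assignment(dendrogram, matrix, strategy, threshold) -> LineageAssignment:
    return LineageAssignment(
        labels=dendrogram.flat_clusters(threshold),
        cells=matrix.cells,
        strategy=strategy,
        threshold=threshold,
        n_excluded=matrix.n_excluded,
    )


def cut_any_overlap(dendrogram: Dendrogram, matrix: DistanceMatrix) -> LineageAssignment:
    """Merge any cells connected by a chain of pairs sharing >= 1 barcode."""
    return _assignment(dendrogram, matrix, "any_overlap", ANY_OVERLAP_THRESHOLD)


def cut_min(dendrogram: Dendrogram, matrix: DistanceMatrix) -> LineageAssignment:
    """Merge only cells whose observed sets are identical (d = 0)."""
    return _assignment(dendrogram, matrix, "min_d", 0.0)


def cut_by_target_count(
    dendrogram: Dendrogram, matrix: DistanceMatrix, target: int
) -> LineageAssignment:
    """Cut at the merge height whose flat-cluster count is closest to ``target``.

    Candidate thresholds are 0 plus the dendrogram's merge heights; ties are
    broken toward the smaller threshold (more clusters).
    """
    if target < 1:
        raise ValueError("target lineage count must be >= 1")
    candidates = np.unique(np.concatenate(([0.0], dendrogram.merge_heights())))
    best_t, best_err = 0.0, None
    for t in candidates:  # ascending: strict improvement keeps the smaller t
        err = abs(dendrogram.cluster_count(t) - target)
        if best_err is None or err < best_err:
            best_t, best_err = float(t), err
    return _assignment(dendrogram, matrix, "true_count", best_t)


def infer_lineages(
    table: ObservedCellTable, strategy: str, truth_count: int | None = None
) -> LineageAssignment:
    """End-to-end reconstruction: distance matrix → dendrogram → threshold cut."""
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
    if strategy == "true_count" and truth_count is None:
        raise ValueError("strategy 'true_count' requires truth_count")
    matrix = build_distance_matrix(table)
    dend = single_linkage_dendrogram(matrix)
    if strategy == "any_overlap":
        return cut_any_overlap(dend, matrix)
    if strategy == "min_d":
        return cut_min(dend, matrix)
    return cut_by_target_count(dend, matrix, truth_count)


def write_assignment_csv(assignment: LineageAssignment, path) -> None:
    out = assignment.cells.copy()
    out["cluster_id"] = assignment.labels
    out["strategy"] = assignment.strategy
    out["threshold"] = assignment.threshold
    out[["cell_id", "generation", "cluster_id", "strategy", "threshold"]].to_csv(
        path, index=False
    )
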