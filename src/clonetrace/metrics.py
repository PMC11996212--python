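"""Scoring inferred lineages against ground truth; MOI estimators.

The headline score is the accurate-lineage ratio: the fraction of true
propagated lineages whose observed cells are recovered as an inferred
cluster *exactly* (set equality, no extra cells).  Cell-level partition
scores (Fowlkes–Mallows, v-measure) are reported alongside, since the two
families can rank experimental designs differently.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.metrics.cluster import contingency_matrix

from .inference import LineageAssignment
from .measurement import ObservedCellTable
from .propagation import Trajectory

__all__ = [
    "TruthPartition",
    "AccuracyReport",
    "labeled_fraction_theory",
    "estimate_moi",
    "true_propagated_lineages",
    "accurate_lineage_ratio",
    "fowlkes_mallows",
    "v_measure",
    "score_assignment",
]


def labeled_fraction_theory(moi: float) -> float:
    """Poisson-model fraction of labeled (>= 1 barcode) cells: 1 - e^{-M}."""
    if moi < 0:
        raise ValueError("moi must be >= 0")
    return -math.expm1(-moi)


def estimate_moi(labeled_fraction: float) -> float:
    """Invert the Poisson labeled fraction: M = -ln(1 - f)."""
    if not 0.0 <= labeled_fraction < 1.0:
        raise ValueError("labeled fraction must lie in [0, 1) for a finite MOI")
    return -math.log1p(-labeled_fraction)


@dataclass
class TruthPartition:
    """Ground-truth lineage blocks over the observed labeled cells.

    ``blocks`` maps founder_id → set of (generation, cell_id) keys of that
    founder's observed cells with non-empty post-dropout sets.  ``n_lineages``
    counts every labeled founder with at least one cell in some analyzed
    snapshot — including founders whose every descendant lost all barcodes to
    dropout (true propagated lineages that cannot be recovered).
    """

    blocks: dict[int, frozenset[tuple[int, int]]]
    n_lineages: int


def true_propagated_lineages(
    trajectory: Trajectory, table: ObservedCellTable
) -> TruthPartition:
    labeled_founders = {
        f for f, s in trajectory.founder_table.items() if len(s) > 0
    }
    present: set[int] = set()
    cell_to_founder: dict[tuple[int, int], int] = {}
    for gen, snap in trajectory.snapshots.items():
        for cid, fid in zip(snap["cell_id"], snap["founder_id"]):
            fid = int(fid)
            if fid in labeled_founders:
                present.add(fid)
                cell_to_founder[(int(gen), int(cid))] = fid

    blocks: dict[int, set[tuple[int, int]]] = {}
    df = table.data
    nonempty = df["barcodes"].map(len) > 0
    for gen, cid in zip(df.loc[nonempty, "generation"], df.loc[nonempty, "cell_id"]):
        key = (int(gen), int(cid))
        fid = cell_to_founder.get(key)
        if fid is not None:
            blocks.setdefault(fid, set()).add(key)
    return TruthPartition(
        blocks={f: frozenset(c) for f, c in blocks.items()},
        n_lineages=len(present & labeled_founders),
    )


def _clusters_as_sets(assignment: LineageAssignment) -> list[frozenset[tuple[int, int]]]:
    keys = list(zip(assignment.cells["generation"].astype(int),
                    assignment.cells["cell_id"].astype(int)))
    by_label: dict[int, set] = {}
    for key, lab in zip(keys, assignment.labels):
        by_label.setdefault(int(lab), set()).add(key)
    return [frozenset(c) for c in by_label.values()]


def accurate_lineage_ratio(
    assignment: LineageAssignment, truth: TruthPartition, relaxed: bool = False
) -> float:
    """Fraction of true propagated lineages recovered as an inferred cluster.

    Default rule: a lineage counts iff some cluster equals its block exactly.
    ``relaxed=True`` instead accepts a cluster that contains a strict majority
    of the block and whose majority is the block (a looser matching rule,
    off by default).
    """
    if truth.n_lineages == 0:
        return 0.0
    clusters = _clusters_as_sets(assignment)
    cluster_set = set(clusters)
    accurate = 0
    for block in truth.blocks.values():
        if not block:
            continue
        if not relaxed:
            accurate += block in cluster_set
        else:
            for cl in clusters:
                inter = len(cl & block)
                if inter > len(block) / 2 and inter > len(cl) / 2:
                    accurate += 1
                    break
    return accurate / truth.n_lineages


def _pair_counts(labels_true, labels_pred):
    c = contingency_matrix(labels_true, labels_pred)
    tp_fp = int((c.sum(axis=0) * (c.sum(axis=0) - 1) // 2).sum())
    tp_fn = int((c.sum(axis=1) * (c.sum(axis=1) - 1) // 2).sum())
    tp = int((c * (c - 1) // 2).sum())
    return tp, tp_fp, tp_fn


def fowlkes_mallows(labels_true, labels_pred) -> float:
    """Pair-counting agreement TP / sqrt((TP+FP)(TP+FN)) between partitions.

    When neither partition contains a within-cluster pair (both all
    singletons) the index is defined as 1; if exactly one side has no pairs
    the index is undefined and an error is raised.
    """
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape:
        raise ValueError("partitions must cover the same cells")
    tp, tp_fp, tp_fn = _pair_counts(labels_true, labels_pred)
    if tp_fp == 0 and tp_fn == 0:
        return 1.0
    if tp_fp == 0 or tp_fn == 0:
        raise ValueError("Fowlkes-Mallows undefined: one partition has no pairs")
    return tp / math.sqrt(tp_fp * tp_fn)


def v_measure(labels_true, labels_pred) -> float:
    """Entropy-based harmonic mean of homogeneity and completeness (beta=1)."""
    return float(skmetrics.v_measure_score(labels_true, labels_pred))


@dataclass
class AccuracyReport:
    """Flat summary of one reconstruction run against ground truth."""

    accurate_lineage_ratio: float
    accurate_lineage_count: int
    accurate_per_initial_cell: float
    labeled_fraction_empirical: float
    fm_index: float
    v_measure: float
    n_true_lineages: int
    n_inferred_clusters: int
    n_excluded_empty_cells: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _truth_labels(assignment: LineageAssignment, truth: TruthPartition) -> np.ndarray:
    """Ground-truth founder label per clustered cell, aligned with assignment."""
    key_to_founder = {}
    for fid, block in truth.blocks.items():
        for key in block:
            key_to_founder[key] = fid
    keys = zip(assignment.cells["generation"].astype(int),
               assignment.cells["cell_id"].astype(int))
    labels = []
    for key in keys:
        if key not in key_to_founder:
            raise ValueError(
                "assignment and truth cover different cells; rebuild the truth "
                "partition from the same observed table"
            )
        labels.append(key_to_founder[key])
    return np.asarray(labels)


def score_assignment(
    assignment: LineageAssignment,
    truth: TruthPartition,
    table: ObservedCellTable,
    n_initial_cells: int,
) -> AccuracyReport:
    ratio = accurate_lineage_ratio(assignment, truth)
    count = round(ratio * truth.n_lineages)
    labels_true = _truth_labels(assignment, truth)
    try:
        fm = fowlkes_mallows(labels_true, assignment.labels)
    except ValueError:
        fm = float("nan")
    return AccuracyReport(
        accurate_lineage_ratio=ratio,
        accurate_lineage_count=count,
        accurate_per_initial_cell=count / n_initial_cells,
        labeled_fraction_empirical=table.labeled_fraction(),
        fm_index=fm,
        v_measure=v_measure(labels_true, assignment.labels),
        n_true_lineages=truth.n_lineages,
        n_inferred_clusters=assignment.n_clusters,
        n_excluded_empty_cells=assignment.n_excluded,
    )
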