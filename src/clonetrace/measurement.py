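"""Dropout-corrupted observation of snapshots, and the adjusted distributions.

Each integrated barcode of each observed cell is read with probability
``1 - p_drop``, independently across barcodes, cells and snapshots (a fresh
random stream per snapshot).  Under uniform dropout the observed set size
stays binomial with ``p_in -> p_in * (1 - p_drop)``, so dropout simply
rescales the effective MOI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .propagation import Trajectory

__all__ = [
    "ObservationConfig",
    "ObservedCellTable",
    "apply_dropout",
    "observe_trajectory",
    "observed_set_size_pmf",
    "cells_per_barcode_pmf",
    "mean_barcodes_in_labeled",
    "mean_barcodes_in_labeled_poisson",
]


@dataclass(frozen=True)
class ObservationConfig:
    dropout_probability: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_probability <= 1.0:
            raise ValueError("dropout probability must lie in [0, 1]")


@dataclass
class ObservedCellTable:
    """Aggregated (cell, snapshot, observed barcode set) records.

    ``data`` has columns ``cell_id``, ``generation`` and ``barcodes`` (a
    frozenset of type ids, possibly empty).  This is the interchange format
    the inference module consumes, so externally produced barcode calls can
    be clustered by writing the same CSV dialect.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"cell_id", "generation", "barcodes"} - set(self.data.columns)
        if missing:
            raise ValueError(f"observed table missing columns: {sorted(missing)}")

    @property
    def n_labeled(self) -> int:
        return int((self.data["barcodes"].map(len) > 0).sum())

    def labeled_fraction(self) -> float:
        if len(self.data) == 0:
            raise ValueError("empty observed table")
        return self.n_labeled / len(self.data)

    def write_csv(self, path) -> None:
        out = self.data.copy()
        out["barcodes"] = out["barcodes"].map(
            lambda s: ";".join(str(b) for b in sorted(s))
        )
        out[["cell_id", "generation", "barcodes"]].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ObservedCellTable":
        df = pd.read_csv(path, dtype={"cell_id": np.int64, "generation": np.int64},
                         keep_default_na=False)
        df["barcodes"] = [
            frozenset(int(b) for b in str(s).split(";") if b != "")
            for s in df["barcodes"]
        ]
        return cls(data=df)


def apply_dropout(
    snapshot: pd.DataFrame,
    founder_table: dict[int, frozenset[int]],
    p_drop: float,
    rng: np.random.Generator,
    generation: int = 0,
) -> ObservedCellTable:
    """Observe one snapshot: retain each integrated barcode w.p. ``1-p_drop``."""
    if not 0.0 <= p_drop <= 1.0:
        raise ValueError("dropout probability must lie in [0, 1]")
    observed = []
    for cell_id, founder_id in zip(snapshot["cell_id"], snapshot["founder_id"]):
        full = founder_table[int(founder_id)]
        if p_drop == 0.0 or not full:
            kept = frozenset(full)
        elif p_drop == 1.0:
            kept = frozenset()
        else:
            arr = np.fromiter(full, dtype=np.int64)
            kept = frozenset(arr[rng.random(arr.size) >= p_drop].tolist())
        observed.append(kept)
    return ObservedCellTable(
        data=pd.DataFrame(
            {
                "cell_id": snapshot["cell_id"].to_numpy(dtype=np.int64),
                "generation": np.full(len(snapshot), generation, dtype=np.int64),
                "barcodes": observed,
            }
        )
    )


def observe_trajectory(
    trajectory: Trajectory, p_drop: float, rng: np.random.Generator
) -> ObservedCellTable:
    """Observe every snapshot and aggregate into one table.

    Dropout noise is drawn from an independent substream per snapshot, so a
    cell re-observed at a later passage sees fresh reading errors.
    """
    gens = sorted(trajectory.snapshots)
    streams = rng.spawn(len(gens))
    parts = [
        apply_dropout(trajectory.snapshots[g], trajectory.founder_table,
                      p_drop, stream, generation=g).data
        for g, stream in zip(gens, streams)
    ]
    return ObservedCellTable(data=pd.concat(parts, ignore_index=True))


def observed_set_size_pmf(B: int, p_in: float, p_drop: float, L) -> np.ndarray | float:
    """Post-dropout set-size pmf: Binomial(B, p_in * (1 - p_drop)) at ``L``."""
    if not 0.0 <= p_drop <= 1.0:
        raise ValueError("dropout probability must lie in [0, 1]")
    from .integration import set_size_pmf

    return set_size_pmf(B, p_in * (1.0 - p_drop), L)


def cells_per_barcode_pmf(S: int, p_in: float, p_drop: float, C) -> np.ndarray | float:
    """Pmf of the number of cells observed to carry a given barcode.

    Binomial(S, p_in (1 - p_drop)); its mean (S/B)·M_eff grows linearly with
    the MOI, which is what drives barcode-set overlap between lineages.
    """
    if not 0.0 <= p_drop <= 1.0:
        raise ValueError("dropout probability must lie in [0, 1]")
    C_arr = np.asarray(C)
    out = stats.binom.pmf(C_arr, S, p_in * (1.0 - p_drop))
    out = np.where((C_arr >= 0) & (C_arr <= S), out, 0.0)
    return float(out) if np.isscalar(C) else out


def mean_barcodes_in_labeled(B: int, p_in: float, p_drop: float) -> float:
    """Mean observed set size among labeled cells (non-empty observed set).

    B q / [1 - (1-q)^B] with q = p_in (1 - p_drop): the unconditional mean
    renormalized by the labeled fraction.
    """
    q = p_in * (1.0 - p_drop)
    if q <= 0:
        raise ValueError("effective insertion probability is zero; mean undefined")
    denom = -np.expm1(B * np.log1p(-q)) if q < 1 else 1.0
    return B * q / denom


def mean_barcodes_in_labeled_poisson(moi_effective: float) -> float:
    """Poisson-limit mean set size among labeled cells: M / (1 - e^{-M})."""
    if moi_effective <= 0:
        raise ValueError("effective MOI must be > 0")
    return moi_effective / -np.expm1(-moi_effective)
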