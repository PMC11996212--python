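"""Neutral propagation of a barcoded cohort with periodic passaging.

Cells double each generation and the culture is periodically subsampled back
to a target size ("passaging"), which stochastically extinguishes lineages.
Dynamics are strictly neutral: no step ever reads a cell's barcode set.  Two
engines are provided — synchronized doubling followed by uniform subsampling
(the default) and a Wright-Fisher multinomial-resampling variant; both keep
the population at the target size after every passaging event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LiveCell",
    "PropagationConfig",
    "Trajectory",
    "propagate",
    "passage",
    "surviving_lineages",
    "write_trajectory_csv",
]

DEFAULT_GENERATIONS = 15
DEFAULT_SNAPSHOTS = (0, 5, 10, 15)


@dataclass(frozen=True)
class LiveCell:
    cell_id: int
    founder_id: int


@dataclass(frozen=True)
class PropagationConfig:
    """Parameters of the growth/passaging schedule.

    ``target_size`` is the post-passage population size; ``passaging_period``
    is the number of generations between passages (1 = passage after every
    doubling).  Snapshots are nondestructive reads of the population at the
    listed generations; ``snapshot_fraction`` optionally subsamples the cells
    that are recorded (1.0 = record everyone).
    """

    generations: int = DEFAULT_GENERATIONS
    snapshot_generations: tuple[int, ...] = DEFAULT_SNAPSHOTS
    passaging_period: int = 1
    target_size: int | None = None  # None: initial cohort size
    engine: str = "synchronized_doubling"
    snapshot_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        snaps = tuple(sorted(set(self.snapshot_generations)))
        if snaps and (snaps[0] < 0 or snaps[-1] > self.generations):
            raise ValueError("snapshot generations must lie within [0, generations]")
        object.__setattr__(self, "snapshot_generations", snaps)
        if self.passaging_period < 1:
            raise ValueError("passaging_period must be >= 1")
        if self.target_size is not None and self.target_size < 1:
            raise ValueError("target_size must be >= 1")
        if self.engine not in ("synchronized_doubling", "wright_fisher"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if not 0.0 < self.snapshot_fraction <= 1.0:
            raise ValueError("snapshot_fraction must lie in (0, 1]")


@dataclass
class Trajectory:
    """Time-indexed snapshots plus the founder → barcode-set lookup.

    Each snapshot is a DataFrame with columns ``cell_id`` and ``founder_id``;
    a cell's barcode set is, by inheritance, its founder's set.
    """

    snapshots: dict[int, pd.DataFrame] = field(default_factory=dict)
    founder_table: dict[int, frozenset[int]] = field(default_factory=dict)

    def snapshot_cells(self, generation: int) -> list[LiveCell]:
        df = self.snapshots[generation]
        return [
            LiveCell(int(c), int(f))
            for c, f in zip(df["cell_id"], df["founder_id"])
        ]


def _record(snapshots, gen, cell_ids, founder_ids, fraction, rng):
    if fraction < 1.0:
        k = max(1, int(round(fraction * cell_ids.size)))
        idx = np.sort(rng.choice(cell_ids.size, size=k, replace=False))
        cell_ids, founder_ids = cell_ids[idx], founder_ids[idx]
    snapshots[gen] = pd.DataFrame(
        {"cell_id": cell_ids.copy(), "founder_id": founder_ids.copy()}
    )


def propagate(cohort, config: PropagationConfig, rng: np.random.Generator) -> Trajectory:
    """Run the growth/passaging schedule and record the configured snapshots.

    The generation-``t`` snapshot is the population after ``t`` completed
    generation steps (so every snapshot of the default schedule has exactly
    ``target_size`` cells).  Daughters of the cell with id ``i`` receive ids
    ``2i`` and ``2i+1``, making trajectories bit-reproducible given a seed.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    target = config.target_size if config.target_size is not None else len(cohort)

    cell_ids = np.arange(len(cohort), dtype=np.int64)
    founder_ids = np.array([c.founder_id for c in cohort], dtype=np.int64)
    traj = Trajectory(
        founder_table={c.founder_id: c.integrated_set for c in cohort}
    )
    snaps = set(config.snapshot_generations)

    for gen in range(config.generations):
        if gen in snaps:
            _record(traj.snapshots, gen, cell_ids, founder_ids,
                    config.snapshot_fraction, rng)
        if config.engine == "synchronized_doubling":
            n = cell_ids.size
            new_ids = np.empty(2 * n, dtype=np.int64)
            new_ids[0::2] = 2 * cell_ids
            new_ids[1::2] = 2 * cell_ids + 1
            cell_ids = new_ids
            founder_ids = np.repeat(founder_ids, 2)
            # passage only once the culture has outgrown the target
            if (gen + 1) % config.passaging_period == 0 and cell_ids.size > target:
                cell_ids, founder_ids = _passage_arrays(
                    cell_ids, founder_ids, target, rng
                )
        else:  # wright_fisher
            parents = rng.integers(0, cell_ids.size, size=target)
            founder_ids = founder_ids[parents]
            cell_ids = np.arange(target, dtype=np.int64)
    if config.generations in snaps:
        _record(traj.snapshots, config.generations, cell_ids, founder_ids,
                config.snapshot_fraction, rng)
    return traj


def _passage_arrays(cell_ids, founder_ids, target_size, rng):
    if target_size > cell_ids.size:
        raise ValueError(
            f"target_size {target_size} exceeds population {cell_ids.size}"
        )
    if target_size == 0:
        logger.warning("passage to size 0: all lineages lost")
        return cell_ids[:0], founder_ids[:0]
    keep = np.sort(rng.choice(cell_ids.size, size=target_size, replace=False))
    return cell_ids[keep], founder_ids[keep]


def passage(population: pd.DataFrame, target_size: int, rng: np.random.Generator) -> pd.DataFrame:
    """Uniform subsample without replacement down to ``target_size`` cells."""
    if target_size < 0:
        raise ValueError("target_size must be >= 0")
    cell_ids = population["cell_id"].to_numpy(dtype=np.int64)
    founder_ids = population["founder_id"].to_numpy(dtype=np.int64)
    cell_ids, founder_ids = _passage_arrays(cell_ids, founder_ids, target_size, rng)
    return pd.DataFrame({"cell_id": cell_ids, "founder_id": founder_ids})


def surviving_lineages(trajectory: Trajectory) -> set[int]:
    """Founder ids with at least one cell in some snapshot after generation 0."""
    out: set[int] = set()
    for gen, df in trajectory.snapshots.items():
        if gen > 0:
            out.update(int(f) for f in df["founder_id"].unique())
    return out


def write_trajectory_csv(trajectory: Trajectory, path) -> None:
    frames = []
    for gen in sorted(trajectory.snapshots):
        df = trajectory.snapshots[gen].copy()
        df.insert(0, "generation", gen)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
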