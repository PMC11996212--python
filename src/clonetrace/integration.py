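"""Barcode integration: seeding founder cells with barcode sets.

A pool of ``B`` distinct barcode types is delivered (e.g. by a lentiviral
library) to ``S`` cells.  In the uniform model every (cell, type) pair
integrates independently with probability ``p_in``, so the per-cell set size
is Binomial(B, p_in) and, for small ``p_in`` and large ``B``, approximately
Poisson with mean ``M = p_in * B`` — the multiplicity of infection (MOI).
The biased model adds per-cell infection susceptibility (Gamma-mixed Poisson
exposure) and a skewed type-abundance distribution, producing the
over-dispersed set-size distributions reported for real libraries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BarcodePool",
    "FounderCell",
    "integrate_uniform",
    "integrate_biased",
    "set_size_pmf",
    "poisson_set_size_pmf",
    "integration_probability_exact",
    "cohort_to_dataframe",
    "write_cohort_csv",
    "cohort_to_sparse",
]

_ENUM_LIMIT = 20  # exact subset enumeration beyond this is intractable


@dataclass(frozen=True)
class BarcodePool:
    """A library of ``complexity`` distinct barcode types.

    ``weights`` holds per-type relative abundances (summing to 1); ``None``
    denotes the uniform pool, avoiding a dense length-B vector for large
    libraries.
    """

    complexity: int
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.complexity < 1:
            raise ValueError(f"pool complexity must be >= 1, got {self.complexity}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.complexity,):
                raise ValueError("weights length must equal pool complexity")
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
            if abs(w.sum() - 1.0) > 1e-12:
                raise ValueError("weights must sum to 1 within 1e-12")
            object.__setattr__(self, "weights", w)

    @property
    def is_uniform(self) -> bool:
        return self.weights is None or bool(
            np.allclose(self.weights, 1.0 / self.complexity, atol=1e-15)
        )

    @classmethod
    def uniform(cls, complexity: int) -> "BarcodePool":
        return cls(complexity=complexity)

    @classmethod
    def skewed(cls, complexity: int, sigma: float, rng: np.random.Generator) -> "BarcodePool":
        """Pool with log-normally skewed abundances; ``sigma=0`` is uniform."""
        if sigma < 0:
            raise ValueError("abundance skew sigma must be >= 0")
        if sigma == 0:
            return cls(complexity=complexity)
        w = rng.lognormal(mean=0.0, sigma=sigma, size=complexity)
        w /= w.sum()
        return cls(complexity=complexity, weights=w)


@dataclass(frozen=True)
class FounderCell:
    """A cell at generation 0 carrying its integrated barcode-type set.

    The set may be empty (unlabeled cell); such cells are retained in the
    cohort because labeled-fraction accounting includes them.
    """

    founder_id: int
    integrated_set: frozenset[int] = field(default_factory=frozenset)


def _sample_distinct(n_types: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of ``size`` distinct type ids from ``[0, n_types)``.

    Rejection sampling (redraw on collision) keeps the cost O(size) when
    size << n_types, which is the regime for large libraries; a partial
    permutation handles the dense regime.
    """
    if size == 0:
        return np.empty(0, dtype=np.int64)
    if size > n_types:
        raise ValueError("cannot draw more distinct types than the pool holds")
    if 4 * size > n_types:
        return rng.choice(n_types, size=size, replace=False).astype(np.int64)
    while True:
        draw = rng.integers(0, n_types, size=size)
        uniq = np.unique(draw)
        if uniq.size == size:
            return uniq


def integrate_uniform(
    n_cells: int, pool: BarcodePool, p_in: float, rng: np.random.Generator
) -> list[FounderCell]:
    """Seed ``n_cells`` founders; every type integrates independently w.p. ``p_in``.

    Equivalent to drawing the set size L ~ Binomial(B, p_in) and then L
    distinct types uniformly — implemented that way so the cost per cell is
    O(L), not O(B).
    """
    if not pool.is_uniform:
        raise ValueError("integrate_uniform requires a uniform pool; use integrate_biased")
    if not 0.0 <= p_in <= 1.0:
        raise ValueError(f"p_in must lie in [0, 1], got {p_in}")
    B = pool.complexity
    sizes = rng.binomial(B, p_in, size=n_cells)
    return [
        FounderCell(founder_id=i, integrated_set=frozenset(_sample_distinct(B, int(L), rng)))
        for i, L in enumerate(sizes)
    ]


def integrate_biased(
    n_cells: int,
    pool: BarcodePool,
    moi: float,
    susceptibility_dispersion: float,
    rng: np.random.Generator,
) -> list[FounderCell]:
    """Seed founders under non-uniform susceptibility and type abundance.

    Per-cell exposure is ``u_s * moi`` with ``u_s`` drawn from a mean-1 Gamma
    with shape ``susceptibility_dispersion``; the integration-event count is
    Poisson at that exposure and each event picks a type by pool weight.
    The resulting set-size distribution is over-dispersed
    (variance ``M + M^2/shape`` for the event counts) and converges to the
    uniform Poisson model as shape → ∞ with uniform weights.
    """
    if susceptibility_dispersion <= 0:
        raise ValueError("susceptibility_dispersion must be > 0")
    if moi < 0:
        raise ValueError("moi must be >= 0")
    B = pool.complexity
    if np.isinf(susceptibility_dispersion):
        exposure = np.full(n_cells, moi)
    else:
        k = susceptibility_dispersion
        exposure = moi * rng.gamma(shape=k, scale=1.0 / k, size=n_cells)
    counts = rng.poisson(exposure)
    total = int(counts.sum())
    if pool.weights is None:
        events = rng.integers(0, B, size=total)
    else:
        events = rng.choice(B, size=total, p=pool.weights)
    offsets = np.concatenate(([0], np.cumsum(counts)))
    return [
        FounderCell(
            founder_id=i,
            integrated_set=frozenset(np.unique(events[offsets[i] : offsets[i + 1]]).tolist()),
        )
        for i in range(n_cells)
    ]


def set_size_pmf(B: int, p_in: float, L) -> np.ndarray | float:
    """Binomial pmf of the integrated-set size: C(B,L) p_in^L (1-p_in)^(B-L).

    Returns 0 outside ``0 <= L <= B`` (convention, so callers may evaluate on
    arbitrary grids).
    """
    if not 0.0 <= p_in <= 1.0:
        raise ValueError("p_in must lie in [0, 1]")
    L_arr = np.asarray(L)
    out = stats.binom.pmf(L_arr, B, p_in)
    out = np.where((L_arr >= 0) & (L_arr <= B), out, 0.0)
    return float(out) if np.isscalar(L) else out


def poisson_set_size_pmf(moi: float, L) -> np.ndarray | float:
    """Poisson(M) pmf — the large-B, small-p_in limit of the set size."""
    if moi < 0:
        raise ValueError("moi must be >= 0")
    L_arr = np.asarray(L)
    if np.any(L_arr < 0):
        raise ValueError("L must be >= 0")
    out = stats.poisson.pmf(L_arr, moi)
    return float(out) if np.isscalar(L) else out


def integration_probability_exact(per_cell_insertion_probs, L: int) -> float:
    """Exact P(|set| = L) for arbitrary per-type insertion probabilities.

    Sums ∏ p_i ∏ (1−p_j) over all L-combinations of the pool — exponential in
    the pool size, so restricted to pools of at most 20 types.  Serves as the
    enumeration oracle for the sampling routines.
    """
    probs = np.asarray(per_cell_insertion_probs, dtype=float)
    B = probs.size
    if B > _ENUM_LIMIT:
        raise ValueError(f"exact enumeration supports pools of <= {_ENUM_LIMIT} types, got {B}")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("insertion probabilities must lie in [0, 1]")
    if L < 0 or L > B:
        return 0.0
    total = 0.0
    idx = range(B)
    for combo in itertools.combinations(idx, L):
        inside = set(combo)
        total += math.prod(
            probs[i] if i in inside else 1.0 - probs[i] for i in idx
        )
    return total


# ---------------------------------------------------------------------------
# cohort I/O

def cohort_to_dataframe(cohort: list[FounderCell]):
    import pandas as pd

    return pd.DataFrame(
        {
            "cell_id": [c.founder_id for c in cohort],
            "founder_id": [c.founder_id for c in cohort],
            "barcodes": [
                ";".join(str(b) for b in sorted(c.integrated_set)) for c in cohort
            ],
        }
    )


def write_cohort_csv(cohort: list[FounderCell], path) -> None:
    cohort_to_dataframe(cohort).to_csv(path, index=False)


def cohort_to_sparse(cohort: list[FounderCell], complexity: int):
    """Cell × barcode incidence matrix in COO layout (MatrixMarket-writable)."""
    from scipy import sparse

    rows, cols = [], []
    for i, c in enumerate(cohort):
        for b in sorted(c.integrated_set):
            rows.append(i)
            cols.append(b)
    data = np.ones(len(rows), dtype=np.int8)
    return sparse.coo_matrix((data, (rows, cols)), shape=(len(cohort), complexity))
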