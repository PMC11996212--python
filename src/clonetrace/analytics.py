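"""Closed-form analytics of the uniform-integration model.

These formulas describe the two failure modes of barcode-set lineage
reconstruction without simulating anything:

* overlap — with per-barcode cell counts ~ Poisson((S/B) M), the chance that
  no barcode lands in two or more cells is (1 + (S/B) M) exp(-(S/B) M);
* identity collapse — after dropout at rate p, two cells sharing an
  integrated set of size L are read identically with probability
  (2p^2 - 2p + 1)^L - p^{2L}, which Poisson-averages over L to
  exp(-2p(1-p)M) - exp(-(1-p^2)M), a concave function of M peaking at an
  intermediate MOI.

They serve both as user-facing design calculators and as the Monte-Carlo
test oracles for the simulation pipeline.
"""

from __future__ import annotations

import math

from scipy.optimize import minimize_scalar

__all__ = [
    "p_no_overlap",
    "p_identical_given_L",
    "p_identical",
    "min_complexity_bound",
    "p_identical_peak_moi",
    "analytic_summary",
]


def _validate(S=None, B=None, M=None, p_drop=None):
    if S is not None and S < 1:
        raise ValueError("S must be >= 1")
    if B is not None and B < 1:
        raise ValueError("B must be >= 1")
    if M is not None and M < 0:
        raise ValueError("MOI must be >= 0")
    if p_drop is not None and not 0.0 <= p_drop <= 1.0:
        raise ValueError("dropout probability must lie in [0, 1]")


def p_no_overlap(S: float, B: float, M: float) -> float:
    """Probability that no barcode is integrated into two or more cells."""
    _validate(S=S, B=B, M=M)
    x = (S / B) * M
    return (1.0 + x) * math.exp(-x)


def p_identical_given_L(p_drop: float, L: int) -> float:
    """P(two cells with the same integrated L-set read identically | L).

    At L = 0 the expression evaluates to 0: an empty-vs-empty comparison is
    excluded by convention (both cells are unlabeled).
    """
    _validate(p_drop=p_drop)
    if L < 0:
        raise ValueError("L must be >= 0")
    p = p_drop
    return (2 * p * p - 2 * p + 1) ** L - p ** (2 * L)


def p_identical(M: float, p_drop: float) -> float:
    """Poisson average of ``p_identical_given_L`` over L ~ Poisson(M)."""
    _validate(M=M, p_drop=p_drop)
    p = p_drop
    return math.exp(-2 * p * (1 - p) * M) - math.exp(-(1 - p * p) * M)


def min_complexity_bound(S: float, M: float) -> float:
    """Library complexity keeping P(any overlap) below ~1/S: B >~ S^{3/2} M."""
    _validate(S=S, M=M)
    return S ** 1.5 * M


def p_identical_peak_moi(p_drop: float, moi_max: float = 50.0) -> float:
    """MOI maximizing the identical-read probability for a given dropout rate.

    Bracketed scalar maximization on (0, moi_max) with absolute tolerance
    1e-6; raises for p_drop in {0, 1}, where no interior maximum exists.
    """
    if not 0.0 < p_drop < 1.0:
        raise ValueError("interior maximum requires 0 < p_drop < 1")
    res = minimize_scalar(
        lambda M: -p_identical(M, p_drop),
        bounds=(1e-9, moi_max),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def analytic_summary(S: float, B: float, M: float, p_drop: float) -> dict:
    """All analytic quantities for one (S, B, M, p_drop) design point."""
    _validate(S=S, B=B, M=M, p_drop=p_drop)
    out = {
        "p_no_overlap": p_no_overlap(S, B, M),
        "p_any_overlap": 1.0 - p_no_overlap(S, B, M),
        "p_identical_after_dropout": p_identical(M, p_drop),
        "labeled_fraction": -math.expm1(-M),
        "effective_moi": M * (1.0 - p_drop),
        "min_complexity_bound": min_complexity_bound(S, M),
    }
    if 0.0 < p_drop < 1.0:
        out["p_identical_peak_moi"] = p_identical_peak_moi(p_drop)
    return out
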