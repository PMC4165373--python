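"""Poisson likelihood-ratio test for a constant expression ratio.

For a pair of clusters (a, b) we ask whether the ratio of their expression
is the same in every condition group.  Counts are summarised per condition
as

    X_ai = 1 + sum_j (r_aij + 0.5 * r_abij)

where r_aij are fragments of condition i, replicate j mapping to a but *not*
shared with b, and r_abij are the shared fragments — each shared fragment
contributes one half to each side, avoiding double counting.  The added one
keeps X strictly positive.

X_ai ~ Pois(mu_ai = f_i * mu_bi) and X_bi ~ Pois(mu_bi); the null hypothesis
is f_i = f for all i.  The likelihood-ratio statistic

    D = -2 (ln l0 - ln l1)

is chi-square on n_conditions - 1 degrees of freedom under the null.  The
maximum-likelihood fits have closed forms: under the alternative the fitted
means are the observations themselves; under the null, with
f_hat = sum_i X_ai / sum_i X_bi and T_i = X_ai + X_bi,

    E_bi = T_i / (1 + f_hat),   E_ai = f_hat * E_bi

(split each condition's total in the common ratio), giving

    D = 2 * sum_i [ X_ai ln(X_ai / E_ai) + X_bi ln(X_bi / E_bi) ].

These closed forms are validated against brute-force numeric likelihood
maximisation in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairCounts",
    "RatioTestResult",
    "pseudocounts",
    "lrt_statistic",
    "d_threshold",
    "DEFAULT_P_VALUE",
]

DEFAULT_P_VALUE = 1e-5


@dataclass(frozen=True)
class PairCounts:
    """Per-condition pseudocounts for a pair of clusters."""

    x_a: tuple[float, ...]
    x_b: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.x_a) != len(self.x_b) or not self.x_a:
            raise ValueError("x_a and x_b must be equal-length and non-empty")
        if any(x < 1 for x in self.x_a) or any(x < 1 for x in self.x_b):
            raise ValueError("pseudocounts must be >= 1 (the +1 offset guarantees X > 0)")

    @property
    def n_conditions(self) -> int:
        return len(self.x_a)

    def swapped(self) -> "PairCounts":
        return PairCounts(self.x_b, self.x_a)


@dataclass(frozen=True)
class RatioTestResult:
    D: float
    df: int
    threshold: float
    reject: bool


def pseudocounts(
    r_a: Sequence[Sequence[float]] | Sequence[np.ndarray],
    r_b: Sequence[Sequence[float]] | Sequence[np.ndarray],
    r_ab: Sequence[Sequence[float]] | Sequence[np.ndarray],
) -> PairCounts:
    """Build :class:`PairCounts` from per-condition replicate counts.

    ``r_a[i][j]`` / ``r_b[i][j]`` are the fragments of condition i, replicate
    j mapping to one cluster and not shared with the other; ``r_ab[i][j]``
    are the shared fragments.  All counts must be non-negative.
    """
    if not (len(r_a) == len(r_b) == len(r_ab)):
        raise ValueError("condition lists must have equal length")
    x_a, x_b = [], []
    for ra_i, rb_i, rab_i in zip(r_a, r_b, r_ab):
        ra_i = np.asarray(ra_i, dtype=float)
        rb_i = np.asarray(rb_i, dtype=float)
        rab_i = np.asarray(rab_i, dtype=float)
        if (ra_i < 0).any() or (rb_i < 0).any() or (rab_i < 0).any():
            raise ValueError("negative count")
        x_a.append(1.0 + float(np.sum(ra_i + 0.5 * rab_i)))
        x_b.append(1.0 + float(np.sum(rb_i + 0.5 * rab_i)))
    return PairCounts(tuple(x_a), tuple(x_b))


def lrt_statistic(pc: PairCounts, threshold: float | None = None) -> RatioTestResult:
    """Closed-form likelihood-ratio statistic for a constant ratio across conditions.

    With one condition there is no contrast: D = 0, df = 0, never rejected.
    ``threshold`` defaults to :func:`d_threshold` for the pair's condition count.
    """
    xa = np.asarray(pc.x_a, dtype=float)
    xb = np.asarray(pc.x_b, dtype=float)
    df = pc.n_conditions - 1
    if threshold is None:
        threshold = d_threshold(pc.n_conditions)
    if df == 0:
        return RatioTestResult(0.0, 0, threshold, False)
    f_hat = xa.sum() / xb.sum()
    e_b = (xa + xb) / (1.0 + f_hat)
    e_a = f_hat * e_b
    d = 2.0 * float(np.sum(xa * np.log(xa / e_a) + xb * np.log(xb / e_b)))
    d = max(d, 0.0)  # guard against rounding below zero
    return RatioTestResult(d, df, threshold, d > threshold)


def d_threshold(n_conditions: int, p_value: float = DEFAULT_P_VALUE) -> float:
    """Rejection threshold on D for a given number of conditions.

    For the default p-value and 2 <= n_conditions < 10 uses the linear
    parameterisation 15 + 2.5 * n_conditions, an approximation of the
    chi-square upper quantile; otherwise returns the exact chi-square
    quantile at ``p_value`` with n_conditions - 1 degrees of freedom.
    With a single condition the test has no degrees of freedom, so the
    threshold is infinite (never reject).
    """
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    if not (0.0 < p_value < 1.0):
        raise ValueError("p_value must be in (0, 1)")
    if n_conditions == 1:
        return math.inf
    if p_value == DEFAULT_P_VALUE and n_conditions < 10:
        return 15.0 + 2.5 * n_conditions
    return float(stats.chi2.isf(p_value, n_conditions - 1))
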