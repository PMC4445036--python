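"""Core data model for set overlaps and the characteristic-parameter transform.

An overlap of two annotation sets is fully described by the integer triple
``(m, n, d)`` — the two set sizes and the size of their intersection —
against a background universe of ``N`` distinct properties.  The same
overlap can be re-expressed by the characteristic triple ``(d, R, r)``:

* ``d``   — intersection size,
* ``R``   — average expansion ratio, ``R = sqrt(m*n) / d`` (how many times
  larger the sets are, geometrically averaged, than their intersection),
* ``r``   — set-size imbalance, ``r = max(m, n) / min(m, n)``.

``R >= 1`` always, and ``1 <= r <= R**2``.  The random expectation of the
intersection size under independent draws is ``lambda = m*n/N``; only cases
with ``d > lambda`` count as a *real* overlap ("within the boundary"), and
in the d-R plane the boundary is the curve ``d = N / R**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "OverlapCase",
    "CharTriple",
    "to_char",
    "from_char",
    "expected_overlap",
    "within_boundary",
    "log_factorial_exact",
    "log_factorial_stirling",
    "LN10",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class OverlapCase:
    """An overlap of two sets: sizes ``m`` and ``n``, shared count ``d``,
    background universe size ``N``.

    Invariants: all fields are non-negative integers, ``d <= min(m, n)``,
    ``m <= N``, ``n <= N``, ``m, n, N >= 1``.  Scoring additionally
    requires ``d >= 1`` (pairs that share nothing are not scored).
    """

    m: int
    n: int
    d: int
    N: int

    def __post_init__(self) -> None:
        for name in ("m", "n", "d", "N"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise TypeError(f"{name} must be an integer, got {v!r}")
        if self.m < 1 or self.n < 1 or self.N < 1:
            raise ValueError("set sizes m, n and background N must be >= 1")
        if self.d < 0:
            raise ValueError("intersection size d must be >= 0")
        if self.d > min(self.m, self.n):
            raise ValueError(
                f"d={self.d} exceeds min(m, n)={min(self.m, self.n)}"
            )
        if self.m > self.N or self.n > self.N:
            raise ValueError("set sizes cannot exceed the background N")

    @property
    def union(self) -> int:
        return self.m + self.n - self.d


@dataclass(frozen=True)
class CharTriple:
    """Characteristic parameters ``(d, R, r)`` of an overlap.

    ``R = sqrt(m*n)/d`` is the average expansion ratio and
    ``r = max(m, n)/min(m, n)`` the set-size imbalance; the valid domain is
    ``R >= 1`` and ``1 <= r <= R**2``.
    """

    d: int
    R: float
    r: float

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("characteristic parameters need d >= 1")
        if self.R < 1.0 - 1e-12:
            raise ValueError(f"R must be >= 1, got {self.R}")
        if not (1.0 - 1e-12 <= self.r <= self.R**2 + 1e-9):
            raise ValueError(f"r={self.r} outside [1, R^2]=[1, {self.R**2}]")


def to_char(case: OverlapCase) -> CharTriple:
    """Transform an ``(m, n, d)`` overlap into its ``(d, R, r)`` triple.

    Rejects ``d = 0``: the expansion ratio is undefined for a void overlap.
    """
    if case.d < 1:
        raise ValueError("characteristic parameters undefined for d = 0")
    R = math.sqrt(case.m * case.n) / case.d
    r = max(case.m, case.n) / min(case.m, case.n)
    return CharTriple(d=case.d, R=R, r=r)


def from_char(
    triple: CharTriple,
    N: int,
    *,
    round_sizes: bool = True,
    rel_tol: float = 1e-6,
) -> OverlapCase:
    """Inverse transform: recover ``(m, n, d)`` from ``(d, R, r)``.

    The implied sizes are ``m = d*R*sqrt(r)`` (the larger set) and
    ``n = d*R/sqrt(r)``.  With ``round_sizes=False`` the implied sizes must
    be integral to within ``rel_tol`` (relative); otherwise they are rounded
    to the nearest integer, which is what simulation grids traversing
    real-valued ``(R, r)`` need.
    """
    sqrt_r = math.sqrt(triple.r)
    m_f = triple.d * triple.R * sqrt_r
    n_f = triple.d * triple.R / sqrt_r
    m, n = round(m_f), round(n_f)
    if not round_sizes:
        for implied, rounded in ((m_f, m), (n_f, n)):
            if abs(implied - rounded) > rel_tol * max(1.0, implied):
                raise ValueError(
                    f"implied set size {implied} is not integral "
                    f"(tolerance {rel_tol})"
                )
    m = max(m, triple.d)
    n = max(n, triple.d)
    if m > N or n > N:
        raise ValueError(f"implied sizes ({m}, {n}) exceed background N={N}")
    return OverlapCase(m=m, n=n, d=triple.d, N=N)


def expected_overlap(case: OverlapCase) -> float:
    """Random expectation ``lambda = m*n/N`` of the intersection size.

    Equivalently ``lambda = d**2 * R**2 / N``; setting ``d = lambda`` gives
    the boundary curve ``d = N / R**2`` in the d-R plane.
    """
    return case.m * case.n / case.N


def within_boundary(case: OverlapCase) -> bool:
    """True iff ``d > lambda`` (strict): the overlap is larger than its
    random expectation.  The boundary ``d = lambda`` itself is excluded."""
    return case.d > expected_overlap(case)


def log_factorial_exact(k):
    """``ln(k!)`` via the log-gamma function; exact to double precision.

    Accepts scalars or arrays; ``k`` must be >= 0.
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 0):
        raise ValueError("factorial undefined for negative k")
    out = gammaln(k_arr + 1.0)
    return float(out) if np.isscalar(k) or k_arr.ndim == 0 else out


def log_factorial_stirling(k):
    """Stirling's approximation ``ln(k!) ~= k ln k - k + ln(2 pi k)/2``.

    Valid for ``k >= 1``; the remainder is bounded by ``1/(12 k)``.
    ``k = 0`` is rejected (use :func:`log_factorial_exact`).
    """
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 1):
        raise ValueError("Stirling form requires k >= 1")
    out = k_arr * np.log(k_arr) - k_arr + 0.5 * np.log(2.0 * math.pi * k_arr)
    return float(out) if np.isscalar(k) or k_arr.ndim == 0 else out
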