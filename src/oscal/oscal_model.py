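"""OScal: a finite, balanced overlap score built on the Stirling-Poisson model.

The plain Poisson score overestimates overlaps with small ``d``: when ``d``
is small, ``lambda = m n / N`` is usually tiny, and the ratio ``d/lambda``
(which drives the score) looks spuriously extreme.  OScal repairs this with
three items,

    ``OS = Ps + M_J - M_r``

* ``Ps`` (the basal score, exposed as model ``OS_B``) is the
  Stirling-Poisson score evaluated at an *enlarged* expectation
  ``lambda' = c(d, R) * lambda``.  The enlargement is implemented as a
  geometric pull of ``lambda`` toward the observed count::

      psi     = w_coef * (R**2 - 1)**w_exp_r / d**w_exp_d
      w       = psi / (1 + psi)            # in [0, 1)
      lambda' = lambda**(1 - w) * d**w     # so c = (d/lambda)**w

  ``w`` grows with ``R`` and shrinks with ``d``, so the coefficient
  ``c = (N / (d R**2))**w`` is large exactly when ``d`` is small and ``R``
  is large, and tends to 1 as ``d`` grows.  Within the boundary
  (``d > lambda``) we always have ``lambda <= lambda' < d``, hence
  ``Ps <= P`` with equality in the large-``d`` limit, and ``Ps`` stays
  finite for arbitrarily large overlaps where H and B underflow.

* ``M_J`` carries the ``r``-dependence: at fixed ``(d, R)`` a more
  imbalanced pair (larger ``r``, smaller Jaccard) scores slightly higher,
  mirroring the hypergeometric ordering.  Its ``r = 1`` baseline decays
  exponentially in ``d``.

* ``M_r`` penalizes hyper-large sets: it is quadratic in the mean set
  fraction ``(m + n) / (2 N)``, negligible for ordinary annotation sets
  and approaching 1 only when both sets fill the universe; it keeps
  ``OS`` finite even at ``m = n = N``.

The five shape constants below are calibrated once against the six
reference overlaps of :func:`oscal.synthetic_data.table1_cases` (the
published scores of those cases are reproduced to two decimals); they are
model constants, not user-tunable parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .overlap_core import LN10, OverlapCase

__all__ = [
    "OscalBreakdown",
    "enlargement_coefficient",
    "oscal_basal",
    "mj_term",
    "mr_term",
    "oscal_score",
    "score_arrays",
    "REFERENCE_N",
]

#: reference background size (approximate human gene count) used as the
#: default universe when only (d, R) are given.
REFERENCE_N = 22507

# calibrated shape constants (see module docstring)
_W_COEF = 4.2082269622801177e-04
_W_EXP_R = 2.242897846486787
_W_EXP_D = 0.34085337085167544
_MJ_AMP = 1.0541939595323484
_MJ_DECAY = 39.73274717891137
_MJ_IMB = 8.0 / 9.0


@dataclass(frozen=True)
class OscalBreakdown:
    """The three items of an OScal score and their sum.

    ``os == ps + mj - mr`` holds exactly by construction.
    """

    coefficient: float
    enlarged_lambda: float
    ps: float
    mj: float
    mr: float
    os: float


def _pull_weight(d, R):
    """Interpolation weight ``w`` in [0, 1): how far lambda is pulled
    toward the observed count d."""
    gap = np.clip(R * R - 1.0, 0.0, None)
    psi = _W_COEF * gap**_W_EXP_R / np.asarray(d, dtype=float) ** _W_EXP_D
    return psi / (1.0 + psi)


def enlargement_coefficient(d, R, N: float = REFERENCE_N):
    """Enlargement coefficient ``c`` with ``lambda' = c * lambda``.

    ``c = (N / (d R**2))**w`` — large for small ``d`` / large ``R``,
    tending to 1 as ``d`` grows at fixed ``R``, and >= 1 everywhere within
    the boundary.  Beyond the boundary (``d < lambda``) the same pull
    regularizes ``lambda'`` toward ``d`` from above, i.e. ``c < 1`` there.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 1):
        raise ValueError("enlargement coefficient requires d >= 1")
    w = _pull_weight(d, np.asarray(R, dtype=float))
    out = (N / (d * np.asarray(R, dtype=float) ** 2)) ** w
    return float(out) if out.ndim == 0 else out


def _stirling_poisson(d, lam):
    return (d * np.log(d / lam) - (d - lam) + 0.5 * np.log(2 * np.pi * d)) / LN10


def _basal_v(m, n, d, N):
    lam = m * n / N
    R = np.sqrt(m * n) / d
    w = _pull_weight(d, R)
    lam_prime = lam ** (1.0 - w) * d**w
    return _stirling_poisson(d, lam_prime), lam_prime


def _mj_v(m, n, d, N):
    R = np.sqrt(m * n) / d
    j = d / (m + n - d)
    j_balanced = 1.0 / (2.0 * R - 1.0)
    return _MJ_AMP * np.exp(-d / _MJ_DECAY) + _MJ_IMB * (j_balanced - j)


def _mr_v(m, n, d, N):
    return ((m + n) / (2.0 * N)) ** 2


def oscal_basal(case: OverlapCase) -> float:
    """The basal score ``Ps`` (model identifier ``OS_B``)."""
    if case.d < 1:
        raise ValueError("scoring requires d >= 1")
    ps, _ = _basal_v(
        float(case.m), float(case.n), float(case.d), float(case.N)
    )
    return float(ps)


def mj_term(case: OverlapCase) -> float:
    """Imbalance item ``M_J``: baseline decaying in ``d`` plus a positive
    contribution growing with ``r`` at fixed ``(d, R)``."""
    if case.d < 1:
        raise ValueError("scoring requires d >= 1")
    return float(_mj_v(float(case.m), float(case.n), float(case.d), case.N))


def mr_term(case: OverlapCase) -> float:
    """Hyper-large-set item ``M_r``, subtracted from the score."""
    if case.d < 1:
        raise ValueError("scoring requires d >= 1")
    return float(_mr_v(float(case.m), float(case.n), float(case.d), case.N))


def oscal_score(case: OverlapCase) -> OscalBreakdown:
    """Full OScal breakdown for one overlap; ``os = ps + mj - mr``."""
    if case.d < 1:
        raise ValueError("scoring requires d >= 1")
    m, n, d, N = float(case.m), float(case.n), float(case.d), float(case.N)
    ps, lam_prime = _basal_v(m, n, d, N)
    mj = _mj_v(m, n, d, N)
    mr = _mr_v(m, n, d, N)
    lam = m * n / N
    return OscalBreakdown(
        coefficient=float(lam_prime / lam),
        enlarged_lambda=float(lam_prime),
        ps=float(ps),
        mj=float(mj),
        mr=float(mr),
        os=float(ps + mj - mr),
    )


def score_arrays(model: str, m, n, d, N) -> np.ndarray:
    """Vectorized ``OS`` / ``OS_B`` over parallel arrays (loop-free)."""
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(d < 1):
        raise ValueError("scoring requires d >= 1")
    N = float(N)
    ps, _ = _basal_v(m, n, d, N)
    if model == "OS_B":
        return ps
    if model == "OS":
        return ps + _mj_v(m, n, d, N) - _mr_v(m, n, d, N)
    raise ValueError(f"unknown OScal identifier {model!r}")
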