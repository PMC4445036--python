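"""Seven classical overlap-quantification models as finite, log-space scores.

Two classes of model are distinguished by whether the intersection size
``d`` survives in the characteristic-parameter form of the expression:

* class I (similarity style): Jaccard ``J``, Ochiai ``K``, overlap
  coefficient ``C`` — functions of ``(R, r)`` only;
* class II (significance style): mutual information ``I``, Poisson ``P``,
  hypergeometric ``H``, binomial ``B`` — ``d`` appears explicitly.

The probability models score an overlap as ``-log10`` of the point
probability of observing exactly ``d`` shared elements.  All of them are
computed in log space with log-gamma, so they stay finite where a naive
probability-first evaluation underflows to 0 and reports an infinite
score (the classical failure of H and B on large overlaps).

Closed forms in characteristic parameters:

* ``J = 1 / (R*(sqrt(r) + 1/sqrt(r)) - 1)``
* ``K = 1 / R``
* ``C = d / min(m, n)``
* ``P = [d ln(d/lambda) - (d - lambda) + ln(2 pi d)/2] / ln 10`` — the
  Stirling-simplified ``-log10`` Poisson point probability with
  ``lambda = m n / N``.  The Stirling form *is* the model here, not a
  shortcut; its error versus the exact Poisson mass is below
  ``1/(12 d ln 10)``.
* ``H = -log10[ C(m, d) C(N-m, n-d) / C(N, n) ]``
* ``B = -log10[ C(T, d) p^d (1-p)^(T-d) ]`` with trials ``T = max(m, n)``
  and success probability ``p = min(m, n)/N`` (symmetric in ``m, n``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, xlogy, xlog1py

from .overlap_core import LN10, OverlapCase

__all__ = [
    "ScoreVector",
    "jaccard",
    "ochiai",
    "overlap_coefficient",
    "mutual_information",
    "poisson_score",
    "hypergeometric_score",
    "binomial_score",
    "score_all",
    "score_arrays",
    "MODEL_IDS",
    "CLASS_I",
    "CLASS_II",
]

CLASS_I = ("J", "K", "C")
CLASS_II = ("I", "P", "H", "B")
#: all model identifiers accepted by :func:`score_all` / the CLI,
#: including the OScal family implemented in :mod:`oscal.oscal_model`.
MODEL_IDS = ("J", "K", "C", "I", "P", "H", "B", "OS_B", "OS")


@dataclass(frozen=True)
class ScoreVector:
    """Per-case scores under a selected set of models."""

    case: OverlapCase
    scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ident, value in self.scores.items():
            if ident not in MODEL_IDS:
                raise ValueError(f"unknown model identifier {ident!r}")
            if not math.isfinite(value):
                raise ValueError(f"non-finite score for model {ident!r}")

    def __getitem__(self, ident: str) -> float:
        return self.scores[ident]


def _lchoose(a, b):
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def _require_scorable(case: OverlapCase) -> None:
    if case.d < 1:
        raise ValueError("scoring requires d >= 1")


# ---------------------------------------------------------------------------
# vectorized kernels: m, n, d are float arrays, N a scalar float


def _jaccard_v(m, n, d, N):
    return d / (m + n - d)


def _ochiai_v(m, n, d, N):
    return d / np.sqrt(m * n)


def _overlap_coefficient_v(m, n, d, N):
    return d / np.minimum(m, n)


def _mutual_information_v(m, n, d, N):
    # 2x2 contingency MI over the N-element universe, in nats
    cells = np.stack([d, m - d, n - d, N - m - n + d]) / N
    pa = m / N
    pb = n / N
    expect = np.stack(
        [pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(cells > 0, cells * np.log(cells / expect), 0.0)
    return np.maximum(terms.sum(axis=0), 0.0)


def _poisson_v(m, n, d, N):
    lam = m * n / N
    return (d * np.log(d / lam) - (d - lam) + 0.5 * np.log(2 * np.pi * d)) / LN10


def _hypergeometric_v(m, n, d, N):
    log_p = _lchoose(m, d) + _lchoose(N - m, n - d) - _lchoose(N, n)
    return -log_p / LN10


def _binomial_v(m, n, d, N):
    trials = np.maximum(m, n)
    p = np.minimum(m, n) / N
    log_p = _lchoose(trials, d) + xlogy(d, p) + xlog1py(trials - d, -p)
    return -log_p / LN10


_KERNELS = {
    "J": _jaccard_v,
    "K": _ochiai_v,
    "C": _overlap_coefficient_v,
    "I": _mutual_information_v,
    "P": _poisson_v,
    "H": _hypergeometric_v,
    "B": _binomial_v,
}


def _scalar(kernel, case: OverlapCase) -> float:
    _require_scorable(case)
    m = np.float64(case.m)
    n = np.float64(case.n)
    d = np.float64(case.d)
    return float(kernel(m, n, d, float(case.N)))


# ---------------------------------------------------------------------------
# public scalar API


def jaccard(case: OverlapCase) -> float:
    """Jaccard index ``J = d / (m + n - d)``, in (0, 1]."""
    return _scalar(_jaccard_v, case)


def ochiai(case: OverlapCase) -> float:
    """Ochiai coefficient ``K = d / sqrt(m n) = 1/R``, in (0, 1]."""
    return _scalar(_ochiai_v, case)


def overlap_coefficient(case: OverlapCase) -> float:
    """Overlap coefficient ``C = d / min(m, n)``, in (0, 1]."""
    return _scalar(_overlap_coefficient_v, case)


def mutual_information(case: OverlapCase) -> float:
    """Mutual information of the 2x2 membership contingency table (nats).

    The table cells are ``d, m-d, n-d, N-m-n+d`` over the ``N``-element
    universe; the value vanishes when ``d`` equals its random expectation.
    """
    _require_scorable(case)
    if case.union > case.N:
        raise ValueError("m + n - d exceeds the background N")
    return _scalar(_mutual_information_v, case)


def poisson_score(case: OverlapCase) -> float:
    """Stirling-simplified ``-log10`` Poisson point probability of ``d``."""
    return _scalar(_poisson_v, case)


def hypergeometric_score(case: OverlapCase) -> float:
    """``-log10`` of the hypergeometric point probability
    ``C(m, d) C(N-m, n-d) / C(N, n)``, via exact log-gamma."""
    _require_scorable(case)
    if case.n - case.d > case.N - case.m:
        raise ValueError("infeasible contingency: n - d > N - m")
    return _scalar(_hypergeometric_v, case)


def binomial_score(case: OverlapCase) -> float:
    """``-log10`` of the binomial point probability with
    ``max(m, n)`` trials and success probability ``min(m, n)/N``."""
    return _scalar(_binomial_v, case)


def score_arrays(model: str, m, n, d, N) -> np.ndarray:
    """Vectorized scoring of one model over parallel arrays ``m, n, d``.

    ``m, n, d`` may be real-valued (the simulation grids traverse the
    continuous ``(d, R, r)`` relaxation); all entries need ``d >= 1``.
    The OScal identifiers are dispatched to :mod:`oscal.oscal_model`.
    """
    if model in ("OS", "OS_B"):
        from . import oscal_model

        return oscal_model.score_arrays(model, m, n, d, N)
    try:
        kernel = _KERNELS[model]
    except KeyError:
        raise ValueError(f"unknown model identifier {model!r}") from None
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(d < 1):
        raise ValueError("scoring requires d >= 1")
    return kernel(m, n, d, float(N))


def score_all(case: OverlapCase, models: Sequence[str]) -> ScoreVector:
    """Score one case under every requested model identifier."""
    if not models:
        raise ValueError("at least one model identifier is required")
    _require_scorable(case)
    from . import oscal_model

    scores: dict[str, float] = {}
    for ident in models:
        if ident in scores:
            raise ValueError(f"duplicate model identifier {ident!r}")
        if ident == "OS":
            scores[ident] = oscal_model.oscal_score(case).os
        elif ident == "OS_B":
            scores[ident] = oscal_model.oscal_basal(case)
        elif ident in _KERNELS:
            scores[ident] = _scalar(_KERNELS[ident], case)
        else:
            raise ValueError(f"unknown model identifier {ident!r}")
    return ScoreVector(case=case, scores=scores)
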