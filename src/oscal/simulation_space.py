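"""The simulated (m, n, d) triple space and its d-R plane geometry.

Every integer triple with ``1 <= d <= min(m, n)`` and ``m, n <= N`` is a
valid simulated overlap.  Mapped through the characteristic parameters,
each case is a point in the d-R plane (at fixed imbalance ``r``), where a
model's equal-score curves (isolines) and the region scoring above a
cutoff (its positive area) make models with incomparable scales directly
comparable.  Class-I models (J, K, C) are defined over the whole plane;
class-II and OScal scores are only meaningful for real overlaps, so their
isolines and positive areas are restricted to the region within the
boundary curve ``d = N / R**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np
from scipy import optimize

from .classic_models import CLASS_I, score_arrays
from .overlap_core import OverlapCase, to_char, within_boundary

__all__ = [
    "GridSpec",
    "RegionLabel",
    "enumerate_cases",
    "score_grid",
    "isoline",
    "positive_area",
    "reference_point",
    "classify_region",
    "district_name",
    "density_map",
    "write_isoline_tsv",
]

#: score tolerance for root-finding on isolines and reference points
SCORE_TOL = 1e-6


@dataclass(frozen=True)
class GridSpec:
    """A rectangular evaluation window in the d-R plane.

    ``d_range`` and ``R_range`` are inclusive spans; ``shape`` is the
    number of sample points along (d, R); ``r_fixed`` selects the 2-D
    slice of the full (d, R, r) space (1 = balanced sets).
    """

    N: int = 22507
    d_range: tuple[float, float] = (1.0, 512.0)
    R_range: tuple[float, float] = (1.0, 16.0)
    shape: tuple[int, int] = (512, 512)
    r_fixed: float = 1.0

    def __post_init__(self) -> None:
        if self.d_range[0] < 1:
            raise ValueError("d_range lower bound must be >= 1")
        if self.R_range[0] < 1:
            raise ValueError("R_range lower bound must be >= 1")
        if self.r_fixed < 1:
            raise ValueError("r_fixed must be >= 1")

    @property
    def d_axis(self) -> np.ndarray:
        return np.linspace(self.d_range[0], self.d_range[1], self.shape[0])

    @property
    def R_axis(self) -> np.ndarray:
        return np.linspace(self.R_range[0], self.R_range[1], self.shape[1])


@dataclass(frozen=True)
class RegionLabel:
    """Membership of one case: beyond/within the boundary, and whether it
    falls in each model's positive area."""

    beyond_boundary: bool
    in_positive_area: Mapping[str, bool] = field(default_factory=dict)


def enumerate_cases(
    N: int, caps: int, stride: int = 1
) -> Iterator[OverlapCase]:
    """Yield every integer triple ``(m, n, d)`` with ``m, n <= caps`` and
    ``1 <= d <= min(m, n)``, stepping each variable by ``stride``.

    The stream is deterministic (m-major, then n, then d); for
    ``stride = 1`` its length is ``sum_{m,n<=caps} min(m, n)``.
    """
    if caps > N:
        raise ValueError("caps must not exceed the background N")
    for m in range(1, caps + 1, stride):
        for n in range(1, caps + 1, stride):
            for d in range(1, min(m, n) + 1, stride):
                yield OverlapCase(m=m, n=n, d=d, N=N)


def _plane_scores(model: str, d: np.ndarray, R: np.ndarray, grid: GridSpec):
    """Continuous-relaxation scores at broadcastable (d, R) arrays, with
    class-II/OScal models masked (NaN) beyond the boundary."""
    sqrt_r = math.sqrt(grid.r_fixed)
    m = d * R * sqrt_r
    n = d * R / sqrt_r
    s = score_arrays(model, m, n, np.broadcast_to(d, m.shape), grid.N)
    if model not in CLASS_I:
        lam = m * n / grid.N
        s = np.where(d > lam, s, np.nan)
    return s


def score_grid(model: str, grid: GridSpec) -> np.ndarray:
    """Dense score field with shape ``grid.shape`` (d along axis 0)."""
    d = grid.d_axis[:, None]
    R = grid.R_axis[None, :]
    return _plane_scores(model, d, R, grid)


def isoline(model: str, level: float, grid: GridSpec) -> np.ndarray:
    """Points ``(R, d)`` where the score field crosses ``level``.

    Crossings are located by sign change along both grid directions with
    linear interpolation, then merged and ordered by ``R`` (ties by
    ``d``).  Returns an array of shape (k, 2); empty when the level is
    unattainable on the grid.  For Ochiai the result is the horizontal
    line ``R = 1/level``; for Poisson a curve within the boundary.
    """
    s = score_grid(model, grid)
    f = s - level
    d_ax, R_ax = grid.d_axis, grid.R_axis
    pts: list[tuple[float, float]] = []

    def _scan(values, coords, fixed, transpose):
        a, b = values[:-1], values[1:]
        cross = np.isfinite(a) & np.isfinite(b) & (np.sign(a) != np.sign(b))
        for i, j in zip(*np.nonzero(cross)):
            t = a[i, j] / (a[i, j] - b[i, j])
            c = coords[i] + t * (coords[i + 1] - coords[i])
            pts.append((fixed[j], c) if not transpose else (c, fixed[j]))

    # along d (columns), then along R (rows)
    _scan(f, d_ax, R_ax, transpose=False)
    _scan(f.T, R_ax, d_ax, transpose=True)
    # exact hits on grid nodes
    for i, j in zip(*np.nonzero(np.isfinite(f) & (f == 0.0))):
        pts.append((R_ax[j], d_ax[i]))
    if not pts:
        return np.empty((0, 2))
    out = np.unique(np.round(np.array(pts), 12), axis=0)
    return out[np.lexsort((out[:, 1], out[:, 0]))]


def positive_area(
    model: str, cutoff: float, grid: GridSpec
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Predicate over ``(R, d)``: true iff the model's score is >= cutoff
    (class-II/OScal additionally require the point to lie within the
    boundary)."""

    def predicate(R, d):
        R = np.asarray(R, dtype=float)
        d = np.asarray(d, dtype=float)
        s = _plane_scores(model, d, R, grid)
        with np.errstate(invalid="ignore"):
            out = np.where(np.isfinite(s), s >= cutoff, False)
        return bool(out) if out.ndim == 0 else out

    return predicate


def reference_point(
    model_a: str,
    cutoff_a: float,
    model_b: str,
    cutoff_b: float,
    grid: GridSpec,
) -> tuple[float, float] | None:
    """Crossing ``(R, d)`` of the two cutoff-lines, or None when no unique
    crossing exists inside the grid (including the degenerate case of
    identical cutoff-lines)."""
    if model_a == model_b and cutoff_a == cutoff_b:
        return None
    sa = score_grid(model_a, grid) - cutoff_a
    sb = score_grid(model_b, grid) - cutoff_b
    with np.errstate(invalid="ignore"):
        mis = np.abs(sa) + np.abs(sb)
    if not np.any(np.isfinite(mis)):
        return None
    i, j = np.unravel_index(np.nanargmin(mis), mis.shape)
    x0 = (grid.d_axis[i], grid.R_axis[j])

    def system(x):
        d, R = x
        d = np.clip(d, grid.d_range[0], grid.d_range[1])
        R = np.clip(R, grid.R_range[0], grid.R_range[1])
        fa = _plane_scores(model_a, np.array(d), np.array(R), grid) - cutoff_a
        fb = _plane_scores(model_b, np.array(d), np.array(R), grid) - cutoff_b
        fa = np.nan_to_num(fa, nan=1e6)
        fb = np.nan_to_num(fb, nan=1e6)
        return [float(fa), float(fb)]

    sol, info, ier, _ = optimize.fsolve(system, x0, full_output=True)
    if ier != 1 or max(abs(v) for v in info["fvec"]) > SCORE_TOL:
        return None
    d_star, R_star = float(sol[0]), float(sol[1])
    if not (
        grid.d_range[0] - 1e-9 <= d_star <= grid.d_range[1] + 1e-9
        and grid.R_range[0] - 1e-9 <= R_star <= grid.R_range[1] + 1e-9
    ):
        return None
    return (R_star, d_star)


def classify_region(
    case: OverlapCase, model_cutoffs: Mapping[str, float]
) -> RegionLabel:
    """Label one case by boundary membership and per-model positivity.

    Positivity follows :func:`positive_area` semantics: class-II and
    OScal models never call a beyond-boundary case positive.
    """
    if not model_cutoffs:
        raise ValueError("at least one model cutoff is required")
    beyond = not within_boundary(case)
    membership: dict[str, bool] = {}
    for model, cutoff in model_cutoffs.items():
        s = score_arrays(
            model,
            float(case.m),
            float(case.n),
            float(case.d),
            case.N,
        )
        positive = bool(s >= cutoff)
        if model not in CLASS_I and beyond:
            positive = False
        membership[model] = positive
    return RegionLabel(beyond_boundary=beyond, in_positive_area=membership)


def district_name(label: RegionLabel, first: str, second: str) -> str:
    """Derived district name for the canonical two-model comparison
    (``first`` a class-I model, ``second`` class-II/OScal).

    Within the boundary: both positive -> "I", first only -> "II",
    second only -> "III", neither -> "N".  Beyond the boundary the
    class-II model is never positive: first positive -> "IV/V"
    (the similarity-model trap districts), else "beyond".
    """
    a = label.in_positive_area.get(first, False)
    b = label.in_positive_area.get(second, False)
    if label.beyond_boundary:
        return "IV/V" if a else "beyond"
    if a and b:
        return "I"
    if a:
        return "II"
    if b:
        return "III"
    return "N"


def density_map(
    cases: Iterable[OverlapCase], grid: GridSpec
) -> np.ndarray:
    """Counts of cases per (d, R) bin, shape ``grid.shape``.

    Cases outside the window are clipped into the edge bins so the total
    count is conserved.
    """
    R_vals, d_vals = [], []
    for case in cases:
        t = to_char(case)
        R_vals.append(t.R)
        d_vals.append(float(t.d))
    if not d_vals:
        return np.zeros(grid.shape)
    d_edges = np.linspace(*grid.d_range, grid.shape[0] + 1)
    R_edges = np.linspace(*grid.R_range, grid.shape[1] + 1)
    d_c = np.clip(d_vals, grid.d_range[0], grid.d_range[1])
    R_c = np.clip(R_vals, grid.R_range[0], grid.R_range[1])
    hist, _, _ = np.histogram2d(d_c, R_c, bins=[d_edges, R_edges])
    return hist


def write_isoline_tsv(points: np.ndarray, path, value: float) -> None:
    """Export an isoline as TSV with columns R, d, value."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("R\td\tvalue\n")
        for R, d in points:
            fh.write(f"{R:.6g}\t{d:.6g}\t{value:.6g}\n")
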