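"""Model comparison by positive predictive value against a gold standard.

Scores produced by different models live on incomparable scales, so
models are compared through their *positive calls*: the pairs scoring at
or above a cutoff.  With a gold-standard pair set (e.g. protein-protein
interactions) as the truth proxy, ``PPV = TP / PC`` — the fraction of
positive calls that are gold pairs.  The cutoff-PPV curve, the
matched-call comparison (different cutoffs, same number of calls) and
per-district PPV summaries all reduce to this one statistic, which
depends only on the ranking a model induces, never on its scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .relation_scoring import ScoredPair
from .simulation_space import RegionLabel, district_name

__all__ = [
    "GoldStandard",
    "PPVCurve",
    "PPVResult",
    "read_pairs",
    "read_scores",
    "scores_frame",
    "ppv_at_cutoff",
    "ppv_curve",
    "matched_calls",
    "region_ppv",
    "write_curve_tsv",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class GoldStandard:
    """A set of canonically ordered entity pairs serving as true positives."""

    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_iterable(cls, it: Iterable[tuple[str, str]]) -> "GoldStandard":
        out = set()
        for a, b in it:
            if a == b:
                continue
            out.add(canonical_pair(a, b))
        return cls(pairs=frozenset(out))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class PPVResult:
    """PPV at one cutoff; ``ppv`` is NaN when there are no calls."""

    ppv: float
    n_calls: int
    tp: int


@dataclass(frozen=True)
class PPVCurve:
    """PPV across descending cutoffs; ``n_calls`` is non-decreasing as the
    cutoff drops."""

    cutoffs: np.ndarray
    n_calls: np.ndarray
    tp: np.ndarray
    ppv: np.ndarray


def read_pairs(path) -> GoldStandard:
    """Read a 2-column TSV of entity pairs; duplicates and pair order
    collapse, self-pairs are skipped with a warning."""
    pairs: list[tuple[str, str]] = []
    n_self = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}: line {lineno}: expected two tab-separated fields"
                )
            if fields[0] == fields[1]:
                n_self += 1
                continue
            pairs.append((fields[0], fields[1]))
    if n_self:
        warnings.warn(
            f"{path}: skipped {n_self} self-pair line(s)", stacklevel=2
        )
    return GoldStandard.from_iterable(pairs)


def read_scores(path) -> pd.DataFrame:
    """Read a scored-pair TSV written by
    :func:`oscal.relation_scoring.write_scores`."""
    return pd.read_csv(path, sep="\t", dtype={"entity_a": str, "entity_b": str})


def scores_frame(pairs: Iterable[ScoredPair], models: Sequence[str]) -> pd.DataFrame:
    """Materialize a stream of scored pairs as a DataFrame."""
    rows = []
    for sp in pairs:
        row = {
            "entity_a": sp.entity_a,
            "entity_b": sp.entity_b,
            "d": sp.d,
            "m": sp.m,
            "n": sp.n,
            "R": sp.R,
            "r": sp.r,
            "lambda": sp.lam,
            "within_boundary": int(sp.within_boundary),
        }
        for mid in models:
            row[mid] = sp.scores[mid]
        rows.append(row)
    cols = [
        "entity_a", "entity_b", "d", "m", "n", "R", "r",
        "lambda", "within_boundary", *models,
    ]
    return pd.DataFrame(rows, columns=cols)


def _gold_mask(scored: pd.DataFrame, gold: GoldStandard) -> np.ndarray:
    return np.fromiter(
        (
            canonical_pair(a, b) in gold.pairs
            for a, b in zip(scored["entity_a"], scored["entity_b"])
        ),
        dtype=bool,
        count=len(scored),
    )


def ppv_at_cutoff(
    scored: pd.DataFrame, gold: GoldStandard, model: str, cutoff: float
) -> PPVResult:
    """PPV among pairs with ``score >= cutoff`` (ties at the cutoff are
    all included).  Zero calls leave the PPV undefined (NaN), never 0."""
    calls = scored[model].to_numpy() >= cutoff
    n_calls = int(calls.sum())
    if n_calls == 0:
        return PPVResult(ppv=math.nan, n_calls=0, tp=0)
    tp = int((calls & _gold_mask(scored, gold)).sum())
    return PPVResult(ppv=tp / n_calls, n_calls=n_calls, tp=tp)


def ppv_curve(
    scored: pd.DataFrame,
    gold: GoldStandard,
    model: str,
    levels: Sequence[float] | None = None,
    max_levels: int | None = None,
) -> PPVCurve:
    """Cumulative PPV across descending cutoffs.

    ``levels`` defaults to the distinct observed scores (exact step
    curve); ``max_levels`` switches to that many score quantiles for
    large inputs.
    """
    s = scored[model].to_numpy(dtype=float)
    if levels is None:
        lv = np.unique(s)[::-1]
        if max_levels is not None and lv.size > max_levels:
            qs = np.linspace(0, 1, max_levels)
            lv = np.unique(np.quantile(s, qs))[::-1]
    else:
        lv = np.asarray(levels, dtype=float)
        if lv.size == 0 or np.any(np.diff(lv) >= 0):
            raise ValueError("levels must be strictly decreasing")
    is_gold = _gold_mask(scored, gold)
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    gold_cum = np.concatenate([[0], np.cumsum(is_gold[order])])
    # number of pairs with score >= cutoff, ties included
    n_calls = np.searchsorted(-s_sorted, -lv, side="right")
    tp = gold_cum[n_calls]
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(n_calls > 0, tp / np.maximum(n_calls, 1), np.nan)
    return PPVCurve(
        cutoffs=lv,
        n_calls=n_calls.astype(int),
        tp=tp.astype(int),
        ppv=ppv,
    )


def matched_calls(
    scored: pd.DataFrame,
    gold: GoldStandard,
    models: Sequence[str],
    k: int,
) -> dict[str, tuple[float, PPVResult]]:
    """For each model: the cutoff equal to its k-th largest score and the
    PPV there.  Ties at the cutoff are all included, so the realized call
    count may exceed ``k``; this compares rankings at matched depth."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(scored):
        raise ValueError(f"k={k} exceeds the {len(scored)} scored pairs")
    out: dict[str, tuple[float, PPVResult]] = {}
    for model in models:
        s = np.sort(scored[model].to_numpy(dtype=float))[::-1]
        cutoff = float(s[k - 1])
        out[model] = (cutoff, ppv_at_cutoff(scored, gold, model, cutoff))
    return out


def region_ppv(
    scored: pd.DataFrame,
    gold: GoldStandard,
    labels: Sequence[RegionLabel],
    first: str | None = None,
    second: str | None = None,
) -> dict[str, PPVResult]:
    """PPV per region label plus 'within'/'beyond' boundary aggregates.

    ``labels`` align with the rows of ``scored``.  When ``first`` and
    ``second`` name the two compared models, regions are keyed by their
    derived district names; otherwise by the raw membership signature.
    """
    if len(labels) != len(scored):
        raise ValueError("labels must align with the scored rows")
    is_gold = _gold_mask(scored, gold)
    keys = []
    for lab in labels:
        if first is not None and second is not None:
            keys.append(district_name(lab, first, second))
        else:
            sig = ",".join(
                f"{m}{'+' if v else '-'}"
                for m, v in sorted(lab.in_positive_area.items())
            )
            keys.append(("beyond:" if lab.beyond_boundary else "within:") + sig)
    out: dict[str, PPVResult] = {}
    groups: dict[str, list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)
    for key, idx in groups.items():
        tp = int(is_gold[idx].sum())
        out[key] = PPVResult(ppv=tp / len(idx), n_calls=len(idx), tp=tp)
    for name, mask in (
        ("Ave_within", [not l.beyond_boundary for l in labels]),
        ("Ave_beyond", [l.beyond_boundary for l in labels]),
    ):
        idx = [i for i, flag in enumerate(mask) if flag]
        if idx:
            tp = int(is_gold[idx].sum())
            out[name] = PPVResult(ppv=tp / len(idx), n_calls=len(idx), tp=tp)
    return out


def write_curve_tsv(curve: PPVCurve, path) -> None:
    """Export a PPV curve as TSV (cutoff, n_calls, tp, ppv)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cutoff\tn_calls\ttp\tppv\n")
        for c, n, t, p in zip(curve.cutoffs, curve.n_calls, curve.tp, curve.ppv):
            ppv_txt = "NA" if math.isnan(p) else f"{p:.6g}"
            fh.write(f"{c:.6g}\t{n}\t{t}\t{ppv_txt}\n")
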