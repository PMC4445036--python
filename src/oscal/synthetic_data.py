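"""Synthetic annotation data with a planted gold standard.

The generator emulates the bipartite structure of real annotation data
(TF -> targets, gene -> GO terms, gene -> PPI partners): entities draw
heavy-tailed (lognormal) property-set sizes from a shared universe, and a
planted subset of entity pairs receives boosted overlap so that scoring
and PPV evaluation are fully testable offline.  Planted pairs are
disjoint (no entity belongs to two planted pairs) for clean accounting.

The module also ships the six reference overlaps (O1-O6, N = 22507) used
throughout as the worked examples of model behavior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .overlap_core import OverlapCase

__all__ = ["SynthConfig", "SynthData", "table1_cases", "generate", "write_fixtures"]


def table1_cases() -> dict[str, OverlapCase]:
    """The six labeled reference overlaps O1-O6 against N = 22507."""
    N = 22507
    return {
        "O1": OverlapCase(m=25, n=25, d=20, N=N),
        "O2": OverlapCase(m=250, n=250, d=200, N=N),
        "O3": OverlapCase(m=250, n=250, d=100, N=N),
        "O4": OverlapCase(m=625, n=100, d=100, N=N),
        "O5": OverlapCase(m=520, n=520, d=200, N=N),
        "O6": OverlapCase(m=520, n=520, d=40, N=N),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``n_properties`` doubles as the background N.  Set sizes follow a
    lognormal law (median ``set_size_median``, shape ``set_size_sigma``),
    clamped to ``[1, n_properties]`` — the heavy tail matches the very
    uneven annotation sizes of real regulatory and ontology data.
    ``overlap_boost`` is the target Jaccard of each planted pair.
    """

    n_entities: int = 300
    n_properties: int = 5000
    set_size_median: float = 30.0
    set_size_sigma: float = 1.0
    n_planted: int = 50
    overlap_boost: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted * 2 > self.n_entities:
            raise ValueError("n_planted must be <= n_entities / 2")
        if not (0.0 < self.overlap_boost <= 1.0):
            raise ValueError("overlap_boost must be in (0, 1]")
        if self.n_properties < 2:
            raise ValueError("need at least two properties")


@dataclass(frozen=True)
class SynthData:
    """Generated edge list plus the planted gold standard."""

    edges: tuple[tuple[str, str], ...]
    gold: tuple[tuple[str, str], ...]
    config: SynthConfig


def _draw_size(rng: np.random.Generator, cfg: SynthConfig) -> int:
    size = rng.lognormal(mean=np.log(cfg.set_size_median), sigma=cfg.set_size_sigma)
    # leave headroom so a planted partner can top up with fresh properties
    return int(np.clip(round(size), 1, cfg.n_properties // 2))


def generate(config: SynthConfig) -> SynthData:
    """Deterministically generate (edge list, planted gold pairs).

    Planted pairs: one member's set is drawn like background; the partner
    copies ``k = round(2 m j / (1 + j))`` of its members (so the pair's
    Jaccard is ``k / (2m - k) ~= j``, the configured boost) and tops up
    with properties drawn outside the source set, keeping the realized
    overlap exact.  ``overlap_boost = 1`` makes the partner an exact copy.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ent_width = max(4, len(str(cfg.n_entities)))
    prop_width = max(5, len(str(cfg.n_properties)))
    entities = [f"E{i:0{ent_width}d}" for i in range(cfg.n_entities)]
    properties = np.array([f"p{j:0{prop_width}d}" for j in range(cfg.n_properties)])

    edges: list[tuple[str, str]] = []
    gold: list[tuple[str, str]] = []

    def add_set(entity: str, props: np.ndarray) -> None:
        for p in props:
            edges.append((entity, str(p)))

    for i in range(cfg.n_planted):
        a, b = entities[2 * i], entities[2 * i + 1]
        m = _draw_size(rng, cfg)
        j = cfg.overlap_boost
        k = int(round(2 * m * j / (1 + j)))
        k = max(1, min(k, m))
        if (m - k) > cfg.n_properties - m:
            raise ValueError(
                "overlap_boost/set size infeasible: not enough fresh "
                "properties for the planted partner"
            )
        source = rng.choice(cfg.n_properties, size=m, replace=False)
        shared = rng.choice(source, size=k, replace=False)
        outside = np.setdiff1d(np.arange(cfg.n_properties), source, assume_unique=False)
        fresh = rng.choice(outside, size=m - k, replace=False)
        partner = np.concatenate([shared, fresh])
        add_set(a, properties[np.sort(source)])
        add_set(b, properties[np.sort(partner)])
        gold.append((a, b) if a < b else (b, a))

    for entity in entities[2 * cfg.n_planted :]:
        m = _draw_size(rng, cfg)
        chosen = rng.choice(cfg.n_properties, size=m, replace=False)
        add_set(entity, properties[np.sort(chosen)])

    return SynthData(
        edges=tuple(edges), gold=tuple(sorted(gold)), config=cfg
    )


def write_fixtures(data: SynthData, outdir) -> dict[str, Path]:
    """Write annotations.tsv, gold_pairs.tsv and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": outdir / "annotations.tsv",
        "gold": outdir / "gold_pairs.tsv",
        "manifest": outdir / "manifest.json",
    }
    with open(paths["annotations"], "w", encoding="utf-8") as fh:
        for entity, prop in data.edges:
            fh.write(f"{entity}\t{prop}\n")
    with open(paths["gold"], "w", encoding="utf-8") as fh:
        for a, b in data.gold:
            fh.write(f"{a}\t{b}\n")
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(asdict(data.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
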