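"""Scoring entity pairs from annotation data.

An annotation dataset maps entities (genes, transcription factors, ...)
to sets of properties (targets, GO terms, interaction partners, ...).
Every pair of entities that shares at least one property defines an
overlap ``(m, n, d)`` against the property universe, which any of the
registered models can score.  Pair enumeration goes through the inverted
property -> entities map, so only co-annotated pairs are ever touched and
the pair stream never materializes in memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Sequence

from .classic_models import ScoreVector, score_all
from .overlap_core import OverlapCase, expected_overlap, to_char, within_boundary

__all__ = [
    "AnnotationIndex",
    "ScoredPair",
    "read_edge_list",
    "read_gmt",
    "write_gmt",
    "background_size",
    "enumerate_sharing_pairs",
    "score_pairs",
    "write_scores",
]


@dataclass(frozen=True)
class AnnotationIndex:
    """Entity -> property sets plus the inverted property -> entity map.

    ``forward`` and ``inverted`` are exact transposes; entities with empty
    property sets are not stored.
    """

    forward: Mapping[str, frozenset[str]]
    inverted: Mapping[str, frozenset[str]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.inverted is None:
            inv: dict[str, set[str]] = {}
            for entity, props in self.forward.items():
                for p in props:
                    inv.setdefault(p, set()).add(entity)
            object.__setattr__(
                self,
                "inverted",
                {p: frozenset(es) for p, es in inv.items()},
            )

    @property
    def universe(self) -> int:
        """Number of distinct properties (the default background N)."""
        return len(self.inverted)

    @property
    def n_entities(self) -> int:
        return len(self.forward)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationIndex":
        fwd: dict[str, set[str]] = {}
        for entity, prop in pairs:
            fwd.setdefault(entity, set()).add(prop)
        return cls(forward={e: frozenset(s) for e, s in fwd.items()})


@dataclass(frozen=True)
class ScoredPair:
    """One scored entity pair with its overlap geometry.

    ``entity_a < entity_b`` in lexicographic order; ``d >= 1``.
    """

    entity_a: str
    entity_b: str
    d: int
    m: int
    n: int
    R: float
    r: float
    lam: float
    within_boundary: bool
    scores: ScoreVector


def read_edge_list(path) -> AnnotationIndex:
    """Read a two-column tab-separated entity -> property edge list.

    Lines starting with '#' and blank lines are skipped; duplicate edges
    collapse.  A malformed line raises with its line number.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}: line {lineno}: expected two tab-separated "
                    f"fields, got {line!r}"
                )
            pairs.append((fields[0], fields[1]))
    return AnnotationIndex.from_pairs(pairs)


def read_gmt(path) -> AnnotationIndex:
    """Read a GMT gene-set file (name TAB description TAB member...).

    The set name becomes the entity, the members its properties; the
    description field is ignored.
    """
    fwd: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not fields[0]:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need name, "
                    f"description and at least one member"
                )
            members = {f for f in fields[2:] if f}
            if not members:
                raise ValueError(
                    f"{path}: line {lineno}: set {fields[0]!r} has no members"
                )
            fwd.setdefault(fields[0], set()).update(members)
    return AnnotationIndex(forward={e: frozenset(s) for e, s in fwd.items()})


def write_gmt(index: AnnotationIndex, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for entity in sorted(index.forward):
            members = "\t".join(sorted(index.forward[entity]))
            fh.write(f"{entity}\t{description}\t{members}\n")


def background_size(index: AnnotationIndex, override: int | None = None) -> int:
    """The background universe N: ``override`` when given (e.g. 22507 for
    a whole-genome universe), else the distinct-property count."""
    if override is not None:
        largest = max((len(s) for s in index.forward.values()), default=0)
        if override < largest:
            raise ValueError(
                f"background override {override} is smaller than the "
                f"largest annotation set ({largest})"
            )
        return override
    return index.universe


def enumerate_sharing_pairs(
    index: AnnotationIndex,
) -> Iterator[tuple[str, str, int, int, int]]:
    """Yield each unordered entity pair sharing >= 1 property exactly once,
    as ``(entity_a, entity_b, d, m, n)`` with ``entity_a < entity_b``.

    Candidates come from the inverted map (union of co-annotated
    entities), never from the all-pairs product; output order is
    lexicographic in (entity_a, entity_b).
    """
    for entity_a in sorted(index.forward):
        props_a = index.forward[entity_a]
        partners: set[str] = set()
        for p in props_a:
            partners.update(index.inverted[p])
        for entity_b in sorted(b for b in partners if b > entity_a):
            props_b = index.forward[entity_b]
            d = len(props_a & props_b)
            if d >= 1:
                yield entity_a, entity_b, d, len(props_a), len(props_b)


def score_pairs(
    index: AnnotationIndex,
    models: Sequence[str],
    N: int | None = None,
    min_d: int = 1,
) -> Iterator[ScoredPair]:
    """Stream one :class:`ScoredPair` per sharing pair with ``d >= min_d``."""
    bg = background_size(index, N)
    for a, b, d, m, n in enumerate_sharing_pairs(index):
        if d < min_d:
            continue
        case = OverlapCase(m=m, n=n, d=d, N=bg)
        triple = to_char(case)
        yield ScoredPair(
            entity_a=a,
            entity_b=b,
            d=d,
            m=m,
            n=n,
            R=triple.R,
            r=triple.r,
            lam=expected_overlap(case),
            within_boundary=within_boundary(case),
            scores=score_all(case, models),
        )


_BASE_COLUMNS = (
    "entity_a",
    "entity_b",
    "d",
    "m",
    "n",
    "R",
    "r",
    "lambda",
    "within_boundary",
)


def write_scores(
    stream: Iterable[ScoredPair], path_or_file, models: Sequence[str]
) -> int:
    """Write scored pairs as TSV (floats at 6 significant digits); returns
    the number of rows written.  An empty stream yields a header-only file.
    """
    own = not hasattr(path_or_file, "write")
    fh: IO[str] = (
        open(path_or_file, "w", encoding="utf-8") if own else path_or_file
    )
    count = 0
    try:
        fh.write("\t".join(_BASE_COLUMNS + tuple(models)) + "\n")
        for sp in stream:
            row = [
                sp.entity_a,
                sp.entity_b,
                str(sp.d),
                str(sp.m),
                str(sp.n),
                f"{sp.R:.6g}",
                f"{sp.r:.6g}",
                f"{sp.lam:.6g}",
                str(int(sp.within_boundary)),
            ]
            row.extend(f"{sp.scores[mid]:.6g}" for mid in models)
            fh.write("\t".join(row) + "\n")
            count += 1
    finally:
        if own:
            fh.close()
    return count
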