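"""Interval graph construction and maximal-clique enumeration.

Vertices are patient-level CNA segments (or bare intervals) on a single
chromosome; edges connect intersecting intervals.  Maximal cliques of an
interval graph are enumerated in O(n log n) by a single left-to-right
endpoint sweep over the sorted endpoints; a Bron-Kerbosch enumeration on
the explicit graph is kept as an independent test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .segment_io import CNASegment, GenomicInterval

__all__ = [
    "IntervalGraph",
    "MaximalClique",
    "build_interval_graph",
    "sweep_maximal_cliques",
    "brute_force_maximal_cliques",
    "clique_mcr",
    "clique_outer",
]

BRUTE_FORCE_CAP = 20

VertexInput = Sequence[GenomicInterval] | Sequence[CNASegment]


def _as_intervals(items: VertexInput) -> list[GenomicInterval]:
    out = []
    for item in items:
        out.append(item.interval if isinstance(item, CNASegment) else item)
    return out


def _check_single_chrom(intervals: Sequence[GenomicInterval]) -> None:
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")


@dataclass(frozen=True)
class MaximalClique:
    """A maximal set of pairwise-overlapping vertices.

    ``member_indices`` index into the input ordering, so cliques from the
    sweep and from the brute-force oracle compare by set equality.
    """

    member_indices: frozenset[int]
    members: tuple[object, ...]
    chrom: str
    alteration_type: str | None = None

    @property
    def intervals(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            m.interval if isinstance(m, CNASegment) else m for m in self.members
        )

    @property
    def patient_set(self) -> frozenset[str]:
        """Distinct patients among members (empty for bare intervals)."""
        return frozenset(
            m.patient_id for m in self.members if isinstance(m, CNASegment)
        )

    def __len__(self) -> int:
        return len(self.member_indices)


class IntervalGraph:
    """Explicit interval graph: vertex i <-> input item i, edges = overlaps."""

    def __init__(self, items: VertexInput):
        intervals = _as_intervals(items)
        _check_single_chrom(intervals)
        self.items = list(items)
        self.intervals = intervals
        g = nx.Graph()
        g.add_nodes_from(range(len(intervals)))
        for i in range(len(intervals)):
            for j in range(i + 1, len(intervals)):
                if intervals[i].overlaps(intervals[j]):
                    g.add_edge(i, j)
        self.graph = g

    @property
    def n_vertices(self) -> int:
        return len(self.intervals)

    def has_edge(self, u: int, v: int) -> bool:
        return self.graph.has_edge(u, v)


def build_interval_graph(items: VertexInput) -> IntervalGraph:
    """Build the explicit overlap graph (all-pairs; used for small inputs and
    as the substrate of the brute-force oracle)."""
    return IntervalGraph(items)


def _make_clique(indices: frozenset[int], items: list, intervals: list) -> MaximalClique:
    members = tuple(items[i] for i in sorted(indices))
    types = {
        m.alteration_type for m in members if isinstance(m, CNASegment)
    }
    return MaximalClique(
        member_indices=indices,
        members=members,
        chrom=intervals[next(iter(indices))].chrom,
        alteration_type=types.pop() if len(types) == 1 else None,
    )


def sweep_maximal_cliques(items: VertexInput) -> list[MaximalClique]:
    """Enumerate all maximal cliques by an endpoint sweep.

    Endpoints are sorted left to right; at equal coordinates end events are
    processed before start events (half-open semantics: touching intervals
    are not adjacent).  The active set is the set of intervals covering the
    sweep point.  When an end event is reached and at least one interval
    has started since the last emission, the active set -- taken before the
    ending interval is removed -- is a maximal clique.
    """
    items = list(items)
    if not items:
        return []
    intervals = _as_intervals(items)
    _check_single_chrom(intervals)

    END, START = 0, 1  # end events sort first at equal coordinates
    events: list[tuple[int, int, int]] = []
    for idx, iv in enumerate(intervals):
        events.append((iv.start, START, idx))
        events.append((iv.end, END, idx))
    events.sort()

    active: set[int] = set()
    started_since_emit = False
    cliques: list[MaximalClique] = []
    for _, kind, idx in events:
        if kind == START:
            active.add(idx)
            started_since_emit = True
        else:
            if started_since_emit:
                cliques.append(_make_clique(frozenset(active), items, intervals))
                started_since_emit = False
            active.remove(idx)
    return cliques


def brute_force_maximal_cliques(items: VertexInput) -> list[MaximalClique]:
    """Oracle: maximal cliques via Bron-Kerbosch (networkx) on the explicit
    graph.  Capped at 20 vertices; intended for tests only."""
    items = list(items)
    if len(items) > BRUTE_FORCE_CAP:
        raise ValueError(
            f"brute-force clique enumeration capped at {BRUTE_FORCE_CAP} intervals, "
            f"got {len(items)}"
        )
    if not items:
        return []
    graph = build_interval_graph(items)
    return [
        _make_clique(frozenset(clq), graph.items, graph.intervals)
        for clq in nx.find_cliques(graph.graph)
    ]


def clique_mcr(clique: MaximalClique) -> GenomicInterval:
    """Minimal common region: intersection of every member interval.

    Nonempty by the 1-D Helly property (members pairwise intersect).
    """
    if not clique.member_indices:
        raise ValueError("empty clique has no MCR")
    ivs = clique.intervals
    return GenomicInterval(
        clique.chrom,
        max(iv.start for iv in ivs),
        min(iv.end for iv in ivs),
    )


def clique_outer(clique: MaximalClique) -> GenomicInterval:
    """Outer span: union extent (min start to max end) of member intervals."""
    if not clique.member_indices:
        raise ValueError("empty clique has no outer span")
    ivs = clique.intervals
    return GenomicInterval(
        clique.chrom,
        min(iv.start for iv in ivs),
        max(iv.end for iv in ivs),
    )
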