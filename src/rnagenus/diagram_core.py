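"""Chord diagrams and the combinatorial primitives built on them.

A chord diagram is the backbone of an RNA molecule laid out on a line (or
circle) with an arc joining every base pair, all arcs drawn on the same
side.  Crossing arcs are the diagrammatic signature of a pseudoknot: two
arcs (i, j) and (k, l) cross iff i < k < j < l, the pattern that cannot
be drawn in the plane without intersection.

This module provides the conversion from :class:`SecondaryStructure` to
:class:`ChordDiagram`, crossing detection, the genus-preserving collapse
of stems ("parallel" arc runs) to single arcs — the *shadow* of a diagram
— and the concatenation/nesting combinators under which genus is additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .structure_io import SecondaryStructure

__all__ = [
    "Arc",
    "ChordDiagram",
    "from_structure",
    "crossings",
    "is_planar",
    "collapse_parallel",
    "concatenate",
    "nest",
]

Arc = tuple[int, int]


@dataclass(frozen=True)
class ChordDiagram:
    """Backbone points 1..n_points with a partial matching of arcs.

    Arcs are ``(left, right)`` tuples, ``left < right``; each point lies
    on at most one arc.
    """

    n_points: int
    arcs: frozenset[Arc] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_points < 0:
            raise ValueError(f"negative n_points {self.n_points}")
        object.__setattr__(self, "arcs", frozenset(self.arcs))
        seen: set[int] = set()
        for i, j in self.arcs:
            if not (1 <= i < j <= self.n_points):
                raise ValueError(
                    f"arc ({i},{j}) out of range for n_points {self.n_points}"
                )
            if i in seen or j in seen:
                raise ValueError(f"point {i if i in seen else j} lies on two arcs")
            seen.update((i, j))

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def sorted_arcs(self) -> list[Arc]:
        return sorted(self.arcs)


def from_structure(s: SecondaryStructure, keep_unpaired: bool = False) -> ChordDiagram:
    """Build the chord diagram of a structure.

    With ``keep_unpaired=False`` (the default) unpaired positions are
    dropped and the 2m paired positions are relabeled 1..2m preserving
    backbone order; isolated points do not affect the topology, but
    ``keep_unpaired=True`` retains them for position-resolved uses.
    """
    if keep_unpaired:
        return ChordDiagram(n_points=s.length, arcs=frozenset(s.pairs))
    points = sorted({p for pair in s.pairs for p in pair})
    relabel = {p: k for k, p in enumerate(points, start=1)}
    arcs = frozenset((relabel[i], relabel[j]) for i, j in s.pairs)
    return ChordDiagram(n_points=len(points), arcs=arcs)


def crossings(d: ChordDiagram) -> set[tuple[Arc, Arc]]:
    """All crossing arc pairs ((i,j),(k,l)) with i < k < j < l."""
    out: set[tuple[Arc, Arc]] = set()
    for a, b in combinations(d.sorted_arcs(), 2):
        (i, j), (k, l) = a, b
        if i < k < j < l:
            out.add((a, b))
    return out


def is_planar(d: ChordDiagram) -> bool:
    """True iff no two arcs cross (equivalently, genus 0)."""
    return not crossings(d)


def _compact(n_points: int, arcs: frozenset[Arc]) -> ChordDiagram:
    points = sorted({p for arc in arcs for p in arc})
    relabel = {p: k for k, p in enumerate(points, start=1)}
    return ChordDiagram(
        n_points=len(points),
        arcs=frozenset((relabel[i], relabel[j]) for i, j in arcs),
    )


def collapse_parallel(d: ChordDiagram) -> ChordDiagram:
    """Collapse every maximal run of parallel arcs to a single arc.

    A run is a stem {(i,j), (i+1,j-1), ...}; collapsing it leaves the
    genus unchanged.  Retained endpoints are relabeled compactly, and the
    collapse is iterated to a fixpoint (relabeling can bring previously
    separated arcs into adjacency), so the result is the diagram's shadow
    and the operation is idempotent.
    """
    current = _compact(d.n_points, d.arcs)
    while True:
        arcs = set(current.arcs)
        keep: set[Arc] = set()
        for i, j in sorted(arcs):
            if (i - 1, j + 1) in arcs:
                continue  # interior of a run; outermost arc represents it
            keep.add((i, j))
        nxt = _compact(current.n_points, frozenset(keep))
        if nxt.arcs == current.arcs and nxt.n_points == current.n_points:
            return nxt
        current = nxt


def concatenate(d1: ChordDiagram, d2: ChordDiagram) -> ChordDiagram:
    """Place ``d2``'s points after ``d1``'s on the backbone."""
    shift = d1.n_points
    arcs = set(d1.arcs) | {(i + shift, j + shift) for i, j in d2.arcs}
    return ChordDiagram(n_points=d1.n_points + d2.n_points, arcs=frozenset(arcs))


def nest(d1: ChordDiagram, d2: ChordDiagram) -> ChordDiagram:
    """Insert ``d2`` strictly inside an innermost arc of ``d1``.

    The host arc is the shortest (then leftmost) arc of ``d1``; ``d2``'s
    points are placed immediately after its left endpoint.  Genus is
    additive under this operation.
    """
    if not d1.arcs:
        raise ValueError("cannot nest into a diagram with no arcs")
    host = min(d1.arcs, key=lambda a: (a[1] - a[0], a[0]))
    cut = host[0]  # d2 inserted between cut and cut+1
    n2 = d2.n_points
    arcs: set[Arc] = set()
    for i, j in d1.arcs:
        arcs.add((i if i <= cut else i + n2, j if j <= cut else j + n2))
    arcs.update((i + cut, j + cut) for i, j in d2.arcs)
    return ChordDiagram(n_points=d1.n_points + n2, arcs=frozenset(arcs))
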