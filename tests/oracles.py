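"""Independent brute-force oracles used by the test suite.

``dart_genus`` computes the genus of a chord diagram by a construction
deliberately different from the package's sigma∘alpha boundary counting:
it builds the ribbon graph explicitly as a rotation system on darts
(half-edges) of the backbone cycle plus arc edges, traces the face
cycles, and applies the closed-surface Euler formula V - E + F = 2 - 2g.

``prefix_genus_bruteforce`` recomputes the genus trace one window at a
time with no incremental bookkeeping.
"""

from __future__ import annotations

from rnagenus.diagram_core import ChordDiagram


def dart_genus(d: ChordDiagram) -> int:
    """Genus of ``d`` via rotation-system face tracing and Euler's formula."""
    points = sorted({p for arc in d.arcs for p in arc})
    n = len(points)
    if n == 0:
        return 0
    relabel = {p: k for k, p in enumerate(points)}

    # edges: backbone cycle k -> k+1 mod n, then one edge per arc
    edges: list[tuple[int, int]] = [(k, (k + 1) % n) for k in range(n)]
    arc_edge_of: dict[int, int] = {}
    for i, j in sorted(d.arcs):
        a, b = relabel[i], relabel[j]
        arc_edge_of[a] = arc_edge_of[b] = len(edges)
        edges.append((a, b))

    # darts are (edge index, end): end 0 leaves edges[e][0], end 1 leaves
    # edges[e][1]; rotation at each vertex is (to-prev, arc, to-next)
    rotation: dict[int, list[tuple[int, int]]] = {v: [] for v in range(n)}
    for v in range(n):
        prev_edge = (v - 1) % n       # backbone edge (v-1, v)
        next_edge = v                 # backbone edge (v, v+1)
        rot = [(prev_edge, 1)]
        if v in arc_edge_of:
            e = arc_edge_of[v]
            rot.append((e, 0 if edges[e][0] == v else 1))
        rot.append((next_edge, 0))
        rotation[v] = rot

    def origin(dart: tuple[int, int]) -> int:
        e, end = dart
        return edges[e][end]

    def reverse(dart: tuple[int, int]) -> tuple[int, int]:
        e, end = dart
        return (e, 1 - end)

    next_in_rotation: dict[tuple[int, int], tuple[int, int]] = {}
    for v, rot in rotation.items():
        for idx, dart in enumerate(rot):
            next_in_rotation[dart] = rot[(idx + 1) % len(rot)]

    # face permutation phi(d) = rotation-successor of the reversed dart
    all_darts = [(e, end) for e in range(len(edges)) for end in (0, 1)]
    seen: set[tuple[int, int]] = set()
    faces = 0
    for start in all_darts:
        if start in seen:
            continue
        faces += 1
        dart = start
        while dart not in seen:
            seen.add(dart)
            dart = next_in_rotation[reverse(dart)]

    V, E, F = n, len(edges), faces
    chi = V - E + F
    assert chi % 2 == 0
    return (2 - chi) // 2


def prefix_genus_bruteforce(pairs, length: int) -> list[int]:
    """Genus trace computed window-by-window from scratch."""
    from rnagenus.genus_engine import genus_of_pairs

    out = []
    for i in range(1, length + 1):
        window = {(a, b) for a, b in pairs if b <= i}
        out.append(genus_of_pairs(window))
    return out
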