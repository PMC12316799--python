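"""Genus of chord diagrams by fat-graph boundary counting.

Thicken a chord diagram into a ribbon (fat) graph: the closed backbone
becomes a cycle of 2m paired points and each arc a band joining two of
them.  The number of boundary components b of the thickened surface is
the number of cycles of the permutation sigma∘alpha, where sigma is the
backbone cycle (1 2 ... 2m) and alpha is the product of the m arc
transpositions.  The genus of the closed surface obtained by capping the
boundaries is then

    g = (m - b + 1) / 2,

the minimal genus of an orientable surface on which the diagram can be
drawn without arc crossings: 0 for pseudoknot-free (planar) structures,
1 for an H-type pseudoknot or a kissing hairpin, and so on.  The Euler
characteristic is reported under the one-puncture convention
chi = 2 - 2g - p with p = 1 (one closed backbone), i.e. chi = 1 - 2g,
which gives the familiar chi = -1 for the genus-1 kissing hairpin.

Two position-resolved generalizations are provided: the *genus trace*
g(i), the genus of the sub-structure restricted to the first i residues,
and the *fingerprint matrix* G = (g_ij), the genus of every sub-chain
window [i..j].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diagram_core import ChordDiagram
from .structure_io import SecondaryStructure

__all__ = [
    "GenusResult",
    "GenusTrace",
    "FingerprintMatrix",
    "boundary_components",
    "genus",
    "genus_of_pairs",
    "genus_trace",
    "fingerprint",
]


@dataclass(frozen=True)
class GenusResult:
    """Genus bookkeeping of a diagram: arcs m, boundaries b, genus g, chi."""

    m: int
    b: int
    g: int
    chi: int

    def __post_init__(self) -> None:
        assert self.g == (self.m - self.b + 1) // 2 or self.m == 0
        assert self.chi == 1 - 2 * self.g


@dataclass(frozen=True)
class GenusTrace:
    """Per-position prefix genus g(1..L); non-decreasing, ends at the total."""

    values: tuple[int, ...]

    @property
    def total(self) -> int:
        return self.values[-1] if self.values else 0


@dataclass(frozen=True)
class FingerprintMatrix:
    """Window genus g_ij for every sub-chain [i..j] (upper triangle).

    ``G`` is an L x L integer array, 0-indexed as ``G[i-1, j-1]``; entries
    below the diagonal are 0 by convention.
    """

    G: np.ndarray

    @property
    def length(self) -> int:
        return self.G.shape[0]

    @property
    def total(self) -> int:
        return int(self.G[0, -1]) if self.length else 0


def boundary_components(d: ChordDiagram) -> int:
    """Count boundary components of the fat graph of ``d``.

    The diagram is restricted to its 2m paired points, relabeled 1..2m in
    backbone order; the count is the number of cycles of sigma∘alpha
    (alpha applied first).  A diagram with no arcs has a single boundary
    (the disk), so m = 0 returns 1.
    """
    points = sorted({p for arc in d.arcs for p in arc})
    n = len(points)
    if n == 0:
        return 1
    relabel = {p: k for k, p in enumerate(points)}
    # alpha: arc involution; sigma: i -> i+1 mod n along the backbone cycle
    alpha = list(range(n))
    for i, j in d.arcs:
        a, b = relabel[i], relabel[j]
        alpha[a], alpha[b] = b, a
    perm = [(alpha[i] + 1) % n for i in range(n)]
    seen = [False] * n
    cycles = 0
    for start in range(n):
        if seen[start]:
            continue
        cycles += 1
        k = start
        while not seen[k]:
            seen[k] = True
            k = perm[k]
    return cycles


def genus(d: ChordDiagram) -> GenusResult:
    """Genus of a chord diagram via boundary-component counting."""
    m = d.n_arcs
    b = boundary_components(d)
    g = 0 if m == 0 else (m - b + 1) // 2
    if m and (m - b + 1) % 2:
        raise AssertionError(f"parity violation: m={m}, b={b}")  # unreachable
    return GenusResult(m=m, b=b, g=g, chi=1 - 2 * g)


def genus_of_pairs(pairs) -> int:
    """Genus of a bare pair set (positions need not be compact)."""
    pairs = frozenset(tuple(p) for p in pairs)
    if not pairs:
        return 0
    n = max(p for pair in pairs for p in pair)
    return genus(ChordDiagram(n_points=n, arcs=pairs)).g


def genus_trace(s: SecondaryStructure) -> GenusTrace:
    """Prefix genus g(i) for i = 1..L.

    g(i) is the genus of the diagram induced by pairs lying entirely in
    [1..i]; the trace is non-decreasing and g(L) is the total genus.
    """
    by_close: dict[int, list[tuple[int, int]]] = {}
    for i, j in s.pairs:
        by_close.setdefault(j, []).append((i, j))
    active: set[tuple[int, int]] = set()
    values: list[int] = []
    g_prev = 0
    for pos in range(1, s.length + 1):
        closed = by_close.get(pos)
        if closed:
            active.update(closed)
            g_prev = genus_of_pairs(active)
        values.append(g_prev)
    return GenusTrace(values=tuple(values))


def fingerprint(s: SecondaryStructure, max_length: int = 400) -> FingerprintMatrix:
    """Fingerprint matrix G with G[i][j] = genus of pairs inside [i..j].

    Cost is O(L^2) genus evaluations; structures longer than
    ``max_length`` are rejected (raise the cap explicitly if wanted).
    Row 1 of the matrix equals the genus trace.
    """
    L = s.length
    if L > max_length:
        raise ValueError(
            f"structure length {L} exceeds the fingerprint cap {max_length}; "
            "pass max_length to raise it (cost grows as L^2)"
        )
    G = np.zeros((L, L), dtype=int)
    pairs = sorted(s.pairs)
    for i in range(1, L + 1):
        window = [p for p in pairs if p[0] >= i]
        by_close: dict[int, list[tuple[int, int]]] = {}
        for p in window:
            by_close.setdefault(p[1], []).append(p)
        active: set[tuple[int, int]] = set()
        g_prev = 0
        for j in range(i, L + 1):
            closed = by_close.get(j)
            if closed:
                active.update(closed)
                g_prev = genus_of_pairs(active)
            G[i - 1, j - 1] = g_prev
    return FingerprintMatrix(G=G)
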