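"""Generators for structures and diagrams with known topology.

Every fixture used in testing and demonstration is built here
programmatically: hairpins (genus 0), H-type pseudoknots and kissing
hairpins (genus 1), two-domain chains, uniform random chord matchings,
and structures assembled to hit an exact target genus by concatenating
and nesting genus-1 blocks.  Designed sequences use G/C-rich stems and
A/U kissing segments so the intended fold is the unambiguous optimum of
the shipped energy table, with no cross-talk between stem and loop
alphabets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diagram_core import ChordDiagram, concatenate, nest
from .structure_io import SecondaryStructure

__all__ = [
    "FixtureSpec",
    "make_hairpin",
    "make_kissing_hairpin",
    "make_h_pseudoknot",
    "make_two_domain",
    "random_matching",
    "random_structure_with_genus",
]

_COMPLEMENT = {"G": "C", "C": "G", "A": "U", "U": "A"}

#: 6-point shadow of the kissing hairpin: two hairpin arcs whose loops
#: are joined by the kissing arc; genus 1.
KISSING_SHADOW = frozenset({(1, 3), (2, 5), (4, 6)})


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request consumed by the CLI ``make-fixture``."""

    kind: str  # hairpin | h_pseudoknot | kissing_hairpin | two_domain
    stems: tuple[int, ...] = (3, 3, 3)
    loops: tuple[int, ...] = (3, 3, 3)
    design_sequence: bool = False


def _design(length: int, pairs, stem_char: dict[int, str]) -> str:
    """Fill a sequence: designated bases from stem_char, partners by
    complementarity, everything else A (inert under canonical rules only
    when it cannot reach a U — callers choose alphabets to keep it so)."""
    seq = ["A"] * length
    for pos, ch in stem_char.items():
        seq[pos - 1] = ch
    for i, j in pairs:
        seq[j - 1] = _COMPLEMENT[seq[i - 1]]
    return "".join(seq)


def make_hairpin(stem: int = 3, loop: int = 3, design_sequence: bool = False
                 ) -> SecondaryStructure:
    """A single hairpin: ``stem`` stacked pairs around a ``loop``-nt loop."""
    if stem < 1 or loop < 3:
        raise ValueError("need stem >= 1 and loop >= 3")
    L = 2 * stem + loop
    pairs = frozenset((i, L + 1 - i) for i in range(1, stem + 1))
    seq = ""
    if design_sequence:
        # all-G 5' strand: strong GC/GC stacks, loop A's cannot pair
        chars = {i: "G" for i in range(1, stem + 1)}
        seq = _design(L, pairs, chars)
    return SecondaryStructure(length=L, pairs=pairs, sequence=seq)


def make_kissing_hairpin(
    stems: tuple[int, int, int] = (3, 3, 3),
    design_sequence: bool = False,
) -> SecondaryStructure:
    """A kissing hairpin: two hairpins whose loops pair with each other.

    ``stems = (s1, s2, s3)``: s1 and s3 are the two hairpin stems, s2 the
    kissing interaction joining their loops.  The collapse of all stems
    gives the 6-point shadow {(1,3), (2,5), (4,6)} of genus 1.  With
    ``design_sequence=True`` the hairpin stems are G/C and the kissing
    segment A/U, so the three helipoints cannot cross-pair.
    """
    s1, s2, s3 = stems
    if min(stems) < 1:
        raise ValueError("stem lengths must be >= 1")
    L = 2 * (s1 + s2 + s3)
    p = 2 * s1 + s2 + 1  # start of the second hairpin's 5' strand
    stem1 = [(i, 2 * s1 + s2 + 1 - i) for i in range(1, s1 + 1)]
    kissing = [(s1 + j, p + s3 + s2 - j) for j in range(1, s2 + 1)]
    stem2 = [(p + k - 1, p + 2 * s3 + s2 - k) for k in range(1, s3 + 1)]
    pairs = frozenset(stem1) | frozenset(kissing) | frozenset(stem2)
    seq = ""
    if design_sequence:
        # alphabet chosen so the three intended stems are the ONLY
        # maximal helipoints and the full fold is the unique free-energy
        # optimum: stem 1 all-G, kissing A/U alternating, stem 2 G then
        # C's (the G cap breaks the cross-helix between the two G/C
        # stems that an all-uniform design would allow)
        chars: dict[int, str] = {}
        for i, _ in stem1:
            chars[i] = "G"
        for k, (i, _) in enumerate(stem2):
            chars[i] = "G" if k == 0 else "C"
        for k, (i, _) in enumerate(kissing):
            chars[i] = "A" if k % 2 == 0 else "U"
        seq = _design(L, pairs, chars)
    return SecondaryStructure(length=L, pairs=pairs, sequence=seq)


def make_h_pseudoknot(
    stems: tuple[int, int] = (3, 3),
    loops: tuple[int, int, int] = (3, 3, 3),
    design_sequence: bool = False,
) -> SecondaryStructure:
    """An H-type pseudoknot: stem 1 pairs region A with C, stem 2 pairs
    B with D, in backbone order A B C D — the crossing-pair shadow
    {(1,3), (2,4)} of genus 1."""
    s1, s2 = stems
    l1, l2, l3 = loops
    if min(stems) < 1 or min(loops) < 1:
        raise ValueError("stems must be >= 1 and loops >= 1")
    L = 2 * (s1 + s2) + l1 + l2 + l3
    a = 0
    b = s1 + l1
    c = b + s2 + l2
    d = c + s1 + l3
    stem1 = [(a + i, c + s1 + 1 - i) for i in range(1, s1 + 1)]
    stem2 = [(b + i, d + s2 + 1 - i) for i in range(1, s2 + 1)]
    pairs = frozenset(stem1) | frozenset(stem2)
    seq = ""
    if design_sequence:
        # stem 1 on the G/C alphabet, stem 2 on A/U: no cross-talk
        chars = {}
        for i, _ in stem1:
            chars[i] = "G"
        for i, _ in stem2:
            chars[i] = "A"
        seq = _design(L, pairs, chars)
    return SecondaryStructure(length=L, pairs=pairs, sequence=seq)


def make_two_domain(
    linker: int = 6,
    stems: tuple[int, int, int] = (2, 2, 2),
) -> SecondaryStructure:
    """Two kissing-hairpin domains joined by an unpaired linker.

    Total genus 2, with the genus trace climbing to 1 inside the first
    domain, holding a plateau across the linker, and reaching 2 in the
    second — the minimal two-plateau fixture for trace-smoothing checks.
    """
    dom = make_kissing_hairpin(stems=stems)
    off = dom.length + linker
    pairs = set(dom.pairs)
    pairs.update((i + off, j + off) for i, j in dom.pairs)
    return SecondaryStructure(length=2 * dom.length + linker,
                              pairs=frozenset(pairs))


def random_matching(n_points: int, n_chords: int, seed=None) -> ChordDiagram:
    """A uniform random partial matching with exactly ``n_chords`` chords.

    Uniformity over all C(n, 2k)(2k-1)!! such matchings: the 2k matched
    points are a uniform subset, and they are paired by repeatedly
    joining the smallest free point to a uniformly random other free
    point (which makes every perfect matching of the subset equally
    likely).
    """
    if 2 * n_chords > n_points:
        raise ValueError(
            f"cannot place {n_chords} chords on {n_points} points"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(n_points, size=2 * n_chords, replace=False) + 1)
    free = list(chosen)
    arcs: set[tuple[int, int]] = set()
    while free:
        left = free.pop(0)
        partner = free.pop(int(rng.integers(len(free))))
        arcs.add((left, partner))
    return ChordDiagram(n_points=n_points, arcs=frozenset(arcs))


def _genus1_block(rng: np.random.Generator) -> ChordDiagram:
    """A random irreducible genus-1 block: crossing pair or kissing shadow."""
    if rng.random() < 0.5:
        return ChordDiagram(n_points=4, arcs=frozenset({(1, 3), (2, 4)}))
    return ChordDiagram(n_points=6, arcs=KISSING_SHADOW)


def _planar_block(rng: np.random.Generator) -> ChordDiagram:
    """A small random planar (genus-0) block: nested or serial arcs."""
    k = int(rng.integers(1, 4))
    if rng.random() < 0.5:  # nested stack of k arcs
        arcs = {(i, 2 * k + 1 - i) for i in range(1, k + 1)}
    else:  # k serial arcs
        arcs = {(2 * i - 1, 2 * i) for i in range(1, k + 1)}
    return ChordDiagram(n_points=2 * k, arcs=frozenset(arcs))


def random_structure_with_genus(
    target_g: int, n_filler: int = 3, seed=None
) -> SecondaryStructure:
    """A structure of exact genus ``target_g`` built by composition.

    ``target_g`` genus-1 irreducible blocks (crossing pairs or kissing
    shadows) and ``n_filler`` planar blocks are combined by random
    concatenation or nesting — both genus-additive — so the total genus
    is exactly the target and the genus trace has ``target_g`` unit
    jumps.
    """
    if target_g < 0:
        raise ValueError("target genus must be >= 0")
    rng = np.random.default_rng(seed)
    blocks = [_genus1_block(rng) for _ in range(target_g)]
    blocks += [_planar_block(rng) for _ in range(n_filler)]
    order = rng.permutation(len(blocks))
    diagram = ChordDiagram(n_points=0)
    for bi in order:
        block = blocks[bi]
        if diagram.arcs and rng.random() < 0.5:
            diagram = nest(diagram, block)
        else:
            diagram = concatenate(diagram, block)
    return SecondaryStructure(length=max(diagram.n_points, 1),
                              pairs=diagram.arcs)
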