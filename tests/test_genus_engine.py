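from collections import Counter

import numpy as np
import pytest

from oracles import dart_genus, prefix_genus_bruteforce
from rnagenus.diagram_core import (ChordDiagram, collapse_parallel,
                                   crossings, from_structure)
from rnagenus.genus_engine import (boundary_components, fingerprint, genus,
                                   genus_trace)
from rnagenus.matrix_model import enumerate_partial_matchings
from rnagenus.structure_io import SecondaryStructure
from rnagenus.synthetic import (make_kissing_hairpin, make_two_domain,
                                random_matching,
                                random_structure_with_genus)


@pytest.mark.parametrize(
    "arcs,b",
    [
        (set(), 1),                      # disk
        ({(1, 2)}, 2),                   # single chord
        ({(1, 3), (2, 4)}, 1),           # crossing pair (hand-traced)
        ({(1, 4), (2, 3)}, 3),           # nested pair (hand-traced)
    ],
)
def test_boundary_component_counts(arcs, b):
    n = max((p for a in arcs for p in a), default=0)
    assert boundary_components(ChordDiagram(n, arcs)) == b


def test_kissing_hairpin_shadow_genus_and_chi(kissing_shadow):
    res = genus(kissing_shadow)
    assert (res.m, res.b, res.g, res.chi) == (3, 2, 1, -1)
    assert crossings(kissing_shadow)  # cannot embed crossing-free at g=0


def test_nested_only_diagram_is_genus_zero():
    d = ChordDiagram(8, {(1, 8), (2, 7), (3, 6), (4, 5)})
    assert genus(d).g == 0


def test_genus_histogram_of_perfect_matchings_on_6_points():
    hist = Counter(
        genus(d).g for d in enumerate_partial_matchings(6, perfect_only=True)
    )
    # 15 matchings total; the 5 planar ones are the Catalan number C_3
    assert hist == {0: 5, 1: 10}


def test_genus_zero_iff_crossing_free_all_matchings_up_to_4_chords():
    for n in (2, 4, 6, 8):
        for d in enumerate_partial_matchings(n, perfect_only=True):
            assert (genus(d).g == 0) == (not crossings(d))


def test_genus_agrees_with_independent_dart_oracle():
    for n in range(0, 9):
        for d in enumerate_partial_matchings(n):
            assert genus(d).g == dart_genus(d)


@pytest.mark.parametrize("seed", range(5))
def test_genus_bounds_and_parity(seed):
    d = random_matching(26, 12, seed=seed)
    res = genus(d)
    assert 0 <= res.g <= res.m // 2
    assert (res.m - res.b + 1) % 2 == 0
    assert res.chi == 1 - 2 * res.g


def test_genus_invariant_under_unpaired_insertion(kissing_shadow):
    spread = SecondaryStructure(
        length=12, pairs={(1, 5), (3, 9), (7, 11)}  # shadow with gaps
    )
    assert genus(from_structure(spread)).g == genus(kissing_shadow).g


def test_composition_order_convention_is_immaterial():
    # counting cycles of alpha∘sigma instead of sigma∘alpha gives the
    # same boundary count (the permutations are conjugate)
    for d in enumerate_partial_matchings(6, perfect_only=True):
        points = sorted({p for a in d.arcs for p in a})
        n = len(points)
        alpha = list(range(n))
        for i, j in d.arcs:
            a, b = points.index(i), points.index(j)
            alpha[a], alpha[b] = b, a
        perm = [alpha[(i + 1) % n] for i in range(n)]  # alpha after sigma
        seen, cycles = [False] * n, 0
        for s in range(n):
            if not seen[s]:
                cycles += 1
                k = s
                while not seen[k]:
                    seen[k] = True
                    k = perm[k]
        assert cycles == boundary_components(d)


def test_genus_trace_kissing_hairpin_and_bruteforce(kissing_hairpin):
    tr = genus_trace(kissing_hairpin)
    vals = list(tr.values)
    assert vals == prefix_genus_bruteforce(kissing_hairpin.pairs,
                                           kissing_hairpin.length)
    assert all(a <= b for a, b in zip(vals, vals[1:]))  # non-decreasing
    assert tr.total == 1
    # the jump happens exactly when the first arc closing a crossing set
    # completes: pair (6,13) closes against stems 1 and the kissing block
    jumps = [i + 1 for i, (a, b) in enumerate(zip([0] + vals, vals)) if b > a]
    assert jumps == [13]


def test_genus_trace_no_pairs_is_all_zero():
    tr = genus_trace(SecondaryStructure(length=7))
    assert tr.values == (0,) * 7


def test_genus_trace_of_concatenated_genus1_blocks_has_two_unit_jumps():
    s = make_two_domain(linker=4, stems=(2, 2, 2))
    vals = list(genus_trace(s).values)
    assert vals[-1] == 2
    jumps = [b - a for a, b in zip(vals, vals[1:]) if b != a]
    assert jumps == [1, 1]


def test_fingerprint_zero_matrix_and_cap():
    fp = fingerprint(SecondaryStructure(length=5))
    assert not fp.G.any()
    with pytest.raises(ValueError, match="cap"):
        fingerprint(SecondaryStructure(length=50), max_length=10)


def test_fingerprint_kissing_hairpin_windows(kissing_hairpin):
    fp = fingerprint(kissing_hairpin)
    L = kissing_hairpin.length
    assert fp.G[0, L - 1] == 1
    # windows covering a single stem see a planar sub-structure
    assert fp.G[0, 9 - 1] == 0    # stem 1 only
    assert fp.G[10 - 1, L - 1] == 0  # stem 2 only


@pytest.mark.parametrize("seed", range(4))
def test_fingerprint_first_row_is_genus_trace_and_window_monotone(seed):
    s = random_structure_with_genus(2, n_filler=2, seed=seed)
    fp = fingerprint(s)
    assert tuple(fp.G[0]) == genus_trace(s).values
    # widening a window in either direction cannot reduce the genus
    G = fp.G
    assert np.all(G[:, 1:] >= G[:, :-1])
    assert np.all(G[:-1, :] >= G[1:, :])


def test_collapse_preserves_genus_on_deep_stems():
    kh = make_kissing_hairpin(stems=(4, 3, 5))
    d = from_structure(kh)
    assert genus(d).g == genus(collapse_parallel(d)).g == 1
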