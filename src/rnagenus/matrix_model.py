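"""Genus-resolved chord-diagram expansion of the toy partition functions.

The Gaussian average Z_n(a) = <(1+x)^n> over a weight exp(-x^2/2a)
expands into a sum over partial chord matchings of n marked points on a
circle: a diagram with k chords contributes a^k, so

    Z_2(a) = 1 + a,        Z_4(a) = 1 + 6a + 3a^2.

The N x N Hermitian-matrix version Z_n(a, N) refines this by topology:
each diagram is additionally weighted by N^(-2g) where g is its genus,
separating planar from pseudoknotted configurations:

    Z_4(a, N) = 1 + 6a + 2a^2 + a^2/N^2,

the a^2/N^2 term being the single crossing two-chord diagram.  At N = 1
the genus weight disappears and the two series coincide.

This module never evaluates an integral: it enumerates the partial
matchings exhaustively and computes each diagram's genus with the
boundary-counting engine, which is exactly what the integrals generate.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial
from typing import Iterator

from .diagram_core import ChordDiagram
from .genus_engine import genus

__all__ = [
    "ExpansionPolynomial",
    "enumerate_partial_matchings",
    "expansion_polynomial",
    "evaluate",
    "n_partial_matchings",
]

DEFAULT_CAP = 12  # matchings grow like the telephone numbers (n=12: 140152)


def n_partial_matchings(n: int) -> int:
    """Closed-form count of partial matchings: sum_k n!/(k! (n-2k)! 2^k)."""
    return sum(
        factorial(n) // (factorial(k) * factorial(n - 2 * k) * 2**k)
        for k in range(n // 2 + 1)
    )


def enumerate_partial_matchings(
    n: int, cap: int = DEFAULT_CAP, perfect_only: bool = False
) -> Iterator[ChordDiagram]:
    """Yield every partial matching of n points exactly once.

    Deterministic order: the smallest free point is either left unpaired
    (first branch, skipped when ``perfect_only``) or paired with each
    larger free point in ascending order.
    """
    if n < 0:
        raise ValueError(f"negative n {n}")
    if n > cap:
        raise ValueError(
            f"n={n} exceeds the enumeration cap {cap} "
            "(double-factorial growth); pass cap to raise it"
        )

    def rec(free: tuple[int, ...], arcs: tuple[tuple[int, int], ...]):
        if not free:
            yield arcs
            return
        head, rest = free[0], free[1:]
        if not perfect_only:
            yield from rec(rest, arcs)
        for idx, partner in enumerate(rest):
            yield from rec(
                rest[:idx] + rest[idx + 1:], arcs + ((head, partner),)
            )

    if perfect_only and n % 2:
        return
    for arcs in rec(tuple(range(1, n + 1)), ()):
        yield ChordDiagram(n_points=n, arcs=frozenset(arcs))


@dataclass(frozen=True)
class ExpansionPolynomial:
    """Diagram counts by (chord count k, genus g) for n marked points.

    Evaluating sum counts * a^k * N^(-2g) reproduces Z_n(a, N); at N = 1
    it collapses to the purely combinatorial 1-D series Z_n(a).
    """

    n: int
    coeffs: dict[tuple[int, int], int]

    def coefficient(self, k: int, g: int) -> int:
        return self.coeffs.get((k, g), 0)

    def planar_series(self) -> dict[int, int]:
        """a^k coefficients of the genus-0 (leading large-N) part."""
        return {k: c for (k, g), c in sorted(self.coeffs.items()) if g == 0}

    def series_1d(self) -> dict[int, int]:
        """a^k coefficients of the N = 1 series (all genera summed)."""
        out: dict[int, int] = {}
        for (k, _), c in self.coeffs.items():
            out[k] = out.get(k, 0) + c
        return out


def expansion_polynomial(n: int, cap: int = DEFAULT_CAP) -> ExpansionPolynomial:
    """Enumerate all partial matchings of n points, tallied by (k, genus)."""
    coeffs: dict[tuple[int, int], int] = {}
    for d in enumerate_partial_matchings(n, cap=cap):
        key = (d.n_arcs, genus(d).g)
        coeffs[key] = coeffs.get(key, 0) + 1
    return ExpansionPolynomial(n=n, coeffs=coeffs)


def evaluate(poly: ExpansionPolynomial, a: float, N: float = 1.0) -> float:
    """Numeric value of Z_n(a, N) = sum counts * a^k * N^(-2g)."""
    if a <= 0 or N <= 0:
        raise ValueError("a and N must be positive")
    return float(
        sum(c * a**k * N ** (-2 * g) for (k, g), c in poly.coeffs.items())
    )


def series_1d_closed_form(n: int) -> dict[int, int]:
    """Independent closed form for the 1-D series: C(n, 2k) (2k-1)!!."""
    out = {}
    for k in range(n // 2 + 1):
        dfact = 1
        for odd in range(2 * k - 1, 0, -2):
            dfact *= odd
        out[k] = comb(n, 2 * k) * dfact
    return out
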