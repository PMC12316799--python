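"""Read and write pseudoknotted RNA secondary structures.

Supported text formats:

* extended dot-bracket — ``.`` for unpaired positions and matched bracket
  families ``()``, ``[]``, ``{}``, ``<>``, then ``Aa``, ``Bb``, ... for
  structures whose arcs cross in more than four mutually crossing layers;
* BPSEQ — one ``position base partner`` record per line, 0 = unpaired;
* CT — the 6-column connectivity table used by mfold/RNAstructure.

All coordinates are 1-based and inclusive, matching the BPSEQ/CT
convention.  The in-memory representation is :class:`SecondaryStructure`,
a sequence plus a set of base pairs — the sparse form of the contact
matrix ``C`` with ``C[i][j] = 1`` iff ``i`` and ``j`` are paired.  Each
position may pair with at most one partner (row/column sums of ``C`` are
at most 1), which every reader enforces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "SecondaryStructure",
    "StructureParseError",
    "BRACKET_FAMILIES",
    "read_dotbracket",
    "write_dotbracket",
    "read_bpseq",
    "read_ct",
    "write_bpseq",
    "write_ct",
    "clean_sequence",
]

RNA_ALPHABET = frozenset("ACGU")

#: Ordered bracket families for extended dot-bracket notation.  The first
#: four are the conventional pseudoknot families; uppercase/lowercase
#: letter pairs extend the alphabet for deeply crossing structures.
BRACKET_FAMILIES: tuple[tuple[str, str], ...] = (
    ("(", ")"),
    ("[", "]"),
    ("{", "}"),
    ("<", ">"),
) + tuple((chr(ord("A") + k), chr(ord("a") + k)) for k in range(26))

_OPEN = {o: idx for idx, (o, _) in enumerate(BRACKET_FAMILIES)}
_CLOSE = {c: idx for idx, (_, c) in enumerate(BRACKET_FAMILIES)}

#: Ribonucleotide replacement policy for non-canonical one-letter codes
#: (unknown/modified nucleosides in database exports): N, X, F, M -> A and
#: V -> G.  Applied only when a reader is asked to, never silently.
REPLACEMENT_POLICY = {"N": "A", "X": "A", "F": "A", "M": "A", "V": "G"}


class StructureParseError(ValueError):
    """Raised when a structure file or string cannot be validated."""


def clean_sequence(seq: str, *, replace_noncanonical: bool = False) -> str:
    """Uppercase ``seq``, map T->U, and validate against {A, C, G, U}.

    With ``replace_noncanonical=True`` the replacement policy
    (N, X, F, M -> A; V -> G) is applied before validation; otherwise any
    non-canonical character raises :class:`StructureParseError`.
    """
    out = []
    for pos, ch in enumerate(seq.strip().upper(), start=1):
        if ch == "T":
            ch = "U"
        if ch not in RNA_ALPHABET:
            if replace_noncanonical and ch in REPLACEMENT_POLICY:
                ch = REPLACEMENT_POLICY[ch]
            else:
                raise StructureParseError(
                    f"non-canonical base {ch!r} at position {pos}; pass "
                    "replace_noncanonical=True to apply the N/X/F/M->A, V->G policy"
                )
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class SecondaryStructure:
    """An RNA secondary structure: backbone length, base pairs, sequence.

    ``pairs`` holds 1-based ``(i, j)`` tuples with ``i < j``; each
    position appears in at most one pair.  ``sequence`` may be empty when
    only the pairing topology is known.
    """

    length: int
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"negative length {self.length}")
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        seen: set[int] = set()
        for i, j in sorted(self.pairs):
            if not (1 <= i < j <= self.length):
                raise ValueError(
                    f"pair ({i},{j}) out of range for length {self.length} "
                    "(pairs must satisfy 1 <= i < j <= length)"
                )
            if i in seen or j in seen:
                pos = i if i in seen else j
                raise ValueError(f"position {pos} paired with more than one partner")
            seen.update((i, j))
        if self.sequence and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner_array(self) -> list[int]:
        """Partner of each position (0 = unpaired), index 1..length."""
        partner = [0] * (self.length + 1)
        for i, j in self.pairs:
            partner[i], partner[j] = j, i
        return partner


def read_dotbracket(text: str, sequence: str | None = None,
                    *, replace_noncanonical: bool = False) -> SecondaryStructure:
    """Parse an extended dot-bracket string into a :class:`SecondaryStructure`.

    Each bracket family is matched with an independent stack, so crossing
    arcs are expressed by putting them in different families, e.g.
    ``"([)]"`` -> pairs {(1,3), (2,4)}.
    """
    text = text.strip()
    stacks: dict[int, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(text, start=1):
        if ch in ".-:,_~":  # common unpaired markers in the wild
            continue
        if ch in _OPEN:
            stacks.setdefault(_OPEN[ch], []).append(pos)
        elif ch in _CLOSE:
            fam = _CLOSE[ch]
            if not stacks.get(fam):
                o, c = BRACKET_FAMILIES[fam]
                raise StructureParseError(
                    f"unbalanced {c!r} at position {pos}: no open {o!r} in family {o}{c}"
                )
            pairs.add((stacks[fam].pop(), pos))
        else:
            raise StructureParseError(f"unknown character {ch!r} at position {pos}")
    for fam, stack in stacks.items():
        if stack:
            o, c = BRACKET_FAMILIES[fam]
            raise StructureParseError(
                f"unbalanced {o!r} at position {stack[-1]} in family {o}{c}: never closed"
            )
    seq = clean_sequence(sequence, replace_noncanonical=replace_noncanonical) if sequence else ""
    if seq and len(seq) != len(text):
        raise StructureParseError(
            f"sequence length {len(seq)} != structure length {len(text)}"
        )
    return SecondaryStructure(length=len(text), pairs=frozenset(pairs), sequence=seq)


def _crossing(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = sorted((a, b))
    return i < k < j < l


def write_dotbracket(s: SecondaryStructure) -> str:
    """Render a structure as an extended dot-bracket string.

    Bracket layers are assigned by greedy coloring of the arc-crossing
    conflict graph: arcs are processed in order of left endpoint and take
    the lowest layer not used by any already-colored arc they cross.  The
    output round-trips: ``read_dotbracket(write_dotbracket(s))``
    reproduces ``s.pairs`` exactly.
    """
    arcs = sorted(s.pairs)
    layer: dict[tuple[int, int], int] = {}
    for arc in arcs:
        used = {layer[prev] for prev in layer if _crossing(arc, prev)}
        lvl = 0
        while lvl in used:
            lvl += 1
        if lvl >= len(BRACKET_FAMILIES):
            raise StructureParseError(
                f"structure needs {lvl + 1} crossing layers; only "
                f"{len(BRACKET_FAMILIES)} bracket families are supported"
            )
        layer[arc] = lvl
    chars = ["."] * s.length
    for (i, j), lvl in layer.items():
        o, c = BRACKET_FAMILIES[lvl]
        chars[i - 1], chars[j - 1] = o, c
    return "".join(chars)


def _pairs_from_partner_records(
    records: list[tuple[int, str, int]], *, replace_noncanonical: bool
) -> SecondaryStructure:
    """Validate (position, base, partner) rows shared by BPSEQ and CT."""
    n = len(records)
    for row, (pos, _, _) in enumerate(records, start=1):
        if pos != row:
            raise StructureParseError(
                f"non-contiguous positions: expected {row}, found {pos}"
            )
    partner = {pos: p for pos, _, p in records}
    bad = []
    pairs: set[tuple[int, int]] = set()
    for pos, _, p in records:
        if p == 0:
            continue
        if not (1 <= p <= n) or p == pos:
            raise StructureParseError(
                f"position {pos}: partner {p} out of range for length {n}"
            )
        if partner.get(p) != pos:
            bad.append(pos)
            continue
        pairs.add((min(pos, p), max(pos, p)))
    if bad:
        raise StructureParseError(
            "asymmetric pairing records at positions " + ", ".join(map(str, bad))
        )
    raw_seq = "".join(base for _, base, _ in records)
    if set(raw_seq) == {"N"}:
        # topology-only file (all-placeholder bases, as written for
        # structures without a sequence)
        seq = ""
    else:
        seq = clean_sequence(raw_seq, replace_noncanonical=replace_noncanonical)
    return SecondaryStructure(length=n, pairs=frozenset(pairs), sequence=seq)


def read_bpseq(lines: Iterable[str] | str,
               *, replace_noncanonical: bool = False) -> SecondaryStructure:
    """Parse BPSEQ records (``position base partner``, 0 = unpaired)."""
    if isinstance(lines, str):
        lines = lines.splitlines()
    records: list[tuple[int, str, int]] = []
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise StructureParseError(f"malformed BPSEQ row: {line!r}")
        try:
            records.append((int(fields[0]), fields[1], int(fields[2])))
        except ValueError as exc:
            raise StructureParseError(f"malformed BPSEQ row: {line!r}") from exc
    if not records:
        raise StructureParseError("empty BPSEQ input")
    return _pairs_from_partner_records(records, replace_noncanonical=replace_noncanonical)


def read_ct(lines: Iterable[str] | str,
            *, replace_noncanonical: bool = False) -> SecondaryStructure:
    """Parse a CT connectivity table (6 columns, header line with length)."""
    if isinstance(lines, str):
        lines = lines.splitlines()
    rows = [ln.strip() for ln in lines if ln.strip() and not ln.strip().startswith("#")]
    if not rows:
        raise StructureParseError("empty CT input")
    try:
        declared = int(rows[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise StructureParseError(f"malformed CT header: {rows[0]!r}") from exc
    records: list[tuple[int, str, int]] = []
    for line in rows[1:]:
        fields = line.split()
        if len(fields) < 6:
            raise StructureParseError(f"malformed CT row: {line!r}")
        try:
            records.append((int(fields[0]), fields[1], int(fields[4])))
        except ValueError as exc:
            raise StructureParseError(f"malformed CT row: {line!r}") from exc
    if len(records) != declared:
        raise StructureParseError(
            f"CT header declares {declared} positions, found {len(records)} rows"
        )
    return _pairs_from_partner_records(records, replace_noncanonical=replace_noncanonical)


def write_bpseq(s: SecondaryStructure) -> str:
    partner = s.partner_array()
    seq = s.sequence or "N" * s.length  # placeholder base when topology-only
    return "\n".join(
        f"{i} {seq[i - 1]} {partner[i]}" for i in range(1, s.length + 1)
    ) + "\n"


def write_ct(s: SecondaryStructure, title: str = "rnagenus") -> str:
    partner = s.partner_array()
    seq = s.sequence or "N" * s.length
    lines = [f"{s.length} {title}"]
    for i in range(1, s.length + 1):
        nxt = i + 1 if i < s.length else 0
        lines.append(f"{i} {seq[i - 1]} {i - 1} {nxt} {partner[i]} {i}")
    return "\n".join(lines) + "\n"
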