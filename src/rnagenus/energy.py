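"""Simplified nearest-neighbor energy model for helipoint free energies.

Free energies are in kcal/mol, negative = stabilizing, nominally at
37 degC.  The stacking table is a small, deliberately simplified set of
nearest-neighbor values in the spirit of the standard Turner-style rules;
it is NOT a calibrated reproduction of any published parameter set, and
absolute energies should not be compared against experimental dG values.
The table is file-loadable so users can substitute their own parameters.

A stack entry maps the ordered adjacency of two base pairs in a helix:
``("GC", "AU")`` means pair (i, j) = G:C stacked on pair (i+1, j-1) =
A:U.  Bulges of size 1 and 1x1 internal loops inside a helipoint incur
constant penalties instead of a stacking bonus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = ["EnergyModel", "default_energy_model", "CANONICAL_PAIRS", "WOBBLE_PAIRS"]

CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG"})
WOBBLE_PAIRS = frozenset({"GU", "UG"})

# 5'->3' stack (top pair over next pair), kcal/mol.  Simplified values:
# strong G:C-rich stacks near -3, A:U-rich near -1, mixed in between.
_STACKS: dict[tuple[str, str], float] = {
    ("GC", "GC"): -3.3, ("GC", "CG"): -3.4, ("CG", "GC"): -2.4, ("CG", "CG"): -3.3,
    ("AU", "AU"): -0.9, ("AU", "UA"): -1.1, ("UA", "AU"): -1.3, ("UA", "UA"): -0.9,
    ("GC", "AU"): -2.1, ("GC", "UA"): -2.2, ("CG", "AU"): -2.1, ("CG", "UA"): -2.4,
    ("AU", "GC"): -2.2, ("AU", "CG"): -2.1, ("UA", "GC"): -2.4, ("UA", "CG"): -2.1,
}

# wobble stacks (used only when G:U pairing is enabled)
_WOBBLE_STACKS: dict[tuple[str, str], float] = {}
for _p in ("GU", "UG"):
    for _q in CANONICAL_PAIRS | WOBBLE_PAIRS:
        _WOBBLE_STACKS.setdefault((_p, _q), -1.0)
        _WOBBLE_STACKS.setdefault((_q, _p), -1.0)
_WOBBLE_STACKS[("GU", "UG")] = -0.5
_WOBBLE_STACKS[("UG", "GU")] = -0.5


@dataclass(frozen=True)
class EnergyModel:
    """Stacking table plus loop penalties for helipoint scoring."""

    stack_table: dict[tuple[str, str], float]
    bulge_penalty: float = 3.3     # size-1 bulge inside a helix
    internal_penalty: float = 1.7  # 1x1 internal loop inside a helix
    source: str = "rnagenus simplified nearest-neighbor table"

    def stack(self, top: str, bottom: str) -> float:
        try:
            return self.stack_table[(top, bottom)]
        except KeyError:
            raise KeyError(
                f"no stacking entry for {top}/{bottom}; the loaded table "
                "does not cover the active pair rules"
            ) from None

    def covers(self, pair_types: Iterable[str]) -> bool:
        pts = list(pair_types)
        return all((p, q) in self.stack_table for p in pts for q in pts)

    def to_text(self) -> str:
        lines = [f"# {self.source}",
                 f"bulge_penalty {self.bulge_penalty}",
                 f"internal_penalty {self.internal_penalty}"]
        for (p, q), e in sorted(self.stack_table.items()):
            lines.append(f"stack {p} {q} {e}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, source: str = "user table") -> "EnergyModel":
        table: dict[tuple[str, str], float] = {}
        bulge, internal = 3.3, 1.7
        for ln, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fields[0] == "stack" and len(fields) == 4:
                table[(fields[1], fields[2])] = float(fields[3])
            elif fields[0] == "bulge_penalty" and len(fields) == 2:
                bulge = float(fields[1])
            elif fields[0] == "internal_penalty" and len(fields) == 2:
                internal = float(fields[1])
            else:
                raise ValueError(f"malformed energy-table line {ln}: {raw!r}")
        if not table:
            raise ValueError("energy table contains no stack entries")
        return cls(stack_table=table, bulge_penalty=bulge,
                   internal_penalty=internal, source=source)


def default_energy_model(gu: bool = False) -> EnergyModel:
    """The shipped table; with ``gu=True`` wobble stacks are included."""
    table = dict(_STACKS)
    if gu:
        table.update(_WOBBLE_STACKS)
    return EnergyModel(stack_table=table)
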