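"""Metropolis Monte-Carlo folding with a topological genus penalty.

The engine works at the level of *helipoints*: stem-like blocks of base
pairs that may contain single-nucleotide bulges or 1x1 internal loops.
All maximal helipoints of a sequence are enumerated up front; a fold is a
subset S of mutually compatible helipoints (no base used twice), scored
by the free energy

    F_S = sum_i  sigma_i^S * dF(h_i)  +  mu * g(S),

where sigma_i^S indicates membership of helipoint h_i in S, dF(h_i) is
its nearest-neighbor free energy, g(S) is the genus of the union of all
selected base pairs, and mu is the topological chemical potential
(kcal/mol per unit genus).  In the matrix-model correspondence
mu = -2 kBT log(N): N > 1 *rewards* genus, while a positive mu penalizes
pseudoknots.  mu = 0 reduces to plain energy minimization with no
topological restriction.

Sampling is a fixed-temperature Metropolis walk that adds or removes one
helipoint at a time, accepting with probability min(1, exp(-dF/kBT)) and
rejecting outright any move that would push the genus above the
configured cap.  A ranked archive keeps the n_suboptimal lowest-energy
distinct structures seen; that suboptimal ensemble — not just the single
minimum — is the object the genus statistics are taken over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .energy import (CANONICAL_PAIRS, WOBBLE_PAIRS, EnergyModel,
                     default_energy_model)
from .genus_engine import genus_of_pairs
from .structure_io import SecondaryStructure, clean_sequence

__all__ = [
    "Helipoint",
    "FoldState",
    "MCConfig",
    "FoldEnsemble",
    "EnergyModel",
    "default_energy_model",
    "KB_KCAL",
    "mu_from_N",
    "enumerate_helipoints",
    "free_energy",
    "metropolis_run",
    "exhaustive_fold",
]

KB_KCAL = 0.0019872  # Boltzmann constant, kcal/(mol K)

MAX_SEQUENCE_LENGTH = 1000  # engine cap, matching the McGenus-style limit


def mu_from_N(N: float, temperature: float = 310.15) -> float:
    """Topological chemical potential mu = -2 kBT log(N), kcal/mol."""
    if N <= 0:
        raise ValueError(f"matrix order N must be positive, got {N}")
    return -2.0 * KB_KCAL * temperature * math.log(N)


@dataclass(frozen=True)
class Helipoint:
    """A stem-like block of base pairs with its free-energy contribution.

    ``pairs`` is ordered outermost-first; consecutive pairs (i, j) and
    (i', j') advance by (i'-i, j-j') in {1, 2} x {1, 2}: (1,1) is a
    stack, (1,2)/(2,1) a size-1 bulge, (2,2) a 1x1 internal loop.
    ``dF`` is in kcal/mol (negative = stabilizing).
    """

    pairs: tuple[tuple[int, int], ...]
    dF: float

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"invalid pair ({i},{j})")
            if i in seen or j in seen:
                raise ValueError("helipoint reuses a base")
            seen.update((i, j))
        for (i, j), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            di, dj = i2 - i, j - j2
            if di not in (1, 2) or dj not in (1, 2):
                raise ValueError(
                    f"pairs ({i},{j})->({i2},{j2}) violate the stack/bulge-1/"
                    "1x1-loop extension rules"
                )

    @property
    def bases(self) -> frozenset[int]:
        return frozenset(p for pair in self.pairs for p in pair)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def compatible(self, other: "Helipoint") -> bool:
        return not (self.bases & other.bases)


@dataclass(frozen=True)
class FoldState:
    """A subset of selected helipoints with its energy and genus."""

    selected: frozenset[int]
    energy: float
    genus: int
    pairs: frozenset[tuple[int, int]]


@dataclass(frozen=True)
class MCConfig:
    """Parameters of a Monte-Carlo folding run.

    Exactly one of ``mu`` (kcal/mol per unit genus) or ``N`` (matrix
    order, mapped through mu = -2 kBT log N) must be given.
    """

    mu: float | None = None
    N: float | None = None
    temperature: float = 310.15
    anneal_from: float | None = None
    max_genus: int = 5
    n_suboptimal: int = 10
    steps: int = 2000
    seed: int = 0
    gu_wobble: bool = False
    min_pairs: int = 3
    min_loop: int = 3
    max_length: int = MAX_SEQUENCE_LENGTH

    def __post_init__(self) -> None:
        if (self.mu is None) == (self.N is None):
            raise ValueError("exactly one of mu / N must be given")
        if self.n_suboptimal < 1:
            raise ValueError("n_suboptimal must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.anneal_from is not None and self.anneal_from < self.temperature:
            raise ValueError("anneal_from must be >= temperature")

    @property
    def kbt(self) -> float:
        return KB_KCAL * self.temperature

    @property
    def mu_effective(self) -> float:
        if self.mu is not None:
            return self.mu
        return mu_from_N(self.N, self.temperature)

    @property
    def pair_rules(self) -> frozenset[str]:
        return CANONICAL_PAIRS | (WOBBLE_PAIRS if self.gu_wobble else frozenset())


@dataclass(frozen=True)
class FoldEnsemble:
    """The n_suboptimal lowest-energy distinct structures of a run."""

    sequence: str
    structures: tuple[FoldState, ...]
    helipoints: tuple[Helipoint, ...]

    @property
    def best(self) -> FoldState:
        return self.structures[0]

    @property
    def mean_genus(self) -> float:
        return float(np.mean([s.genus for s in self.structures]))

    def secondary_structures(self) -> list[SecondaryStructure]:
        return [
            SecondaryStructure(length=len(self.sequence), pairs=s.pairs,
                               sequence=self.sequence)
            for s in self.structures
        ]


def _helipoint_energy(seq: str, chain: Sequence[tuple[int, int]],
                      model: EnergyModel) -> float:
    """dF of a pair chain: stacking bonuses plus bulge/loop penalties."""
    def ptype(p):
        i, j = p
        return seq[i - 1] + seq[j - 1]

    dF = 0.0
    for a, b in zip(chain, chain[1:]):
        di, dj = b[0] - a[0], a[1] - b[1]
        if di == 1 and dj == 1:
            dF += model.stack(ptype(a), ptype(b))
        elif di == 2 and dj == 2:
            dF += model.internal_penalty
        else:
            dF += model.bulge_penalty
    return dF


def enumerate_helipoints(
    sequence: str,
    model: EnergyModel | None = None,
    pair_rules: frozenset[str] = CANONICAL_PAIRS,
    min_pairs: int = 3,
    min_loop: int = 3,
) -> list[Helipoint]:
    """All maximal helipoints of ``sequence`` with negative free energy.

    Candidate pairs (i, j) require ``sequence[i] sequence[j]`` in
    ``pair_rules`` and a hairpin loop of at least ``min_loop`` unpaired
    nucleotides (j - i > min_loop).  A helipoint is a maximal chain of
    candidate pairs under the stack / size-1-bulge / 1x1-internal-loop
    extension steps; only chains with at least ``min_pairs`` pairs and
    dF < 0 are returned, each exactly once, in deterministic order.
    """
    seq = clean_sequence(sequence)
    model = model or default_energy_model(gu=bool(pair_rules & WOBBLE_PAIRS))
    n = len(seq)
    cand: set[tuple[int, int]] = {
        (i, j)
        for i in range(1, n + 1)
        for j in range(i + min_loop + 1, n + 1)
        if seq[i - 1] + seq[j - 1] in pair_rules
    }

    def successors(p):
        i, j = p
        return [
            (i + di, j - dj)
            for di in (1, 2)
            for dj in (1, 2)
            if (i + di, j - dj) in cand and i + di < j - dj
        ]

    has_pred = set()
    for p in cand:
        has_pred.update(successors(p))
    sources = sorted(cand - has_pred)

    out: dict[tuple[tuple[int, int], ...], Helipoint] = {}

    def extend(chain: list[tuple[int, int]]) -> None:
        succ = successors(chain[-1])
        if not succ:
            key = tuple(chain)
            if len(chain) >= min_pairs and key not in out:
                dF = _helipoint_energy(seq, chain, model)
                if dF < 0:
                    out[key] = Helipoint(pairs=key, dF=dF)
            return
        for nxt in sorted(succ):
            chain.append(nxt)
            extend(chain)
            chain.pop()

    for src in sources:
        extend([src])
    return sorted(out.values(), key=lambda h: h.pairs)


def free_energy(selected: Sequence[Helipoint], mu: float) -> float:
    """F_S = sum dF over selected helipoints + mu * genus of their union.

    Raises if the selection is internally incompatible (shared bases) —
    that is a caller bug, not a fold with infinite energy.
    """
    used: set[int] = set()
    pairs: set[tuple[int, int]] = set()
    dF = 0.0
    for h in selected:
        if used & h.bases:
            raise ValueError("incompatible helipoint selection: shared bases")
        used |= h.bases
        pairs.update(h.pairs)
        dF += h.dF
    return dF + mu * genus_of_pairs(pairs)


def _make_state(idx: frozenset[int], helipoints: Sequence[Helipoint],
                mu: float) -> FoldState:
    pairs = frozenset(p for k in idx for p in helipoints[k].pairs)
    g = genus_of_pairs(pairs)
    energy = sum(helipoints[k].dF for k in idx) + mu * g
    return FoldState(selected=idx, energy=energy, genus=g, pairs=pairs)


def metropolis_run(
    sequence: str,
    config: MCConfig,
    model: EnergyModel | None = None,
    helipoints: Sequence[Helipoint] | None = None,
) -> FoldEnsemble:
    """Run the Metropolis walk and return the suboptimal ensemble.

    Each step proposes, with equal probability, adding a uniformly random
    compatible unselected helipoint or removing a uniformly random
    selected one; acceptance is min(1, exp(-dF_S / kBT)).  With
    ``config.anneal_from`` set, the walk temperature starts there and
    cools geometrically to ``config.temperature`` over the run (the
    physical temperature — and hence mu from N — is unaffected); deep
    local minima of helix-rich sequences are hard to leave at 310 K, so
    annealed or hot walks are the practical way to reach the optimum.
    Moves that would raise the genus above ``config.max_genus`` are
    rejected.  The
    archive of the ``n_suboptimal`` lowest-energy distinct pair sets
    always contains the open chain (energy 0), so a steps=0 run returns
    just that baseline.  Identical (sequence, config, seed) gives an
    identical ensemble.
    """
    seq = clean_sequence(sequence)
    if len(seq) > config.max_length:
        raise ValueError(
            f"sequence length {len(seq)} exceeds the engine cap "
            f"{config.max_length}"
        )
    model = model or default_energy_model(gu=config.gu_wobble)
    if helipoints is None:
        helipoints = enumerate_helipoints(
            seq, model=model, pair_rules=config.pair_rules,
            min_pairs=config.min_pairs, min_loop=config.min_loop,
        )
    helipoints = tuple(helipoints)
    mu = config.mu_effective
    rng = np.random.default_rng(config.seed)

    # incremental state
    selected: set[int] = set()
    used_bases: set[int] = set()
    pairs: set[tuple[int, int]] = set()
    energy = 0.0
    g = 0

    archive: dict[frozenset[tuple[int, int]], FoldState] = {}

    def record() -> None:
        key = frozenset(pairs)
        if key not in archive:
            archive[key] = FoldState(
                selected=frozenset(selected), energy=energy, genus=g, pairs=key
            )

    if config.anneal_from is None or config.steps <= 1:
        kbt_schedule = [config.kbt] * config.steps
    else:
        ratio = config.temperature / config.anneal_from
        kbt_schedule = [
            KB_KCAL * config.anneal_from * ratio ** (t / (config.steps - 1))
            for t in range(config.steps)
        ]

    record()
    for step in range(config.steps):
        kbt = kbt_schedule[step]
        do_add = rng.random() < 0.5
        if do_add:
            candidates = [
                k for k, h in enumerate(helipoints)
                if k not in selected and not (used_bases & h.bases)
            ]
            if not candidates:
                continue
            k = candidates[rng.integers(len(candidates))]
            new_pairs = pairs | set(helipoints[k].pairs)
            d_dF = helipoints[k].dF
        else:
            if not selected:
                continue
            pool = sorted(selected)
            k = pool[rng.integers(len(pool))]
            new_pairs = pairs - set(helipoints[k].pairs)
            d_dF = -helipoints[k].dF
        new_g = genus_of_pairs(new_pairs)
        if new_g > config.max_genus:
            continue
        dE = d_dF + mu * (new_g - g)
        if dE <= 0 or rng.random() < math.exp(-dE / kbt):
            if do_add:
                selected.add(k)
                used_bases |= helipoints[k].bases
            else:
                selected.discard(k)
                used_bases -= helipoints[k].bases
            pairs = new_pairs
            energy += dE
            g = new_g
            record()

    ranked = sorted(archive.values(), key=lambda s: (s.energy, sorted(s.pairs)))
    return FoldEnsemble(
        sequence=seq,
        structures=tuple(ranked[: config.n_suboptimal]),
        helipoints=helipoints,
    )


def exhaustive_fold(
    sequence: str,
    config: MCConfig,
    model: EnergyModel | None = None,
    helipoints: Sequence[Helipoint] | None = None,
    max_helipoints: int = 20,
) -> FoldEnsemble:
    """Exact optimum by enumeration of all compatible helipoint subsets.

    Exponential in the number of helipoints (capped at
    ``max_helipoints``); intended for small designed sequences and as the
    reference the stochastic engine is validated against.
    """
    seq = clean_sequence(sequence)
    model = model or default_energy_model(gu=config.gu_wobble)
    if helipoints is None:
        helipoints = enumerate_helipoints(
            seq, model=model, pair_rules=config.pair_rules,
            min_pairs=config.min_pairs, min_loop=config.min_loop,
        )
    helipoints = tuple(helipoints)
    if len(helipoints) > max_helipoints:
        raise ValueError(
            f"{len(helipoints)} helipoints exceed the exhaustive cap "
            f"{max_helipoints}"
        )
    mu = config.mu_effective
    states: list[FoldState] = []

    def rec(start: int, idx: frozenset[int], used: frozenset[int]) -> None:
        states.append(_make_state(idx, helipoints, mu))
        for k in range(start, len(helipoints)):
            if not (used & helipoints[k].bases):
                rec(k + 1, idx | {k}, used | helipoints[k].bases)

    rec(0, frozenset(), frozenset())
    states = [s for s in states if s.genus <= config.max_genus]
    states.sort(key=lambda s: (s.energy, sorted(s.pairs)))
    return FoldEnsemble(
        sequence=seq,
        structures=tuple(states[: config.n_suboptimal]),
        helipoints=helipoints,
    )
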