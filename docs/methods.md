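# Methods

## Model and conventions

**Structures and diagrams.**  A secondary structure is a backbone of L
residues plus a partial matching of base pairs (1-based, i < j; at most
one partner per position — the sparse contact matrix).  Its chord
diagram keeps, by default, only the 2m paired positions relabeled
1..2m; isolated (unpaired) points carry no topology, and are retained
only where absolute positions matter (genus trace, fingerprint).  Two
arcs (i, j), (k, l) cross iff i < k < j < l; a diagram is planar iff it
has no crossing, iff its genus is 0.

**Genus.**  The fat-graph boundary count b is the number of cycles of
σ∘α with σ the backbone cycle and α the arc involution (α applied
first).  The composition order is a convention only: the cycle count of
the consistent alternative α∘σ is identical (the permutations are
conjugate), which the suite asserts.  Genus is g = (m − b + 1)/2.  The
Euler characteristic is reported under the one-puncture convention
χ = 2 − 2g − p with p = 1 (one closed backbone), i.e. χ = 1 − 2g.  This
convention is chosen because per-diagram V/E/F cell decompositions are
ambiguous for arc diagrams, while χ = 1 − 2g is unambiguous and yields
the expected χ = −1 for the genus-1 kissing hairpin.  An independent
test oracle (`tests/oracles.py`) recomputes genus from a dart/rotation
-system face tracing and the closed-surface formula V − E + F = 2 − 2g;
the two constructions agree on every partial matching with up to 8
points (checked exhaustively).

**Shadow.**  `collapse_parallel` replaces each maximal stem
{(i, j), (i+1, j−1), …} by its outermost arc, compacts labels, and
iterates to a fixpoint (compaction can bring previously separated arcs
into adjacency).  The fixpoint makes the operation idempotent; each
collapse step preserves genus.

**Composition.**  `concatenate` places one diagram after another;
`nest` inserts a diagram immediately after the left endpoint of the
shortest (then leftmost) arc of the host.  Both are genus-additive,
which the generator of controlled-genus structures exploits: a target
genus is hit exactly by combining genus-1 irreducible blocks (crossing
pair or kissing shadow) with planar filler.

**Diagram expansion.**  Z_n(a, N) is computed purely combinatorially:
every partial matching of n points is enumerated (smallest free point
unpaired or paired to each larger free point, ascending — deterministic
and duplicate-free), tallied by (chord count k, genus g), and evaluated
as Σ count·a^k·N^(−2g).  At N = 1 this reduces to the 1-D series
Σ_k C(n, 2k)(2k−1)!! a^k, an identity the suite checks against the
closed form.  The default enumeration cap is n = 12 (the number of
partial matchings grows like the telephone numbers; n = 12 gives
140 152 diagrams, well under a second).

## Folding engine

**Helipoints.**  Candidate pairs require a canonical cWW pairing
(A·U, G·C; G·U behind an explicit flag) and a hairpin loop of at least
3 nt (j − i > 3).  A helipoint is a maximal chain of candidate pairs
under the extension steps (Δi, Δj) ∈ {1, 2}²: (1,1) stack, (1,2)/(2,1)
size-1 bulge, (2,2) 1×1 internal loop.  Chains shorter than
`min_pairs` (default 3) or with non-negative ΔF are discarded.  The
defaults (min_pairs 3, min loop 3) are declared choices — standard
practice rather than published constants.

**Energy.**  ΔF of a helipoint sums nearest-neighbor stacking terms
plus constant penalties for bulges (+3.3 kcal/mol) and 1×1 internal
loops (+1.7 kcal/mol).  The shipped stacking table is a small,
simplified set of nearest-neighbor values (G/C-rich stacks near
−3.3 kcal/mol, A/U-rich near −1, mixed in between, nominal 37 °C); it
is deliberately **not** a calibrated published parameter set, and
absolute energies should not be compared with experimental ΔG.  The
table is file-loadable (`EnergyModel.from_text`) so users can
substitute real parameters; correctness claims rest on the optimizer
(MC optimum ≡ exhaustive-subset optimum), not on energy values.

**Free energy and sampling.**  F_S = Σ σᵢ^S·ΔF(hᵢ) + μ·g(S), with g(S)
the genus of the union of selected pairs.  μ > 0 penalizes genus;
μ = −2k_BT·log N maps the matrix order onto the potential (N > 1 gives
μ < 0).  The sampler is Metropolis: each step proposes, with equal
probability, adding a uniformly random compatible helipoint or removing
a uniformly random selected one, accepted with min(1, exp(−ΔF_S/k_BT));
moves pushing genus past `max_genus` are rejected outright.  Energies
are tracked incrementally (ΔF plus μ times the genus change) and the
suite asserts equality with full recomputation to 1e−9.  A ranked
archive keeps the `n_suboptimal` (default 10) lowest-energy distinct
pair sets visited, always including the open chain, so a 0-step run
returns the unfolded baseline.  Runs are exactly reproducible from
(sequence, config, seed); k_B = 0.0019872 kcal/(mol·K), default
T = 310.15 K.

**Annealing.**  Helix-rich sequences have deep local minima: at 310 K
the probability of removing a −6.6 kcal/mol helix is ~2×10⁻⁵ per
attempt, so a fixed-temperature walk can take arbitrarily long to leave
a mis-paired stem.  `anneal_from` starts the walk hot and cools
geometrically to the physical temperature over the run; the physical
temperature (and hence μ from N) is unaffected.  The validation runs
use 3000–5000 steps annealed from 1500 K, which reaches the exhaustive
optimum on all tested designed sequences for every seed tried.

## Ensemble statistics

Trace summaries compute per-position mean, mode, standard deviation,
minimum and maximum over member genus traces; mode ties break toward
the smaller genus.  Smoothing is a 1-D Gaussian filter (default
σ = 1) applied to mean and std only, with reflection padding at the
boundaries; missing data (NaN) splits the signal and each valid
segment is smoothed independently, so gaps do not bleed.  The
genus-vs-length regression is ordinary least squares
(`scipy.stats.linregress`); the zero-intercept variant uses the
uncentered total sum of squares for r² (the standard through-origin
convention) and ŝ²/Σd² for the slope variance.

## Synthetic data

The generator builds hairpins, H-type pseudoknots, kissing hairpins,
two-domain chains, uniform random matchings (uniform 2k-subset plus
uniform perfect matching on it), and exact-genus structures by
genus-additive composition.  Designed sequences use an alphabet chosen
so the intended stems are the only maximal helipoints and the intended
fold is the unique free-energy optimum under the shipped table: the
default kissing hairpin (3-pair stems) uses an all-G first stem, an
A/U-alternating kissing segment and a G-capped C stem, giving a
2.4 kcal/mol gap to the best competing fold.  This guarantee is
verified for the default geometry; very short stems (< 3 pairs) cannot
satisfy the 3-nt minimum hairpin loop and will not fold.  What the
generator does **not** emulate: natural base composition, non-canonical
pairs, modified nucleosides, or realistic length/genus distributions —
passing tests demonstrate the correctness of the combinatorics and the
optimizer, not predictive accuracy on biological RNA.

The regression recovery check generates 500 (length, mean-genus)
records on lengths uniform in [30, 1000] from a linear law with
Gaussian noise (σ = 0.5) and requires the fitted slope to lie within 3
standard errors of the truth; the generating coefficients play the
role of a known ground truth, not of a reproduced dataset.

## Numerical and interface choices

* Coordinates 1-based throughout (BPSEQ/CT convention); dot-bracket
  layers assigned by greedy coloring of the crossing graph (lowest free
  layer, arcs by left endpoint), which makes writing deterministic and
  round-trip exact.
* Non-ACGU bases are rejected by default; the replacement policy
  N, X, F, M → A and V → G is available as an explicit reader option.
* Fingerprint computation is O(L²) genus evaluations and is capped at
  L = 400 by default (override via `max_length`).
* Sequence cap for the folding engine: 1000 nt.
* Suboptimal-structure distinctness is exact pair-set identity; ties in
  energy are ordered by the sorted pair list for determinism.

## Known limitations

The energy model is a toy; no entropic loop terms beyond the helipoint
constants; the helipoint enumeration can grow combinatorially on long
repetitive sequences (intended scale: designed and database-sized
molecules, not genomes); exhaustive folding is exponential and capped
at 20 helipoints; the MC engine makes no claim of Boltzmann-weighted
sampling of the ensemble — the archive is an optimization record, as
in the tool family this engine emulates.
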