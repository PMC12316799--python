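import math

import numpy as np
import pytest

from rnagenus.energy import EnergyModel, default_energy_model
from rnagenus.folding_mc import (Helipoint, MCConfig, enumerate_helipoints,
                                 exhaustive_fold, free_energy, metropolis_run,
                                 mu_from_N)
from rnagenus.genus_engine import genus_of_pairs

ANNEALED = dict(steps=5000, anneal_from=1500.0)


def test_hairpin_helipoint_enumeration():
    hps = enumerate_helipoints("GGGAAACCC", min_pairs=3)
    assert [h.pairs for h in hps] == [((1, 9), (2, 8), (3, 7))]
    assert hps[0].dF == pytest.approx(2 * -3.3)


def test_no_complementarity_means_no_helipoints():
    assert enumerate_helipoints("AAAAAA") == []


def test_designed_kissing_hairpin_contains_intended_helipoints(kissing_hairpin):
    hps = {h.pairs for h in enumerate_helipoints(kissing_hairpin.sequence)}
    assert ((1, 9), (2, 8), (3, 7)) in hps
    assert ((4, 15), (5, 14), (6, 13)) in hps
    assert ((10, 18), (11, 17), (12, 16)) in hps


def test_helipoints_are_maximal_and_unique():
    hps = enumerate_helipoints("GGGAAACCCCCCUUUGGG")
    keys = [h.pairs for h in hps]
    assert len(keys) == len(set(keys))
    # no reported helipoint is a prefix/suffix sub-chain of another
    for a in keys:
        for b in keys:
            if a is not b:
                assert not (set(a) < set(b))


def test_helipoint_extension_rules_validated():
    Helipoint(pairs=((1, 10), (2, 9), (4, 7)), dF=-1.0)  # stack + 2x2 loop
    with pytest.raises(ValueError, match="extension rules"):
        Helipoint(pairs=((1, 10), (4, 9)), dF=-1.0)  # bulge of size 2
    with pytest.raises(ValueError, match="reuses"):
        Helipoint(pairs=((1, 10), (1, 9)), dF=-1.0)


def test_bulged_helix_enumeration_and_energy():
    # G at 1-3 and 5 pairs C at 9-12; position 4 is a size-1 bulge, so
    # the maximal chain (1,12)(2,11)(3,10)(5,9) carries two GC stacks
    # and one bulge penalty: 2*(-3.3) + 3.3 = -3.3 kcal/mol
    model = default_energy_model()
    hps = enumerate_helipoints("GGGAGAAACCCC", min_pairs=3)
    bulged = [h for h in hps if h.pairs == ((1, 12), (2, 11), (3, 10), (5, 9))]
    assert len(bulged) == 1
    assert bulged[0].dF == pytest.approx(
        2 * model.stack("GC", "GC") + model.bulge_penalty
    )


def test_free_energy_composition():
    assert free_energy([], mu=5.0) == 0.0
    flat = Helipoint(pairs=((1, 20), (2, 19), (3, 18)), dF=-5.0)
    assert free_energy([flat], mu=7.0) == pytest.approx(-5.0)  # planar, g=0
    crossing = Helipoint(pairs=((5, 30), (6, 29), (7, 28)), dF=-5.0)
    assert genus_of_pairs(set(flat.pairs) | set(crossing.pairs)) == 1
    assert free_energy([flat, crossing], mu=3.0) == pytest.approx(-7.0)
    with pytest.raises(ValueError, match="incompatible"):
        free_energy([flat, Helipoint(pairs=((3, 40), (4, 39), (5, 38)), dF=-1.0)],
                    mu=0.0)


@pytest.mark.parametrize("N,temperature,expected", [
    (1.0, 310.15, 0.0),
    (math.e, 0.5 / 0.0019872, -1.0),
])
def test_mu_from_N_closed_form(N, temperature, expected):
    assert mu_from_N(N, temperature) == pytest.approx(expected)
    with pytest.raises(ValueError):
        mu_from_N(0.0)


def test_mu_sign_tracks_matrix_order():
    assert mu_from_N(2.0) < 0 < mu_from_N(0.5)


def test_metropolis_is_deterministic_under_seed(kissing_hairpin):
    cfg = MCConfig(mu=0.0, seed=11, steps=1500, anneal_from=1000.0)
    a = metropolis_run(kissing_hairpin.sequence, cfg)
    b = metropolis_run(kissing_hairpin.sequence, cfg)
    assert a.structures == b.structures


def test_zero_steps_returns_open_chain():
    ens = metropolis_run("GGGAAACCC", MCConfig(mu=0.0, steps=0))
    assert len(ens.structures) == 1
    assert ens.best.energy == 0.0 and ens.best.pairs == frozenset()


def test_sequence_length_cap():
    with pytest.raises(ValueError, match="cap"):
        metropolis_run("A" * 1001, MCConfig(mu=0.0, steps=1))


def test_config_validation():
    with pytest.raises(ValueError, match="exactly one"):
        MCConfig(mu=0.0, N=2.0)
    with pytest.raises(ValueError, match="exactly one"):
        MCConfig()
    with pytest.raises(ValueError, match="n_suboptimal"):
        MCConfig(mu=0.0, n_suboptimal=0)


def test_single_hairpin_ground_state_matches_exhaustive():
    cfg = MCConfig(mu=0.0, seed=5, **ANNEALED)
    mc = metropolis_run("GGGAAACCC", cfg)
    ex = exhaustive_fold("GGGAAACCC", cfg)
    assert mc.best.pairs == ex.best.pairs == frozenset({(1, 9), (2, 8), (3, 7)})
    assert mc.best.genus == 0
    assert mc.best.energy == pytest.approx(ex.best.energy, abs=1e-9)


@pytest.mark.parametrize("mu,expected_genus", [(0.0, 1), (20.0, 0)])
def test_kissing_hairpin_optimum_vs_exhaustive(kissing_hairpin, mu,
                                               expected_genus):
    cfg = MCConfig(mu=mu, seed=2, **ANNEALED)
    ex = exhaustive_fold(kissing_hairpin.sequence, cfg)
    mc = metropolis_run(kissing_hairpin.sequence, cfg)
    assert ex.best.genus == expected_genus
    assert mc.best.energy == pytest.approx(ex.best.energy, abs=1e-9)
    assert mc.best.pairs == ex.best.pairs


def test_mean_ensemble_genus_non_increasing_in_mu(kissing_hairpin):
    means = []
    for mu in (0.0, 2.0, 5.0, 20.0):
        per_seed = [
            metropolis_run(
                kissing_hairpin.sequence,
                MCConfig(mu=mu, seed=seed, steps=3000, anneal_from=1500.0),
            ).mean_genus
            for seed in range(5)
        ]
        means.append(float(np.mean(per_seed)))
    assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))


def test_incremental_energy_matches_recomputation(kissing_hairpin):
    cfg = MCConfig(mu=1.5, seed=7, steps=800, anneal_from=1200.0)
    ens = metropolis_run(kissing_hairpin.sequence, cfg)
    for state in ens.structures:
        recomputed = free_energy(
            [ens.helipoints[k] for k in sorted(state.selected)], mu=1.5
        )
        assert state.energy == pytest.approx(recomputed, abs=1e-9)


def test_max_genus_cap_excludes_pseudoknots(kissing_hairpin):
    cfg = MCConfig(mu=0.0, seed=3, max_genus=0, **ANNEALED)
    ens = metropolis_run(kissing_hairpin.sequence, cfg)
    assert all(s.genus == 0 for s in ens.structures)


def test_energy_table_roundtrip():
    model = default_energy_model(gu=True)
    back = EnergyModel.from_text(model.to_text())
    assert back.stack_table == model.stack_table
    assert back.bulge_penalty == model.bulge_penalty
    with pytest.raises(ValueError, match="malformed"):
        EnergyModel.from_text("stack GC\n")


def test_gu_wobble_behind_flag():
    seq = "GGGAAAUUU"  # G:U closing pairs only under the wobble rule
    assert enumerate_helipoints(seq) == []
    cfg = MCConfig(mu=0.0, gu_wobble=True)
    hps = enumerate_helipoints(seq, pair_rules=cfg.pair_rules,
                               model=default_energy_model(gu=True))
    assert any(h.pairs == ((1, 9), (2, 8), (3, 7)) for h in hps)
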