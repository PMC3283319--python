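"""Acceptance rules of the constrained models."""

import itertools

import numpy as np
import pytest

from conftest import build_genome
from dcjc.engine import run_simulation
from dcjc.fixtures import make_fixture
from dcjc.genome import DCJMove, apply_move, classify_move, init_genome
from dcjc.models import (ModelConfig, accept_ds, accept_maxL, accept_maxT,
                         accept_move, accept_pfix,
                         sensitive_partition_unchanged)


def all_lin_lin_translocations(genome, L1, L2):
    for p1 in range(L1 + 1):
        for p2 in range(L2 + 1):
            for rejoin in (0, 1):
                move = DCJMove(0, p1, 1, p2, rejoin)
                try:
                    if classify_move(genome, move) != "translocation":
                        continue
                except ValueError:
                    continue
                yield move


# ------------------------------------------------------------------ DS


def test_ds_accepts_everything_without_sensitive_genes(rng):
    g = init_genome(3, 30, 0.0, rng)
    run = run_simulation(ModelConfig.ds(0.0), 100, seed=1, genome=g)
    assert run.log.rejected_by_model == 0


@pytest.mark.parametrize("kind", ["ds-illegal-cut", "ds-illegal-rejoin"])
def test_ds_rejects_illegal_fixture(kind):
    genome, move = make_fixture(kind)
    assert not accept_ds(genome, move)
    # and the brute-force partition oracle agrees
    after = genome.copy()
    apply_move(after, move)
    assert not sensitive_partition_unchanged(genome, after)


def test_ds_acceptance_equals_partition_oracle_exhaustively():
    g = build_genome([1, 2, 3, 4, 5, 6], [7, 8, 9, 10, 11, 12],
                     sensitive=[2, 5, 9])
    for move in all_lin_lin_translocations(g, 6, 6):
        after = g.copy()
        apply_move(after, move)
        assert accept_ds(g, move) == sensitive_partition_unchanged(g, after), move


def test_ds_partition_invariant_over_run(rng):
    g = init_genome(4, 200, 0.15, rng)
    part0 = g.sensitive_partition()

    def check(move, genome):
        assert genome.sensitive_partition() == part0

    run = run_simulation(ModelConfig.ds(0.15), 2000, seed=3, genome=g,
                         move_callback=check)
    assert run.end.sensitive_partition() == part0


# ---------------------------------------------------------------- maxT


def test_maxT_examples():
    g = build_genome(list(range(1, 31)), list(range(31, 61)))
    # |a|=5, |c|=5 -> accepted at T=20 (swap exchanges the (a, c) view)
    assert accept_maxT(g, DCJMove(0, 5, 1, 5, 0), 20)
    # all four fragments longer than T -> rejected for both rejoins
    assert not accept_maxT(g, DCJMove(0, 15, 1, 15, 0), 10)
    assert not accept_maxT(g, DCJMove(0, 15, 1, 15, 1), 10)


def test_maxT_brute_force_map():
    g = build_genome(list(range(1, 31)), list(range(31, 61)))
    T = 7
    for move in all_lin_lin_translocations(g, 30, 30):
        a, b = move.pos1, 30 - move.pos1
        c, d = move.pos2, 30 - move.pos2
        if move.rejoin == 0:  # exchanged pairs (a,c) / (d,b)
            expected = (a <= T and c <= T) or (d <= T and b <= T)
        else:  # exchanged pairs (b,c) / (a,d)
            expected = (b <= T and c <= T) or (a <= T and d <= T)
        assert accept_maxT(g, move, T) == expected, move


def test_maxT_excision_cap():
    g = build_genome(list(range(1, 31)))
    ok = DCJMove(0, 5, 0, 10, 1)     # excise 5 genes
    too_big = DCJMove(0, 5, 0, 27, 1)  # excise 22 genes
    assert accept_maxT(g, ok, 20)
    assert not accept_maxT(g, too_big, 20)
    # inversions are unconstrained under maxT
    assert accept_maxT(g, DCJMove(0, 1, 0, 29, 0), 1)


# ---------------------------------------------------------------- maxL


def test_maxL_inversion_boundary():
    g = build_genome(list(range(1, 31)))
    at_limit = DCJMove(0, 5, 0, 15, 0)   # inversion of 10
    over = DCJMove(0, 5, 0, 16, 0)       # inversion of 11
    assert accept_maxL(g, at_limit, 10)
    assert not accept_maxL(g, over, 10)


def test_maxL_is_maxT_plus_inversion_rule():
    g = build_genome(list(range(1, 21)), list(range(21, 41)))
    L = 6
    slots = [(0, p) for p in range(21)] + [(1, p) for p in range(21)]
    for (c1, p1), (c2, p2) in itertools.combinations(slots, 2):
        for rejoin in (0, 1):
            move = DCJMove(c1, p1, c2, p2, rejoin)
            try:
                cls = classify_move(g, move)
            except ValueError:
                continue
            got = accept_maxL(g, move, L)
            if cls == "inversion":
                assert got == (move.pos2 - move.pos1 <= L)
            else:
                assert got == accept_maxT(g, move, L)


# ---------------------------------------------------------------- pfix


def test_pfix_limits(rng):
    g = build_genome(list(range(1, 21)), list(range(21, 41)))
    inv = DCJMove(0, 2, 0, 8, 0)
    assert accept_pfix(g, inv, 0.0, rng)  # intra always accepted
    tr = DCJMove(0, 5, 1, 5, 0)
    assert not accept_pfix(g, tr, 0.0, rng)
    assert accept_pfix(g, tr, 1.0, rng)


def test_pfix_zero_yields_no_inter_moves():
    run = run_simulation(ModelConfig.pfix(0.0), 200, c=4, n_genes=200, seed=2)
    assert run.log.n_t == 0
    assert run.log.n == 200


def test_pfix_empirical_rate(rng):
    g = build_genome(list(range(1, 21)), list(range(21, 41)))
    tr = DCJMove(0, 5, 1, 5, 0)
    p = 0.01
    trials = 100_000
    hits = sum(accept_pfix(g, tr, p, rng) for _ in range(trials))
    se = np.sqrt(p * (1 - p) * trials)
    assert abs(hits - p * trials) <= 3 * se


def test_pfix_literal_scope_flag(rng):
    # with gate_all_inter=False only translocations/excisions are gated
    g = build_genome(list(range(1, 11)), ([11, 12, 13], True))
    reint = DCJMove(0, 4, 1, 0, 0)
    assert classify_move(g, reint) == "reintegration"
    cfg = ModelConfig(model="pfix", p_fix=0.0, gate_all_inter=False)
    assert accept_move(g, reint, cfg, rng)
    cfg_all = ModelConfig(model="pfix", p_fix=0.0, gate_all_inter=True)
    assert not accept_move(g, reint, cfg_all, rng)


# ------------------------------------------------------------- config


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(model="bogus")
    with pytest.raises(ValueError):
        ModelConfig.ds(1.5)
    with pytest.raises(ValueError):
        ModelConfig.pfix(-0.1)
    assert ModelConfig.max_t(np.inf).parameter == np.inf
    assert ModelConfig.ds(0.1).with_parameter(0.2).mu == 0.2
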