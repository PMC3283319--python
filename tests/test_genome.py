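"""Core genome representation, move classification and application."""

import itertools

import numpy as np
import pytest

from conftest import build_genome
from dcjc.genome import (DCJMove, apply_move, classify_move, init_genome,
                         invert_move, segment_summary)


def orders(genome):
    return [(ch.circular, [int(g) for g in ch.genes])
            for ch in genome.chromosomes]


# ---------------------------------------------------------------- init


def test_init_genome_shape(rng):
    g = init_genome(4, 22, 0.0, rng)
    lengths = [len(ch.genes) for ch in g.chromosomes]
    # remainder genes go to the lowest-index chromosomes
    assert lengths == [6, 6, 5, 5]
    assert not any(ch.circular for ch in g.chromosomes)
    g.validate()
    assert np.array_equal(np.sort(g.gene_ids()), np.arange(1, 23))


def test_init_genome_sensitive_fraction(rng):
    g = init_genome(10, 20000, 0.25, rng)
    frac = g.sensitive[1:].mean()
    # binomial(20000, .25): 3 sigma ~ 0.0092
    assert abs(frac - 0.25) < 0.01


def test_init_genome_mu_zero(rng):
    g = init_genome(5, 100, 0.0, rng)
    assert not g.sensitive.any()


# ------------------------------------------------- classification oracle


def brute_force_class(genome, move):
    """Classify by applying the move and diffing topology/content."""
    before = orders(genome)
    after_g = genome.copy()
    apply_move(after_g, move)
    after = orders(after_g)
    n_lin_b = sum(1 for c, _ in before if not c)
    n_lin_a = sum(1 for c, _ in after if not c)
    n_circ_b = sum(1 for c, _ in before if c)
    n_circ_a = sum(1 for c, _ in after if c)
    ch1, ch2 = genome.chromosomes[move.chrom1], genome.chromosomes[move.chrom2]
    if move.same_chromosome:
        if not ch1.circular:
            return "inversion" if n_circ_a == n_circ_b else "excision"
        return "inversion" if n_circ_a == n_circ_b else "fission"
    if ch1.circular != ch2.circular:
        return "reintegration"
    if ch1.circular and ch2.circular:
        return "fusion"
    if n_lin_a < n_lin_b:
        return "fusion"
    return "translocation"


def all_moves(genome):
    slots = []
    for ci, ch in enumerate(genome.chromosomes):
        top = len(ch.genes) - 1 if ch.circular else len(ch.genes)
        slots.extend((ci, p) for p in range(top + 1))
    for (c1, p1), (c2, p2) in itertools.combinations(slots, 2):
        for rejoin in (0, 1):
            yield DCJMove(c1, p1, c2, p2, rejoin)


def test_classification_matches_brute_force_on_small_genome():
    g = build_genome([1, 2], [3, 4], ([5, 6], True))
    for move in all_moves(g):
        assert classify_move(g, move) == brute_force_class(g, move), move


def test_classify_rejects_coincident_cuts():
    g = build_genome([1, 2, 3])
    with pytest.raises(ValueError):
        classify_move(g, DCJMove(0, 1, 0, 1, 0))


# ------------------------------------------------------------ apply


def test_translocation_swap_and_cross():
    g = build_genome([1, 2, 3, 4], [5, 6, 7, 8])
    swap = g.copy()
    apply_move(swap, DCJMove(0, 2, 1, 2, 0))
    assert orders(swap) == [(False, [1, 2, 7, 8]), (False, [5, 6, 3, 4])]
    cross = g.copy()
    apply_move(cross, DCJMove(0, 2, 1, 2, 1))
    assert orders(cross) == [(False, [1, 2, -6, -5]), (False, [-4, -3, 7, 8])]


def test_excision_and_fusion():
    g = build_genome([1, 2, 3, 4, 5])
    apply_move(g, DCJMove(0, 1, 0, 4, 1))
    assert orders(g) == [(False, [1, 5]), (True, [2, 3, 4])]
    g2 = build_genome([1, 2], [3, 4])
    apply_move(g2, DCJMove(0, 2, 1, 0, 0))  # telomeric cuts -> fusion
    assert len(g2.chromosomes) == 1
    assert sorted(abs(int(x)) for x in g2.chromosomes[0].genes) == [1, 2, 3, 4]


def test_gene_content_conserved_over_random_moves(rng):
    g = init_genome(4, 60, 0.1, rng)
    ids0 = np.sort(g.gene_ids())
    from dcjc.engine import run_simulation
    from dcjc.models import ModelConfig
    res = run_simulation(ModelConfig.dcj(), 300, seed=7, genome=g)
    assert np.array_equal(np.sort(res.end.gene_ids()), ids0)
    res.end.validate()


def test_full_chromosome_inversion_is_equivalent():
    g = build_genome([1, 2, 3], [4, 5])
    h = g.copy()
    apply_move(h, DCJMove(0, 0, 0, 3, 0))
    assert orders(h)[0] == (False, [-3, -2, -1])
    assert g.equivalent(h)


# --------------------------------------------------------- reversibility


@pytest.mark.parametrize("seed", range(5))
def test_apply_then_inverse_restores(seed):
    from dcjc.engine import run_simulation
    from dcjc.models import ModelConfig

    rng = np.random.default_rng(seed)
    g = init_genome(3, 40, 0.2, rng)
    moves = []

    def record(move, genome):
        moves.append(move)

    # internal cuts only: every move class in play has a single-move
    # inverse (a linear-linear fusion does not)
    config = ModelConfig(model="dcj", allow_telomeric_cuts=False)
    res = run_simulation(config, 50, seed=seed, genome=g,
                         move_callback=record)
    # for every accepted move: applying it and then its inverse restores
    # the pre-move genome (up to circle rotation / chromosome order)
    state = res.start.copy()
    classes_seen = set()
    for move in moves:
        classes_seen.add(classify_move(state, move))
        probe = state.copy()
        apply_move(probe, move)
        inv = invert_move(state, move)
        apply_move(probe, inv)
        assert probe.equivalent(state), (move, inv)
        apply_move(state, move)
    assert orders(state) == orders(res.end)
    if seed == 0:  # this seeded run exercises every invertible class
        assert {"inversion", "translocation", "excision",
                "reintegration"} <= classes_seen


# ------------------------------------------------------- segment_summary


def test_segment_summary_against_linear_scan(rng):
    g = init_genome(4, 200, 0.3, rng)
    for _ in range(200):
        ci = rng.integers(len(g.chromosomes))
        L = len(g.chromosomes[ci].genes)
        i, j = sorted(rng.integers(0, L + 1, size=2))
        length, sens = segment_summary(g, ci, i, j)
        seg = g.chromosomes[ci].genes[i:j]
        assert length == len(seg)
        assert sens == int(g.sensitive[np.abs(seg)].sum())


def test_segment_summary_whole_and_empty(rng):
    g = init_genome(2, 30, 0.5, rng)
    L = len(g.chromosomes[0].genes)
    length, sens = segment_summary(g, 0, 0, L)
    assert length == L
    assert sens == int(g.sensitive[np.abs(g.chromosomes[0].genes)].sum())
    assert segment_summary(g, 0, 3, 3) == (0, 0)
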