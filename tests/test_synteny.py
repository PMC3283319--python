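"""Micro/macro-synteny statistics."""

import numpy as np
import pytest
from scipy.stats import chisquare

from conftest import build_genome
from dcjc.engine import run_simulation
from dcjc.fixtures import make_fixture
from dcjc.genome import init_genome
from dcjc.models import ModelConfig
from dcjc.synteny import (compare_genomes, dot_plot_matrix, macro_synteny_p,
                          micro_synteny_s, pal_homology, sample_markers)


def markers_all(genome):
    return np.arange(1, genome.n_genes + 1, dtype=np.int64)


# -------------------------------------------------------------- markers


def test_sample_markers_bounds(rng):
    g = init_genome(2, 50, 0.0, rng)
    m = sample_markers(g, 10, rng)
    assert len(np.unique(m)) == 10
    assert m.min() >= 1 and m.max() <= 50
    assert np.array_equal(sample_markers(g, 50, rng), markers_all(g))
    with pytest.raises(ValueError):
        sample_markers(g, 51, rng)
    with pytest.raises(ValueError):
        sample_markers(g, 0, rng)


def test_sample_markers_uniform_across_genome():
    g = init_genome(4, 400, 0.0, np.random.default_rng(0))
    counts = np.zeros(401)
    for seed in range(1000):
        counts[sample_markers(g, 40, seed)] += 1
    stat, p = chisquare(counts[1:])
    assert p > 1e-3


# ------------------------------------------------------------------- s


def test_s_identical_genomes(rng):
    g = init_genome(3, 60, 0.0, rng)
    assert micro_synteny_s(g, g.copy(), markers_all(g)) == 1.0


def test_s_single_translocation_hand_count():
    before, after, _ = make_fixture("single-translocation")
    m = markers_all(before)
    # 18 adjacencies in a, 2 broken by the reciprocal translocation
    assert micro_synteny_s(before, after, m) == pytest.approx(16 / 18)
    # symmetric: b gained 2 new adjacencies, lost the same 2
    assert micro_synteny_s(after, before, m) == pytest.approx(16 / 18)


def test_s_marker_reduction():
    a = build_genome([1, 2, 3, 4, 5, 6])
    b = build_genome([1, 3, 5], [2, 4, 6])
    m = np.array([1, 3, 5], dtype=np.int64)
    # reduced-a order (1,3,5): both adjacencies intact in b
    assert micro_synteny_s(a, b, m) == 1.0


def test_s_signed_vs_unsigned():
    a = build_genome([1, 2, 3, 4])
    b = build_genome([1, -2, 3, 4])
    m = markers_all(a)
    # unsigned: all 3 adjacencies conserved as unordered pairs
    assert micro_synteny_s(a, b, m) == 1.0
    # signed: (1,2) and (2,3) now disagree in relative orientation
    assert micro_synteny_s(a, b, m, signed=True) == pytest.approx(1 / 3)


def test_s_requires_two_markers(rng):
    g = init_genome(1, 10, 0.0, rng)
    with pytest.raises(ValueError):
        micro_synteny_s(g, g, np.array([3], dtype=np.int64))


def test_s_circular_wrap_adjacency_counts():
    a = build_genome(([1, 2, 3], True))
    b = build_genome([3, 1, 2])
    m = markers_all(a)
    # a's adjacencies: {1,2},{2,3},{3,1}; b has {3,1},{1,2}
    assert micro_synteny_s(a, b, m) == pytest.approx(2 / 3)


# ------------------------------------------------------------------- z


def test_pal_homology_identity(rng):
    g = init_genome(4, 80, 0.0, rng)
    hom = pal_homology(g, g.copy(), markers_all(g))
    assert np.array_equal(hom.best_match, np.arange(4))
    assert np.all(np.diag(hom.z) > 0)


def test_pal_homology_closed_form():
    # 3 PALs x 3 PALs with 10 markers per PAL of a, O given directly
    a = build_genome(list(range(1, 11)), list(range(11, 21)),
                     list(range(21, 31)))
    # b: PAL1 = a's PAL1; PAL2 = 8 of a's PAL2 + 2 of PAL3; PAL3 = rest
    b = build_genome(
        list(range(1, 11)),
        list(range(11, 19)) + [21, 22],
        [19, 20] + list(range(23, 31)),
    )
    m = markers_all(a)
    hom = pal_homology(a, b, m)
    O = hom.observed
    assert np.array_equal(O, [[10, 0, 0], [0, 8, 2], [0, 2, 8]])
    N = 30
    for i in range(3):
        for j in range(3):
            mi, mj = 10.0, hom.markers_b[j]
            E = mi * mj / N
            V = mi * (mj / N) * (1 - mj / N)
            assert hom.expected[i, j] == pytest.approx(E)
            assert hom.variance[i, j] == pytest.approx(V)
            assert hom.z[i, j] == pytest.approx((O[i, j] - E) / np.sqrt(V))
    assert list(hom.best_match) == [0, 1, 2]
    assert macro_synteny_p(a, b, m, hom=hom) == pytest.approx(26 / 30)


@pytest.mark.parametrize("c", [5, 20])
def test_p_saturates_at_one_over_c(c):
    n_genes = 100 * c
    run = run_simulation(ModelConfig.dcj(), 30 * n_genes, c=c,
                         n_genes=n_genes, seed=c)
    ps = [compare_genomes(run.start, run.end, rng=k).p for k in range(3)]
    p = float(np.mean(ps))
    assert abs(p - 1 / c) < max(2.5 / c, 0.03), p


def test_p_asymmetry_is_small_but_not_assumed_zero(rng):
    run = run_simulation(ModelConfig.ds(0.1), 800, c=5, n_genes=1000, seed=4)
    m = sample_markers(run.start, 600, rng)
    p_ab = macro_synteny_p(run.start, run.end, m)
    p_ba = macro_synteny_p(run.end, run.start, m)
    assert abs(p_ab - p_ba) < 0.1


def test_circular_fragment_markers_not_conserved():
    a = build_genome([1, 2, 3, 4, 5, 6])
    b = build_genome([1, 2, 5, 6], ([3, 4], True))
    m = markers_all(a)
    hom = pal_homology(a, b, m)
    # 4 of 6 markers still on the (homologous) linear chromosome
    assert macro_synteny_p(a, b, m, hom=hom) == pytest.approx(4 / 6)
    # but the circle's internal adjacency still counts for s
    assert micro_synteny_s(a, b, m) == pytest.approx(3 / 5)


def test_subsampled_estimates_marker_count_dependence():
    """p is robust to marker subsampling; s is scale-dependent.

    Macro-synteny is a per-marker chromosome-membership statistic, so a
    uniform subsample estimates the full-set value. Micro-synteny is an
    adjacency statistic on the marker-reduced order: sparser markers
    span longer gene paths and are less likely to stay adjacent, so the
    subsampled s lies at or below the full-set s. Marker counts must
    therefore be matched between compared genomes (as they are
    throughout) rather than assumed interchangeable.
    """
    run = run_simulation(ModelConfig.ds(0.08), 3000, c=10, n_genes=4000,
                         seed=11)
    full = compare_genomes(run.start, run.end)
    subs = [compare_genomes(run.start, run.end, n_markers=1500, rng=k)
            for k in range(5)]
    assert abs(np.mean([r.p for r in subs]) - full.p) < 0.05
    assert np.mean([r.s for r in subs]) <= full.s
    # replicate subsamples of equal size agree among themselves
    assert np.std([r.s for r in subs]) < 0.25 * np.mean([r.s for r in subs])


def test_dot_plot_matrix_shape(rng):
    run = run_simulation(ModelConfig.dcj(), 50, c=4, n_genes=200, seed=3)
    m = sample_markers(run.start, 80, rng)
    df = dot_plot_matrix(run.start, run.end, m)
    assert len(df) == 80
    assert set(df.columns) == {"gene_id", "pos_a", "pal_a", "pos_b", "pal_b"}
    same = dot_plot_matrix(run.start, run.start, m)
    assert (same["pos_a"] == same["pos_b"]).all()
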