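"""Hand-checkable toy genomes and matrices used in tests and examples."""

from __future__ import annotations

import numpy as np

from .genome import Chromosome, DCJMove, Genome, apply_move, classify_move

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("single-translocation", "ds-illegal-cut",
                 "ds-illegal-rejoin", "additive-tree")


def _two_by_ten() -> Genome:
    """Two linear chromosomes of ten genes each (ids 1..10 and 11..20)."""
    chroms = [Chromosome(np.arange(1, 11, dtype=np.int64)),
              Chromosome(np.arange(11, 21, dtype=np.int64))]
    sens = np.zeros(21, dtype=bool)
    anc = np.zeros(21, dtype=np.int64)
    anc[11:] = 1
    return Genome(chroms, sensitive=sens, ancestral=anc)


def make_fixture(kind: str, seed: int = 0):
    """Build one of the named toy fixtures.

    ``single-translocation``
        (genome_before, genome_after, move): a 2x10-gene genome and its
        image under one reciprocal (tail-swap) translocation at
        mid-chromosome; the marker adjacency count is checkable by hand
        (18 adjacencies before, 16 conserved).
    ``ds-illegal-cut``
        (genome, move): sensitive genes placed on both sides of each cut,
        so any reconnection changes the sensitive partition and the DS
        rule must reject the move.
    ``ds-illegal-rejoin``
        (genome, move): sensitive genes on both fragments that the rejoin
        would bring together — rejected by the DS rule.
    ``additive-tree``
        (distance_matrix, taxa, newick): a 5-taxon additive matrix
        generated from a known tree, for exact NJ recovery.
    """
    if kind == "single-translocation":
        before = _two_by_ten()
        move = DCJMove(chrom1=0, pos1=5, chrom2=1, pos2=5, rejoin=0,
                       move_class="translocation")
        assert classify_move(before, move) == "translocation"
        after = before.copy()
        apply_move(after, move)
        return before, after, move

    if kind == "ds-illegal-cut":
        genome = _two_by_ten()
        # sensitive genes straddle both cut points: {5,6} and {15,16}
        genome.sensitive[[5, 6, 15, 16]] = True
        move = DCJMove(chrom1=0, pos1=5, chrom2=1, pos2=5, rejoin=0,
                       move_class="translocation")
        return genome, move

    if kind == "ds-illegal-rejoin":
        genome = _two_by_ten()
        # one sensitive gene on each exchanged tail: 8 (chrom 0) and 18
        # (chrom 1); the swap joins them onto the same chromosomes' heads,
        # moving each to a new sensitive companion set.
        genome.sensitive[[2, 8, 12, 18]] = True
        move = DCJMove(chrom1=0, pos1=5, chrom2=1, pos2=5, rejoin=0,
                       move_class="translocation")
        return genome, move

    if kind == "additive-tree":
        # unrooted tree: ((A:2,B:3):4,(C:2,D:5):1,E:6)
        newick = "((A:2,B:3):4,(C:2,D:5):1,E:6);"
        taxa = ("A", "B", "C", "D", "E")
        paths = {
            ("A", "B"): 5, ("A", "C"): 9, ("A", "D"): 12, ("A", "E"): 12,
            ("B", "C"): 10, ("B", "D"): 13, ("B", "E"): 13,
            ("C", "D"): 7, ("C", "E"): 9, ("D", "E"): 12,
        }
        k = len(taxa)
        d = np.zeros((k, k))
        for (x, y), v in paths.items():
            i, j = taxa.index(x), taxa.index(y)
            d[i, j] = d[j, i] = v
        return d, taxa, newick

    raise ValueError(f"unknown fixture kind {kind!r}; "
                     f"expected one of {FIXTURE_KINDS}")
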