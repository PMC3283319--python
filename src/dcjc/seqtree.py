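"""Balanced-tree gene-order structure with reverse flags and subtree summaries.

Chromosomes are stored as randomized binary search trees (treaps) keyed
by position, with per-node subtree size and sensitive-gene counts and a
lazy "reverse" flag that flips both the order and the orientation of a
whole subtree in O(1). Splitting, joining, reversing and counting
sensitive genes on any fragment therefore all run in O(log N) expected
time, and the trees stay O(log N) high on average without explicit
rebalancing, so every DCJ move and every constraint query is
logarithmic in genome size.

A deliberately simple pure-Python list representation
(:class:`ListGenome`) is provided alongside as the independent oracle:
tests replay the same move sequence through both and require identical
gene orders after every step.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .genome import DCJMove, Genome, classify_move

__all__ = ["TreapChromosome", "TreapGenome", "ListGenome"]


class _Node:
    __slots__ = ("gene", "sens", "prio", "size", "scount", "rev",
                 "left", "right")

    def __init__(self, gene: int, sens: bool, prio: float) -> None:
        self.gene = gene
        self.sens = sens
        self.prio = prio
        self.size = 1
        self.scount = int(sens)
        self.rev = False
        self.left: "_Node | None" = None
        self.right: "_Node | None" = None


def _pull(t: _Node) -> None:
    t.size = 1 + (t.left.size if t.left else 0) + (t.right.size if t.right else 0)
    t.scount = int(t.sens) + (t.left.scount if t.left else 0) \
        + (t.right.scount if t.right else 0)


def _push(t: _Node) -> None:
    if t.rev:
        t.left, t.right = t.right, t.left
        t.gene = -t.gene
        if t.left:
            t.left.rev = not t.left.rev
        if t.right:
            t.right.rev = not t.right.rev
        t.rev = False


def _merge(a: _Node | None, b: _Node | None) -> _Node | None:
    if a is None:
        return b
    if b is None:
        return a
    if a.prio > b.prio:
        _push(a)
        a.right = _merge(a.right, b)
        _pull(a)
        return a
    _push(b)
    b.left = _merge(a, b.left)
    _pull(b)
    return b


def _split(t: _Node | None, k: int) -> tuple[_Node | None, _Node | None]:
    """First k elements to the left part, the rest to the right."""
    if t is None:
        return None, None
    _push(t)
    left_size = t.left.size if t.left else 0
    if k <= left_size:
        l, r = _split(t.left, k)
        t.left = r
        _pull(t)
        return l, t
    l, r = _split(t.right, k - left_size - 1)
    t.right = l
    _pull(t)
    return t, r


def _build(genes: Iterable[int], sens_lookup: np.ndarray,
           rng: np.random.Generator) -> _Node | None:
    root: _Node | None = None
    # right-spine insertion with random priorities; expected O(n log n)
    for g in genes:
        node = _Node(int(g), bool(sens_lookup[abs(int(g))]), float(rng.random()))
        root = _merge(root, node)
    return root


def _collect(t: _Node | None, rev: bool, out: list[int]) -> None:
    """In-order traversal honoring pending reverse flags, non-mutating."""
    if t is None:
        return
    eff = rev ^ t.rev
    first, second = (t.right, t.left) if eff else (t.left, t.right)
    _collect(first, eff, out)
    out.append(-t.gene if eff else t.gene)
    _collect(second, eff, out)


def _height(t: _Node | None) -> int:
    if t is None:
        return 0
    return 1 + max(_height(t.left), _height(t.right))


class TreapChromosome:
    """One chromosome held as an implicit treap."""

    def __init__(self, root: _Node | None, circular: bool) -> None:
        self.root = root
        self.circular = circular

    @classmethod
    def from_genes(cls, genes, sens_lookup: np.ndarray,
                   rng: np.random.Generator, circular: bool = False
                   ) -> "TreapChromosome":
        return cls(_build(genes, sens_lookup, rng), circular)

    def __len__(self) -> int:
        return self.root.size if self.root else 0

    def to_genes(self) -> list[int]:
        out: list[int] = []
        _collect(self.root, False, out)
        return out

    def height(self) -> int:
        return _height(self.root)

    def split(self, k: int) -> tuple[_Node | None, _Node | None]:
        return _split(self.root, k)

    def segment_summary(self, i: int, j: int) -> tuple[int, int]:
        """(length, sensitive count) of the gap interval [i, j)."""
        ab, c = _split(self.root, j)
        a, b = _split(ab, i)
        res = (b.size, b.scount) if b else (0, 0)
        self.root = _merge(_merge(a, b), c)
        return res


def _reverse(t: _Node | None) -> _Node | None:
    if t is not None:
        t.rev = not t.rev
    return t


class TreapGenome:
    """Genome mirror whose chromosomes live in treaps.

    Applies the same :class:`~dcjc.genome.DCJMove` objects as the flat
    representation, with every structural edit done through O(log N)
    split/merge/reverse operations.
    """

    def __init__(self, genome: Genome, seed: int | None = 0) -> None:
        rng = np.random.default_rng(seed)
        self.sensitive = genome.sensitive
        self.chromosomes = [
            TreapChromosome.from_genes(ch.genes, genome.sensitive, rng,
                                       ch.circular)
            for ch in genome.chromosomes
        ]

    def to_orders(self) -> list[tuple[bool, list[int]]]:
        return [(ch.circular, ch.to_genes()) for ch in self.chromosomes]

    def mean_height(self) -> float:
        hs = [ch.height() for ch in self.chromosomes if len(ch)]
        return float(np.mean(hs)) if hs else 0.0

    def max_height(self) -> int:
        return max((ch.height() for ch in self.chromosomes), default=0)

    def segment_summary(self, chrom: int, i: int, j: int) -> tuple[int, int]:
        return self.chromosomes[chrom].segment_summary(i, j)

    def apply(self, move: DCJMove, move_class: str) -> None:
        chroms = self.chromosomes
        k1, k2 = move.chrom1, move.chrom2
        if move.chrom1 == move.chrom2:
            ch = chroms[k1]
            i, j = move.pos1, move.pos2
            ab, c = _split(ch.root, j)
            a, m = _split(ab, i)
            if move_class == "inversion":
                ch.root = _merge(_merge(a, _reverse(m)), c)
            elif move_class == "excision":
                rest = _merge(a, c)
                if rest is None:
                    chroms[k1] = TreapChromosome(m, circular=True)
                else:
                    ch.root = rest
                    chroms.append(TreapChromosome(m, circular=True))
            else:  # circular fission
                chroms[k1] = TreapChromosome(m, circular=True)
                chroms.append(TreapChromosome(_merge(c, a), circular=True))
            return
        ch1, ch2 = chroms[k1], chroms[k2]
        if ch1.circular and ch2.circular:
            x1, y1 = _split(ch1.root, move.pos1)
            m1 = _merge(y1, x1)
            x2, y2 = _split(ch2.root, move.pos2)
            m2 = _merge(y2, x2)
            if move.rejoin == 1:
                m2 = _reverse(m2)
            chroms[k1] = TreapChromosome(_merge(m1, m2), circular=True)
            del chroms[k2]
            return
        if ch1.circular or ch2.circular:
            circ_k, lin_k = (k1, k2) if ch1.circular else (k2, k1)
            circ_pos = move.pos1 if ch1.circular else move.pos2
            lin_pos = move.pos2 if ch1.circular else move.pos1
            x, y = _split(chroms[circ_k].root, circ_pos)
            m = _merge(y, x)
            if move.rejoin == 1:
                m = _reverse(m)
            c_part, d_part = _split(chroms[lin_k].root, lin_pos)
            chroms[lin_k].root = _merge(_merge(c_part, m), d_part)
            del chroms[circ_k]
            return
        a, b = _split(ch1.root, move.pos1)
        c, d = _split(ch2.root, move.pos2)
        if move.rejoin == 0:
            new1, new2 = _merge(a, d), _merge(c, b)
        else:
            new1, new2 = _merge(a, _reverse(c)), _merge(_reverse(b), d)
        products = [p for p in (new1, new2) if p is not None]
        chroms[k1] = TreapChromosome(products[0], circular=False)
        if len(products) == 2:
            chroms[k2] = TreapChromosome(products[1], circular=False)
        else:
            del chroms[k2]


class ListGenome:
    """Naive pure-Python genome: one list of signed ints per chromosome.

    Implements moves by plain slicing — the transparent O(N) oracle the
    tree structure is checked against.
    """

    def __init__(self, genome: Genome) -> None:
        self.chromosomes = [
            (ch.circular, [int(g) for g in ch.genes])
            for ch in genome.chromosomes
        ]
        self.sensitive = genome.sensitive

    def to_orders(self) -> list[tuple[bool, list[int]]]:
        return [(circ, list(genes)) for circ, genes in self.chromosomes]

    def segment_summary(self, chrom: int, i: int, j: int) -> tuple[int, int]:
        genes = self.chromosomes[chrom][1][i:j]
        return len(genes), sum(bool(self.sensitive[abs(g)]) for g in genes)

    def apply(self, move: DCJMove, move_class: str) -> None:
        chroms = self.chromosomes

        def rev(seg: list[int]) -> list[int]:
            return [-g for g in reversed(seg)]

        k1, k2 = move.chrom1, move.chrom2
        if k1 == k2:
            circ, g = chroms[k1]
            i, j = move.pos1, move.pos2
            if move_class == "inversion":
                chroms[k1] = (circ, g[:i] + rev(g[i:j]) + g[j:])
            elif move_class == "excision":
                rest = g[:i] + g[j:]
                if rest:
                    chroms[k1] = (circ, rest)
                    chroms.append((True, g[i:j]))
                else:
                    chroms[k1] = (True, g[i:j])
            else:  # fission of a circle
                chroms[k1] = (True, g[i:j])
                chroms.append((True, g[j:] + g[:i]))
            return
        (c1, g1), (c2, g2) = chroms[k1], chroms[k2]
        if c1 and c2:
            m1 = g1[move.pos1:] + g1[: move.pos1]
            m2 = g2[move.pos2:] + g2[: move.pos2]
            if move.rejoin == 1:
                m2 = rev(m2)
            chroms[k1] = (True, m1 + m2)
            del chroms[k2]
            return
        if c1 or c2:
            circ_k, lin_k = (k1, k2) if c1 else (k2, k1)
            circ_pos = move.pos1 if c1 else move.pos2
            lin_pos = move.pos2 if c1 else move.pos1
            gc = chroms[circ_k][1]
            m = gc[circ_pos:] + gc[:circ_pos]
            if move.rejoin == 1:
                m = rev(m)
            gl = chroms[lin_k][1]
            chroms[lin_k] = (False, gl[:lin_pos] + m + gl[lin_pos:])
            del chroms[circ_k]
            return
        a, b = g1[: move.pos1], g1[move.pos1:]
        c, d = g2[: move.pos2], g2[move.pos2:]
        if move.rejoin == 0:
            new1, new2 = a + d, c + b
        else:
            new1, new2 = a + rev(c), rev(b) + d
        products = [p for p in (new1, new2) if p]
        chroms[k1] = (False, products[0])
        if len(products) == 2:
            chroms[k2] = (False, products[1])
        else:
            del chroms[k2]
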