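"""Genome representation and double-cut-and-join (DCJ) move mechanics.

A genome is a set of chromosomes, each an ordered sequence of oriented
genes. Genes are encoded as signed integers: ``+g`` for forward
orientation, ``-g`` for reverse, with gene identifiers ``1..N``. A DCJ
move cuts the genome at two adjacencies (including telomeric ends of
linear chromosomes) and reconnects the resulting free ends in one of the
two non-identity ways, realizing inversions, reciprocal translocations,
excisions and reintegrations of circular fragments, fissions and
fusions.

Two genome-level annotation arrays ride along with the gene order:
``sensitive`` (dosage-sensitivity flags, the basis of the DCJ-DS
constraint) and ``ancestral`` (the chromosome each gene occupied at
initialization, used as ground truth for synteny statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Chromosome",
    "Genome",
    "DCJMove",
    "MoveLog",
    "init_genome",
    "classify_move",
    "apply_move",
    "invert_move",
    "segment_summary",
    "MOVE_CLASSES",
    "INTER_CLASSES",
]

#: All move classes. "fission" is the splitting of a circular chromosome;
#: splitting a linear chromosome into two linear pieces is not a DCJ product
#: of two real cuts (it would require a telomere cap pair).
MOVE_CLASSES = (
    "inversion",
    "excision",
    "translocation",
    "fusion",
    "reintegration",
    "fission",
)

#: Classes that change which chromosome genes reside on (counted in n_t).
INTER_CLASSES = frozenset(
    ("excision", "translocation", "fusion", "reintegration", "fission")
)


@dataclass
class Chromosome:
    """An ordered sequence of oriented genes (signed int array)."""

    genes: np.ndarray
    circular: bool = False

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_adjacencies(self) -> int:
        """Number of cuttable adjacencies (telomeric ends included)."""
        return len(self.genes) + (0 if self.circular else 1)

    def copy(self) -> "Chromosome":
        return Chromosome(self.genes.copy(), self.circular)

    def canonical(self) -> tuple:
        """Orientation/rotation-invariant key.

        A linear chromosome equals its reversal (with all signs flipped);
        a circular chromosome additionally equals any rotation.
        """
        fwd = tuple(int(g) for g in self.genes)
        rev = tuple(-int(g) for g in self.genes[::-1])
        if not self.circular:
            return ("L",) + min(fwd, rev)
        best = None
        n = len(fwd)
        for seq in (fwd, rev):
            for r in range(n):
                cand = seq[r:] + seq[:r]
                if best is None or cand < best:
                    best = cand
        return ("C",) + (best or ())


class Genome:
    """A collection of chromosomes plus per-gene annotations.

    Parameters
    ----------
    chromosomes
        Chromosome objects; gene ids across all of them must form the
        set ``{1..N}`` exactly once each.
    sensitive
        Boolean array of length ``N + 1`` (index 0 unused): dosage
        sensitivity flag per gene id.
    ancestral
        Integer array of length ``N + 1``: 0-based index of the
        chromosome each gene occupied at initialization.
    """

    def __init__(
        self,
        chromosomes: Sequence[Chromosome],
        sensitive: np.ndarray | None = None,
        ancestral: np.ndarray | None = None,
    ) -> None:
        self.chromosomes: list[Chromosome] = list(chromosomes)
        n = sum(len(ch) for ch in self.chromosomes)
        if sensitive is None:
            sensitive = np.zeros(n + 1, dtype=bool)
        if ancestral is None:
            ancestral = np.zeros(n + 1, dtype=np.int64)
            for k, ch in enumerate(self.chromosomes):
                ancestral[np.abs(ch.genes)] = k
        self.sensitive = np.asarray(sensitive, dtype=bool)
        self.ancestral = np.asarray(ancestral, dtype=np.int64)

    # -- basic properties -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return sum(len(ch) for ch in self.chromosomes)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def n_adjacencies(self) -> int:
        return sum(ch.n_adjacencies for ch in self.chromosomes)

    def gene_ids(self) -> np.ndarray:
        """Sorted array of all gene ids present (for invariant checks)."""
        if not self.chromosomes:
            return np.array([], dtype=np.int64)
        return np.sort(np.abs(np.concatenate([ch.genes for ch in self.chromosomes])))

    def copy(self) -> "Genome":
        return Genome(
            [ch.copy() for ch in self.chromosomes],
            self.sensitive.copy(),
            self.ancestral.copy(),
        )

    def with_sensitive(self, sensitive: np.ndarray) -> "Genome":
        """Same gene order with a different sensitivity marking."""
        g = self.copy()
        g.sensitive = np.asarray(sensitive, dtype=bool)
        return g

    def sensitive_partition(self) -> frozenset:
        """Partition of sensitive gene ids by chromosome.

        The DCJ-DS constraint holds iff this value is invariant over a
        run. Chromosomes without sensitive genes contribute nothing.
        """
        blocks = []
        for ch in self.chromosomes:
            ids = np.abs(ch.genes)
            block = frozenset(int(i) for i in ids[self.sensitive[ids]])
            if block:
                blocks.append(block)
        return frozenset(blocks)

    def canonical(self) -> tuple:
        """Order/orientation-invariant form of the whole genome."""
        return tuple(sorted(ch.canonical() for ch in self.chromosomes))

    def equivalent(self, other: "Genome") -> bool:
        return self.canonical() == other.canonical()

    def validate(self) -> None:
        ids = self.gene_ids()
        n = len(ids)
        if n and not np.array_equal(ids, np.arange(1, n + 1)):
            raise ValueError("gene ids must be exactly 1..N, each once")
        for ch in self.chromosomes:
            if len(ch) == 0:
                raise ValueError("empty chromosome present")

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        kinds = sum(ch.circular for ch in self.chromosomes)
        return (
            f"<Genome {self.n_genes} genes, {self.n_chromosomes} chromosomes "
            f"({kinds} circular), {int(self.sensitive.sum())} sensitive>"
        )


def init_genome(
    c: int,
    n_genes: int,
    mu: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> Genome:
    """Create the starting genome: ``c`` linear chromosomes, ``n_genes`` genes.

    Chromosome sizes are ``floor(N/c)`` with the remainder distributed one
    gene each to the lowest-index chromosomes. Every gene starts in
    forward orientation; each is independently flagged sensitive with
    probability ``mu``.
    """
    if c < 1:
        raise ValueError("chromosome count must be >= 1")
    if n_genes < c:
        raise ValueError("need at least one gene per chromosome")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("sensitive fraction mu must be in [0, 1]")
    rng = np.random.default_rng(rng)

    base, rem = divmod(n_genes, c)
    sizes = [base + (1 if k < rem else 0) for k in range(c)]
    chromosomes = []
    start = 1
    ancestral = np.zeros(n_genes + 1, dtype=np.int64)
    for k, size in enumerate(sizes):
        ids = np.arange(start, start + size, dtype=np.int64)
        ancestral[ids] = k
        chromosomes.append(Chromosome(ids, circular=False))
        start += size
    sensitive = np.zeros(n_genes + 1, dtype=bool)
    sensitive[1:] = rng.random(n_genes) < mu
    return Genome(chromosomes, sensitive, ancestral)


@dataclass(frozen=True)
class DCJMove:
    """Two cut points plus a rejoin choice.

    ``chrom1``/``chrom2`` index into ``genome.chromosomes``; ``pos1``/``pos2``
    are 0-based gap indices (for a linear chromosome of length L, gaps
    ``0..L`` with 0 and L telomeric; for a circular one, gaps ``0..L-1``
    with gap 0 the wrap adjacency). ``rejoin`` selects between the two
    non-identity reconnections (see :func:`apply_move`). For cuts on one
    chromosome ``pos1 < pos2``; for two chromosomes ``chrom1 < chrom2``
    by convention of the proposal machinery.
    """

    chrom1: int
    pos1: int
    chrom2: int
    pos2: int
    rejoin: int
    move_class: str = ""

    @property
    def same_chromosome(self) -> bool:
        return self.chrom1 == self.chrom2


def _rev(seg: np.ndarray) -> np.ndarray:
    return -seg[::-1]


def classify_move(genome: Genome, move: DCJMove) -> str:
    """Move class as a pure function of cut geometry, rejoin, and topology."""
    ch1 = genome.chromosomes[move.chrom1]
    if move.same_chromosome:
        if move.pos1 == move.pos2:
            raise ValueError("cut points must be distinct")
        if ch1.circular:
            return "inversion" if move.rejoin == 0 else "fission"
        return "inversion" if move.rejoin == 0 else "excision"
    ch2 = genome.chromosomes[move.chrom2]
    if ch1.circular and ch2.circular:
        return "fusion"
    if ch1.circular or ch2.circular:
        return "reintegration"
    # two linear chromosomes: fusion iff exactly one product is empty
    la, lb = move.pos1, len(ch1) - move.pos1
    lc, ld = move.pos2, len(ch2) - move.pos2
    if move.rejoin == 0:  # products a+d, c+b
        empty1, empty2 = (la == 0 and ld == 0), (lc == 0 and lb == 0)
    else:  # products a+rev(c), rev(b)+d
        empty1, empty2 = (la == 0 and lc == 0), (lb == 0 and ld == 0)
    if empty1 and empty2:
        raise ValueError("degenerate move on two empty chromosomes")
    return "fusion" if (empty1 or empty2) else "translocation"


def apply_move(genome: Genome, move: DCJMove) -> Genome:
    """Apply a DCJ move in place and return the genome.

    Gene content is preserved; only adjacencies implied by the rejoin
    change. Empty chromosome products are dropped; a new circular
    fragment is appended at the end of the chromosome list.
    """
    cls = classify_move(genome, move)
    chroms = genome.chromosomes
    k1, k2 = move.chrom1, move.chrom2

    if move.same_chromosome:
        ch = chroms[k1]
        g = ch.genes
        i, j = move.pos1, move.pos2
        if cls == "inversion":
            ch.genes = np.concatenate([g[:i], _rev(g[i:j]), g[j:]])
        elif cls == "excision":
            mid = g[i:j].copy()
            rest = np.concatenate([g[:i], g[j:]])
            if len(rest):
                ch.genes = rest
                chroms.append(Chromosome(mid, circular=True))
            else:  # circularization of the whole chromosome
                chroms[k1] = Chromosome(mid, circular=True)
        else:  # fission of a circular chromosome into two circles
            mid = g[i:j].copy()
            rest = np.concatenate([g[j:], g[:i]])
            chroms[k1] = Chromosome(mid, circular=True)
            chroms.append(Chromosome(rest, circular=True))
        return genome

    ch1, ch2 = chroms[k1], chroms[k2]
    if ch1.circular and ch2.circular:
        m1 = np.concatenate([ch1.genes[move.pos1 :], ch1.genes[: move.pos1]])
        m2 = np.concatenate([ch2.genes[move.pos2 :], ch2.genes[: move.pos2]])
        if move.rejoin == 1:
            m2 = _rev(m2)
        chroms[k1] = Chromosome(np.concatenate([m1, m2]), circular=True)
        del chroms[k2]
        return genome
    if ch1.circular or ch2.circular:
        if ch1.circular:
            circ_k, lin_k = k1, k2
            circ_pos, lin_pos = move.pos1, move.pos2
        else:
            circ_k, lin_k = k2, k1
            circ_pos, lin_pos = move.pos2, move.pos1
        circ, lin = chroms[circ_k], chroms[lin_k]
        m = np.concatenate([circ.genes[circ_pos:], circ.genes[:circ_pos]])
        if move.rejoin == 1:
            m = _rev(m)
        lin.genes = np.concatenate([lin.genes[:lin_pos], m, lin.genes[lin_pos:]])
        del chroms[circ_k]
        return genome

    # two linear chromosomes
    a, b = ch1.genes[: move.pos1], ch1.genes[move.pos1 :]
    c, d = ch2.genes[: move.pos2], ch2.genes[move.pos2 :]
    if move.rejoin == 0:
        new1, new2 = np.concatenate([a, d]), np.concatenate([c, b])
    else:
        new1, new2 = np.concatenate([a, _rev(c)]), np.concatenate([_rev(b), d])
    products = [p for p in (new1, new2) if len(p)]
    if not products:
        raise ValueError("move would empty the genome")
    chroms[k1] = Chromosome(products[0], circular=False)
    if len(products) == 2:
        chroms[k2] = Chromosome(products[1], circular=False)
    else:
        del chroms[k2]
    return genome


def invert_move(genome: Genome, move: DCJMove) -> DCJMove:
    """The move that undoes ``move`` if applied right after it.

    DCJ is reversible: re-cutting the two freshly created junctions and
    choosing the reconnection that restores the old adjacencies inverts
    the move. ``genome`` must be in the *pre-move* state.
    """
    cls = classify_move(genome, move)
    ch1 = genome.chromosomes[move.chrom1]
    if cls == "inversion":
        return move  # self-inverse
    if cls == "excision":
        # circle (appended last, cut at its wrap gap) reintegrates at pos1
        rest_len = len(ch1) - (move.pos2 - move.pos1)
        new_circle = len(genome.chromosomes) if rest_len else move.chrom1
        if rest_len == 0:
            raise ValueError("circularization inverse requires a linear target")
        return DCJMove(move.chrom1, move.pos1, new_circle, 0, 0)
    if cls == "translocation":
        if move.rejoin == 0:  # products a+d, c+b: cut back at |a| and |c|
            return DCJMove(move.chrom1, move.pos1, move.chrom2, move.pos2, 0)
        # products a+rev(c), rev(b)+d: cut back at |a| and |b|
        return DCJMove(move.chrom1, move.pos1, move.chrom2, len(ch1) - move.pos1, 1)
    if cls == "fission":
        # circles [i, j) at chrom1 and the remainder appended last;
        # inverse: circular fusion at their wrap gaps
        return DCJMove(move.chrom1, 0, len(genome.chromosomes), 0, 0)
    if cls == "reintegration":
        # the circular chromosome is deleted; the linear one absorbs it
        ch2 = genome.chromosomes[move.chrom2]
        if ch1.circular:
            circ_k, lin_k, lin_pos, clen = (move.chrom1, move.chrom2,
                                            move.pos2, len(ch1.genes))
        else:
            circ_k, lin_k, lin_pos, clen = (move.chrom2, move.chrom1,
                                            move.pos1, len(ch2.genes))
        lin_after = lin_k - (1 if circ_k < lin_k else 0)
        return DCJMove(lin_after, lin_pos, lin_after, lin_pos + clen, 1)
    if cls == "fusion":
        if ch1.circular:  # circle + circle -> one circle; inverse: fission
            split = len(ch1.genes)
            merged = move.chrom1 - (1 if move.chrom2 < move.chrom1 else 0)
            return DCJMove(merged, 0, merged, split, 1)
        raise ValueError(
            "fusion of two linear chromosomes has no single-move inverse in "
            "this cut/rejoin repertoire (linear fission is not proposable)")
    raise NotImplementedError(f"inverse not provided for class {cls!r}")


def segment_summary(
    genome: Genome, chrom: int, start: int, stop: int
) -> tuple[int, int]:
    """(gene count, sensitive count) over gap interval ``[start, stop)``."""
    ch = genome.chromosomes[chrom]
    if not 0 <= start <= stop <= len(ch):
        raise ValueError("segment out of range")
    seg = np.abs(ch.genes[start:stop])
    return len(seg), int(genome.sensitive[seg].sum())


@dataclass
class MoveLog:
    """Tallies of proposed/accepted moves for a simulation run."""

    accepted_by_class: dict = field(
        default_factory=lambda: {cls: 0 for cls in MOVE_CLASSES}
    )
    proposed: int = 0
    rejected_by_model: int = 0
    resampled_coincident: int = 0

    @property
    def n(self) -> int:
        return sum(self.accepted_by_class.values())

    @property
    def n_t(self) -> int:
        return sum(v for k, v in self.accepted_by_class.items() if k in INTER_CLASSES)

    @property
    def n_inversions(self) -> int:
        return self.accepted_by_class["inversion"]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "n_t": self.n_t,
            "proposed": self.proposed,
            "rejected_by_model": self.rejected_by_model,
            "resampled_coincident": self.resampled_coincident,
            **{f"accepted_{k}": v for k, v in self.accepted_by_class.items()},
        }
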