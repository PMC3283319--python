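"""Pairwise synteny conservation statistics.

Two summary statistics describe how much of the gene order of genome *a*
survives in genome *b*, both computed on a set of single-copy marker
genes:

* micro-synteny ``s`` — the fraction of marker-gene adjacencies of *a*
  (in the marker-reduced gene order) that are also adjacencies of *b*;
* macro-synteny ``p`` — the fraction of markers that lie on homologous
  chromosomes (putative ancestral linkage groups, PALs) in the two
  genomes, with PAL homology assigned by the z-score of the shared
  marker count against a binomial saturation model.

For simulated genomes a PAL is simply a (linear) chromosome; markers on
excised circular fragments have no PAL and count as non-conserved for
``p``, while their internal adjacencies still count for ``s``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome

__all__ = [
    "sample_markers",
    "micro_synteny_s",
    "pal_homology",
    "macro_synteny_p",
    "compare_genomes",
    "dot_plot_matrix",
    "PALHomology",
    "SyntenyResult",
]

logger = logging.getLogger(__name__)

_ENC = np.int64(1) << 32  # adjacency key packing base


def sample_markers(
    genome: Genome, n_markers: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Uniform sample of marker gene ids, without replacement."""
    n = genome.n_genes
    if n_markers > n:
        raise ValueError(f"cannot sample {n_markers} markers from {n} genes")
    if n_markers < 1:
        raise ValueError("need at least one marker")
    rng = np.random.default_rng(rng)
    return np.sort(rng.choice(n, size=n_markers, replace=False) + 1).astype(np.int64)


def _marker_lookup(genome: Genome, markers: np.ndarray) -> np.ndarray:
    is_marker = np.zeros(genome.n_genes + 1, dtype=bool)
    is_marker[markers] = True
    return is_marker


def _reduced_orders(genome: Genome, is_marker: np.ndarray):
    """Marker-only gene order per chromosome (non-markers spliced out)."""
    out = []
    for ch in genome.chromosomes:
        keep = is_marker[np.abs(ch.genes)]
        out.append((ch.circular, ch.genes[keep]))
    return out


def _adjacency_keys(orders, signed: bool) -> np.ndarray:
    keys = []
    for circular, arr in orders:
        if len(arr) < 2:
            continue
        x, y = arr[:-1], arr[1:]
        if circular:
            x = np.concatenate([x, arr[-1:]])
            y = np.concatenate([y, arr[:1]])
        if signed:
            # adjacency (x -> y) equals its mirror (-y -> -x)
            off = np.int64(1) << 30
            e1 = (x + off) * _ENC + (y + off)
            e2 = (-y + off) * _ENC + (-x + off)
            keys.append(np.minimum(e1, e2))
        else:
            u, v = np.abs(x), np.abs(y)
            keys.append(np.minimum(u, v) * _ENC + np.maximum(u, v))
    if not keys:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(keys))


def micro_synteny_s(
    a: Genome, b: Genome, markers: np.ndarray, signed: bool = False
) -> float:
    """Fraction of marker adjacencies of ``a`` conserved in ``b``.

    Both genomes are first reduced to the marker genes (neighbors of a
    removed gene become adjacent); by default adjacency is unordered and
    orientation-blind, ``signed=True`` requires relative orientation to
    match as well.
    """
    if len(markers) < 2:
        raise ValueError("micro-synteny needs at least two markers")
    is_marker = _marker_lookup(a, markers)
    adj_a = _adjacency_keys(_reduced_orders(a, is_marker), signed)
    adj_b = _adjacency_keys(_reduced_orders(b, is_marker), signed)
    if len(adj_a) == 0:
        raise ValueError("genome a has no marker adjacencies")
    shared = np.intersect1d(adj_a, adj_b, assume_unique=True)
    return len(shared) / len(adj_a)


def _pal_assignment(genome: Genome) -> tuple[np.ndarray, int]:
    """PAL index per gene id (-1 for genes on circular fragments)."""
    pal = np.full(genome.n_genes + 1, -1, dtype=np.int64)
    n_pals = 0
    for ch in genome.chromosomes:
        if ch.circular:
            continue
        pal[np.abs(ch.genes)] = n_pals
        n_pals += 1
    return pal, n_pals


@dataclass
class PALHomology:
    """Best-match chromosome homology between two genomes.

    ``z[i, j]`` scores the observed number of shared markers between PAL
    ``i`` of genome a and PAL ``j`` of genome b against the binomial
    saturation expectation E = m_i m_j / N and variance
    V = m_i (m_j/N)(1 - m_j/N); ``best_match[i]`` is the argmax of row
    ``i`` (-1 where undefined because the PAL carries no markers).
    """

    observed: np.ndarray
    expected: np.ndarray
    variance: np.ndarray
    z: np.ndarray
    best_match: np.ndarray
    markers_a: np.ndarray
    markers_b: np.ndarray
    n_markers: int


def pal_homology(a: Genome, b: Genome, markers: np.ndarray) -> PALHomology:
    """Assign each PAL of ``a`` its highest-z-score homolog among ``b``'s PALs."""
    pal_a, na = _pal_assignment(a)
    pal_b, nb = _pal_assignment(b)
    pa = pal_a[markers]
    pb = pal_b[markers]
    n_m = len(markers)

    m_a = np.bincount(pa[pa >= 0], minlength=na).astype(float)
    m_b = np.bincount(pb[pb >= 0], minlength=nb).astype(float)
    both = (pa >= 0) & (pb >= 0)
    obs = np.bincount(pa[both] * nb + pb[both], minlength=na * nb).reshape(na, nb)
    obs = obs.astype(float)

    expected = np.outer(m_a, m_b) / n_m
    q = m_b / n_m
    variance = m_a[:, None] * (q * (1.0 - q))[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - expected) / np.sqrt(variance)

    empty_a = m_a == 0
    empty_b = m_b == 0
    if empty_a.any() or empty_b.any():
        logger.info(
            "excluding %d/%d marker-free PALs from homology",
            int(empty_a.sum()), int(empty_b.sum()),
        )
    score = np.where(np.isfinite(z), z, -np.inf)
    score[:, empty_b] = -np.inf
    if nb > 0 and not empty_b.all():
        best = np.argmax(score, axis=1)
    else:
        best = np.full(na, -1, dtype=np.int64)
    best = np.where(empty_a | ~np.isfinite(score.max(axis=1, initial=-np.inf)),
                    -1, best)
    return PALHomology(obs, expected, variance, z, best, m_a, m_b, n_m)


def macro_synteny_p(
    a: Genome, b: Genome, markers: np.ndarray, hom: PALHomology | None = None
) -> float:
    """Fraction of markers residing on homologous PALs of ``a`` and ``b``."""
    if hom is None:
        hom = pal_homology(a, b, markers)
    pal_a, _ = _pal_assignment(a)
    pal_b, _ = _pal_assignment(b)
    pa = pal_a[markers]
    pb = pal_b[markers]
    ok = (pa >= 0) & (pb >= 0)
    conserved = np.zeros(len(markers), dtype=bool)
    conserved[ok] = hom.best_match[pa[ok]] == pb[ok]
    return float(conserved.mean())


@dataclass
class SyntenyResult:
    """Pairwise conservation statistics on a marker subset."""

    s: float
    p: float
    n_markers: int


def compare_genomes(
    a: Genome,
    b: Genome,
    n_markers: int | None = None,
    markers: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    signed: bool = False,
) -> SyntenyResult:
    """Compute (s, p) between two genomes on a sampled marker set."""
    if markers is None:
        if n_markers is None:
            n_markers = a.n_genes
        markers = sample_markers(a, n_markers, rng)
    hom = pal_homology(a, b, markers)
    return SyntenyResult(
        s=micro_synteny_s(a, b, markers, signed=signed),
        p=macro_synteny_p(a, b, markers, hom=hom),
        n_markers=len(markers),
    )


def dot_plot_matrix(a: Genome, b: Genome, markers: np.ndarray) -> pd.DataFrame:
    """Marker positions for a whole-genome comparison dot plot.

    Positions are ranks in each genome's concatenated gene order with
    chromosomes in list order (circular fragments at their list
    position), restricted to the marker set. One row per marker.
    """
    def positions(genome: Genome):
        pos = np.zeros(genome.n_genes + 1, dtype=np.int64)
        pal = np.full(genome.n_genes + 1, -1, dtype=np.int64)
        cursor = 0
        pal_idx = 0
        for ch in genome.chromosomes:
            ids = np.abs(ch.genes)
            pos[ids] = np.arange(cursor, cursor + len(ids))
            if not ch.circular:
                pal[ids] = pal_idx
                pal_idx += 1
            cursor += len(ids)
        return pos, pal

    pos_a, pal_a = positions(a)
    pos_b, pal_b = positions(b)
    return pd.DataFrame(
        {
            "gene_id": markers,
            "pos_a": pos_a[markers],
            "pal_a": pal_a[markers],
            "pos_b": pos_b[markers],
            "pal_b": pal_b[markers],
        }
    )
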