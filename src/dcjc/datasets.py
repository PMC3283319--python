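"""Bundled example data: pairwise synteny statistics for five metazoan genomes.

Published whole-genome comparisons of five anciently diverged metazoans
— human (Hs), lancelet (Bf), sea anemone (Nv), placozoan (Ta) and
sponge (Aq) — report, for each genome pair, the number of single-copy
marker genes compared, the observed macro-synteny conservation ``p``
and micro-synteny conservation ``s``, and the rearrangement count ``n``,
sensitive-gene percentage ``mu`` and inter-chromosomal count ``n_t``
obtained by fitting the dosage-sensitivity (DS) rearrangement model to
the pair. These numbers parameterize the worked examples, the
neighbor-joining tree, and the multi-lineage conservation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TAXA",
    "TAXON_NAMES",
    "PairStats",
    "PAIRWISE",
    "N_FAMILIES",
    "FIVE_WAY_OBSERVED",
    "pairwise_table",
    "distance_matrix",
]

#: Short labels of the five genomes, in canonical order.
TAXA = ("Hs", "Bf", "Nv", "Ta", "Aq")

#: Full species names for the short labels.
TAXON_NAMES = {
    "Hs": "Homo sapiens (human)",
    "Bf": "Branchiostoma floridae (lancelet)",
    "Nv": "Nematostella vectensis (sea anemone)",
    "Ta": "Trichoplax adhaerens (placozoan)",
    "Aq": "Amphimedon queenslandica (sponge)",
}


@dataclass(frozen=True)
class PairStats:
    """Observed and DS-model-fitted statistics for one genome pair.

    ``markers`` is the number of single-copy orthologs compared, ``p``
    and ``s`` the observed macro-/micro-synteny conservation, and
    ``n`` (accepted rearrangements), ``mu`` (sensitive fraction) and
    ``n_t`` (inter-chromosomal rearrangements) the DS-model fit.
    """

    a: str
    b: str
    markers: int
    p: float
    s: float
    n: int
    mu: float
    n_t: int


_ROWS = [
    # a,   b,   markers, p,   s,     n,     mu,     n_t
    ("Hs", "Bf", 4408, 0.58, 0.0218, 26441, 0.0727, 1712),
    ("Hs", "Nv", 3451, 0.45, 0.0038, 49650, 0.0793, 2931),
    ("Hs", "Ta", 3557, 0.51, 0.0138, 30122, 0.0696, 2115),
    ("Hs", "Aq", 2400, 0.35, 0.0038, 49550, 0.0689, 3328),
    ("Bf", "Nv", 3972, 0.51, 0.0055, 42970, 0.0817, 2431),
    ("Bf", "Ta", 3970, 0.59, 0.0229, 25492, 0.0739, 1637),
    ("Bf", "Aq", 2690, 0.42, 0.0082, 35917, 0.0662, 2602),
    ("Nv", "Ta", 2664, 0.39, 0.0141, 30652, 0.0775, 1868),
    ("Nv", "Aq", 3972, 0.57, 0.0049, 43878, 0.0690, 3092),
    ("Ta", "Aq", 2953, 0.44, 0.0152, 27394, 0.0596, 2232),
]

#: All ten pairwise comparisons, keyed by frozenset of taxon labels.
PAIRWISE = {frozenset((r[0], r[1])): PairStats(*r) for r in _ROWS}

#: Number of single-copy gene families present in all five genomes.
N_FAMILIES = 1144

#: Observed number of those families with five-way conserved macro-synteny.
FIVE_WAY_OBSERVED = 298


def pairwise_table() -> list[PairStats]:
    """All ten pairwise rows in canonical (upper-triangle) order."""
    return [PAIRWISE[frozenset((a, b))]
            for i, a in enumerate(TAXA) for b in TAXA[i + 1:]]


def distance_matrix(field: str = "n") -> tuple[np.ndarray, tuple[str, ...]]:
    """Symmetric 5x5 distance matrix from one fitted field (``n`` or ``n_t``)."""
    k = len(TAXA)
    d = np.zeros((k, k), dtype=float)
    for i, a in enumerate(TAXA):
        for j, b in enumerate(TAXA):
            if i != j:
                d[i, j] = getattr(PAIRWISE[frozenset((a, b))], field)
    return d, TAXA
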