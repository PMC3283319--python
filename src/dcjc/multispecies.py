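"""Multi-lineage simulations and multi-way synteny conservation counts.

A root genome evolves independently along the branches of a star or a
resolved (Newick) phylogeny; a common set of marker gene families is
then scored for conservation across all leaves. Two sensitive-set modes
distinguish the dosage-sensitivity hypothesis from its null: ``shared``
keeps one sensitive-gene set for every branch, ``independent`` redraws
the set (at the same fraction) per branch, preserving the rearrangement
dynamics but destroying cross-lineage correlation in which genes are
constrained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .engine import run_simulation
from .genome import Genome, init_genome
from .models import ModelConfig
from .synteny import pal_homology, sample_markers, _pal_assignment

__all__ = [
    "TreeSimSpec",
    "ConservationCount",
    "simulate_star",
    "simulate_tree",
    "star_pool",
    "count_multiway_conserved",
    "multiway_experiment",
    "expected_independent",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TreeSimSpec:
    """Specification of a multi-lineage simulation.

    ``branch_moves`` maps leaf/branch names to accepted-move counts for a
    star tree, or is ignored when ``newick`` is given (branch lengths are
    then read from the tree, in accepted-move units). ``mode`` selects
    shared vs. independently redrawn sensitive-gene sets per branch.
    """

    config: ModelConfig
    c: int = 20
    n_genes: int = 20000
    mode: str = "shared"
    branch_moves: dict = field(default_factory=dict)
    newick: str | None = None
    n_families: int = 1144

    def __post_init__(self) -> None:
        if self.mode not in ("shared", "independent"):
            raise ValueError("mode must be 'shared' or 'independent'")


@dataclass
class ConservationCount:
    """Multi-way conservation of marker families across leaves."""

    n_families: int
    k_conserved: int
    per_replicate: list[int] = field(default_factory=list)

    @property
    def fraction(self) -> float:
        return self.k_conserved / self.n_families


def _seed_stream(seed):
    ss = np.random.SeedSequence(seed)
    while True:
        (child,) = ss.spawn(1)
        yield int(child.generate_state(1)[0] % (2**31))
        ss = child


def _branch_genome(root: Genome, spec: TreeSimSpec, seeds) -> Genome:
    """Root genome with the branch's sensitive set (shared or redrawn)."""
    if spec.mode == "shared":
        return root
    rng = np.random.default_rng(next(seeds))
    sens = np.zeros(root.n_genes + 1, dtype=bool)
    sens[1:] = rng.random(root.n_genes) < spec.config.mu
    return root.with_sensitive(sens)


def simulate_star(spec: TreeSimSpec, n_leaves: int, branch_n: int,
                  seed: int = 0, root: Genome | None = None
                  ) -> tuple[Genome, dict[str, Genome]]:
    """Evolve one root genome along ``n_leaves`` independent branches."""
    seeds = _seed_stream(seed)
    if root is None:
        root = init_genome(spec.c, spec.n_genes, spec.config.mu,
                           np.random.default_rng(next(seeds)))
    else:
        next(seeds)
    leaves = {}
    for i in range(n_leaves):
        start = _branch_genome(root, spec, seeds)
        res = run_simulation(spec.config, branch_n, c=spec.c,
                             n_genes=spec.n_genes, seed=next(seeds),
                             genome=start)
        leaves[f"L{i + 1}"] = res.end
    return root, leaves


def simulate_tree(spec: TreeSimSpec, seed: int = 0,
                  root: Genome | None = None
                  ) -> tuple[Genome, dict[str, Genome]]:
    """Evolve a root genome along a resolved Newick tree.

    Branch lengths are accepted-move counts (rounded to integers);
    internal nodes pass their end genome to child branches. Returns the
    root genome and a mapping of leaf names to leaf genomes.
    """
    if spec.newick is None:
        raise ValueError("spec.newick is required for simulate_tree")
    tree = TreeNode.read([spec.newick])
    seeds = _seed_stream(seed)
    if root is None:
        root = init_genome(spec.c, spec.n_genes, spec.config.mu,
                           np.random.default_rng(next(seeds)))
    else:
        next(seeds)

    leaves: dict[str, Genome] = {}

    def descend(node, genome: Genome) -> None:
        for child in node.children:
            n = int(round(child.length or 0))
            start = _branch_genome(genome, spec, seeds)
            if n > 0:
                res = run_simulation(spec.config, n, c=spec.c,
                                     n_genes=spec.n_genes,
                                     seed=next(seeds), genome=start)
                end = res.end
            else:
                end = start.copy()
            if child.is_tip():
                if child.name is None:
                    raise ValueError("unnamed leaf in tree")
                leaves[child.name] = end
            else:
                descend(child, end)

    descend(tree, root)
    return root, leaves


def star_pool(spec: TreeSimSpec, branch_n: int, pool_size: int = 100,
              seed: int = 0) -> tuple[Genome, list[Genome]]:
    """Pool of independent realizations of length ``branch_n`` from one root.

    Supports the resampling protocol in which ``k`` pool members at a
    time are drawn without replacement and treated as the leaves of a
    star phylogeny.
    """
    root, leaves = simulate_star(spec, pool_size, branch_n, seed=seed)
    return root, list(leaves.values())


def count_multiway_conserved(
    root: Genome,
    leaves,
    n_families: int,
    seed: int = 0,
    markers: np.ndarray | None = None,
) -> ConservationCount:
    """Count marker families conserved in every leaf.

    A family counts as conserved iff, in every leaf, it lies on the PAL
    that is the best z-score match of its root (ancestral) chromosome.
    """
    leaves = list(leaves.values()) if isinstance(leaves, dict) else list(leaves)
    if markers is None:
        markers = sample_markers(root, n_families, seed)
    pal_root, _ = _pal_assignment(root)
    pr = pal_root[markers]
    conserved = pr >= 0
    for leaf in leaves:
        hom = pal_homology(root, leaf, markers)
        pal_leaf, _ = _pal_assignment(leaf)
        pl = pal_leaf[markers]
        ok = conserved & (pl >= 0)
        ok[ok] = hom.best_match[pr[ok]] == pl[ok]
        conserved = ok
    return ConservationCount(len(markers), int(conserved.sum()))


def multiway_experiment(
    spec: TreeSimSpec,
    n_leaves: int,
    branch_n: int,
    replicates: int,
    seed: int = 0,
) -> ConservationCount:
    """Replicated star simulations with per-replicate multi-way counts."""
    seeds = _seed_stream(seed)
    counts = []
    for _ in range(replicates):
        root, leaves = simulate_star(spec, n_leaves, branch_n,
                                     seed=next(seeds))
        cc = count_multiway_conserved(root, leaves, spec.n_families,
                                      seed=next(seeds))
        counts.append(cc.k_conserved)
    total = ConservationCount(spec.n_families, int(np.round(np.mean(counts))),
                              per_replicate=counts)
    return total


def expected_independent(p_values, k: int, n_families: int) -> float:
    """Expected k-way conserved families under independent gene movement.

    With pairwise conservation approximately q^2 for per-branch retention
    q on a star tree, q = sqrt(mean p) and the expectation is
    ``n_families * q**k``.
    """
    p_values = list(p_values)
    if not p_values:
        raise ValueError("need at least one pairwise p value")
    if not all(0 < p <= 1 for p in p_values):
        raise ValueError("p values must lie in (0, 1]")
    q = float(np.mean(p_values)) ** 0.5
    return n_families * q**k
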