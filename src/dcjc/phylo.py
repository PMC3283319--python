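"""Neighbor-joining trees from rearrangement distances, and PHYLIP IO.

The fitted rearrangement counts of pairwise model fits serve as additive
distances; the tree is built with the standard Saitou–Nei
neighbor-joining algorithm (via scikit-bio). Distance matrices are read
and written in the PHYLIP square format, trees in Newick.
"""

from __future__ import annotations

import io
import logging

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = [
    "nj_tree",
    "read_phylip",
    "write_phylip",
    "sisters",
    "tree_to_newick",
]

logger = logging.getLogger(__name__)


def _validate(distances: np.ndarray, taxa) -> np.ndarray:
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if len(taxa) != d.shape[0]:
        raise ValueError("taxa count does not match matrix size")
    if len(taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return d


def nj_tree(distances: np.ndarray, taxa) -> TreeNode:
    """Unrooted Saitou–Nei neighbor-joining tree.

    Negative branch lengths (possible on non-additive input) are clamped
    to zero with a log entry.
    """
    d = _validate(distances, taxa)
    tree = nj(DistanceMatrix(d, ids=list(taxa)))
    n_clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    if n_clamped:
        logger.info("clamped %d negative branch lengths to 0", n_clamped)
    return tree


def sisters(tree: TreeNode, a: str, b: str) -> bool:
    """True iff leaves ``a`` and ``b`` form a cherry (share an internal node)."""
    node = tree.find(a)
    parent = node.parent
    if parent is None:
        return False
    leaves = [tip.name for tip in parent.tips()]
    return sorted(leaves) == sorted([a, b])


def write_phylip(distances: np.ndarray, taxa, path) -> None:
    """Write a PHYLIP square distance matrix."""
    d = _validate(distances, taxa)
    with open(path, "w") as fh:
        fh.write(f"{len(taxa)}\n")
        for name, row in zip(taxa, d):
            label = f"{name:<10s}"[:10]
            fh.write(label + "  ".join(f"{x:.6f}" for x in row) + "\n")


def read_phylip(path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a PHYLIP square distance matrix; returns (matrix, taxa)."""
    if hasattr(path, "read"):
        fh = path
        lines = fh.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError("empty PHYLIP file")
    try:
        k = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError("malformed PHYLIP header") from exc
    if len(lines) - 1 < k:
        raise ValueError(f"expected {k} matrix rows, found {len(lines) - 1}")
    taxa = []
    rows = []
    for ln in lines[1:1 + k]:
        name = ln[:10].strip()
        vals = ln[10:].split()
        if len(vals) != k:
            # tolerate whitespace-separated labels longer/shorter than 10
            parts = ln.split()
            name, vals = parts[0], parts[1:]
        if len(vals) != k:
            raise ValueError(f"row for {name!r} has {len(vals)} values, expected {k}")
        taxa.append(name)
        rows.append([float(v) for v in vals])
    return np.array(rows, dtype=float), tuple(taxa)


def tree_to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
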