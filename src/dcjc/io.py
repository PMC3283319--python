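"""Genome file IO and run manifests.

Genomes are stored in the GRIMM-style signed-permutation format: a
``>name`` header, then one chromosome per line as whitespace-separated
signed integers, terminated by ``$`` (linear) or ``@`` (circular).
Sensitive flags and ancestral chromosome labels live in an optional
sidecar TSV with columns ``gene_id``, ``sensitive``,
``ancestral_chromosome``; without a sidecar, no genes are sensitive and
the ancestral chromosome defaults to the current one.

Every CLI run writes a JSON manifest (command, configuration, seeds,
package version, wall time per stage, SHA-256 of every output) that
suffices to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .genome import Chromosome, Genome

__all__ = [
    "read_genome",
    "write_genome",
    "RunManifest",
    "sha256_file",
]


def write_genome(genome: Genome, path, name: str = "genome",
                 sidecar: bool = True) -> None:
    """Write a genome in GRIMM-style format (+ sensitive/ancestral sidecar)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for ch in genome.chromosomes:
            terminator = "@" if ch.circular else "$"
            fh.write(" ".join(str(int(g)) for g in ch.genes)
                     + f" {terminator}\n")
    if sidecar:
        side = path.with_suffix(path.suffix + ".tsv")
        with open(side, "w") as fh:
            fh.write("gene_id\tsensitive\tancestral_chromosome\n")
            for gid in range(1, genome.n_genes + 1):
                fh.write(f"{gid}\t{int(genome.sensitive[gid])}\t"
                         f"{int(genome.ancestral[gid])}\n")


def read_genome(path, sidecar: bool | None = None) -> Genome:
    """Read a GRIMM-style genome file.

    ``sidecar=None`` loads ``<path>.tsv`` if it exists; ``True`` requires
    it; ``False`` ignores it (no sensitive genes, ancestral = current
    chromosome).
    """
    path = Path(path)
    chromosomes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(">") or line.startswith("#"):
                continue
            tokens = line.split()
            if tokens[-1] not in ("$", "@"):
                raise ValueError(
                    f"{path}:{lineno}: chromosome line must end in $ or @")
            circular = tokens[-1] == "@"
            try:
                genes = np.array([int(t) for t in tokens[:-1]], dtype=np.int64)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed token") from exc
            if np.any(genes == 0):
                raise ValueError(f"{path}:{lineno}: gene id 0 is not allowed")
            chromosomes.append(Chromosome(genes, circular=circular))

    all_ids = np.concatenate([np.abs(ch.genes) for ch in chromosomes]) \
        if chromosomes else np.empty(0, dtype=np.int64)
    n = len(all_ids)
    counts = np.bincount(all_ids, minlength=n + 1)
    if np.any(counts[1:] != 1):
        dup = int(np.flatnonzero(counts[1:] != 1)[0]) + 1
        raise ValueError(f"{path}: gene id {dup} is duplicated or missing "
                         f"(ids must be exactly 1..{n})")

    sensitive = np.zeros(n + 1, dtype=bool)
    ancestral = np.zeros(n + 1, dtype=np.int64)
    for idx, ch in enumerate(chromosomes):
        ancestral[np.abs(ch.genes)] = idx

    side = path.with_suffix(path.suffix + ".tsv")
    if sidecar is True and not side.exists():
        raise FileNotFoundError(f"required sidecar {side} not found")
    if sidecar is not False and side.exists():
        with open(side) as fh:
            header = fh.readline().strip().split("\t")
            if header[:3] != ["gene_id", "sensitive", "ancestral_chromosome"]:
                raise ValueError(f"{side}: unexpected sidecar header")
            for lineno, raw in enumerate(fh, start=2):
                if not raw.strip():
                    continue
                try:
                    gid_s, sens_s, anc_s = raw.strip().split("\t")
                    gid = int(gid_s)
                    sensitive[gid] = bool(int(sens_s))
                    ancestral[gid] = int(anc_s)
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{side}:{lineno}: malformed row") from exc
    return Genome(chromosomes, sensitive=sensitive, ancestral=ancestral)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one CLI run."""

    command: str
    config: dict
    seed: int | None
    version: str = __version__
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    _t0: float = field(default_factory=time.monotonic, repr=False)

    def stage_done(self, name: str) -> None:
        now = time.monotonic()
        self.stages[name] = round(now - self._t0, 4)
        self._t0 = now

    def add_output(self, path) -> None:
        self.outputs[str(path)] = sha256_file(path)

    def write(self, path) -> None:
        payload = {
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "wall_time_s": self.stages,
            "output_sha256": self.outputs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
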