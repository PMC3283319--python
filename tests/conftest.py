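import numpy as np
import pytest

from dcjc.genome import Chromosome, Genome


def build_genome(*chrom_specs, n_genes=None, sensitive=()):
    """Genome from explicit chromosome gene lists.

    ``chrom_specs`` are (genes, circular) pairs or plain lists (linear).
    ``sensitive`` lists sensitive gene ids.
    """
    chroms = []
    for spec in chrom_specs:
        if isinstance(spec, tuple):
            genes, circular = spec
        else:
            genes, circular = spec, False
        chroms.append(Chromosome(np.asarray(genes, dtype=np.int64),
                                 circular=circular))
    if n_genes is None:
        n_genes = int(max(abs(int(g)) for spec in chrom_specs
                          for g in (spec[0] if isinstance(spec, tuple) else spec)))
    sens = np.zeros(n_genes + 1, dtype=bool)
    for gid in sensitive:
        sens[gid] = True
    anc = np.zeros(n_genes + 1, dtype=np.int64)
    for idx, ch in enumerate(chroms):
        anc[np.abs(ch.genes)] = idx
    return Genome(chroms, sensitive=sens, ancestral=anc)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
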