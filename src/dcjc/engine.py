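"""Rejection-sampling simulation loop for the DCJ-[C] model family.

Moves are proposed by drawing two distinct cut points uniformly at random
over all adjacencies of the genome (telomeric ends included, unless
disabled in the model config) plus a uniform choice between the two
non-identity reconnections, then accepted or rejected by the active
model's rule until the requested number of moves has been accepted.

Proposals are evaluated in vectorized batches against flat per-chromosome
prefix-sum arrays, which makes the heavy rejection regimes (DCJ-DS,
DCJ-maxT, DCJ-pfix reject the vast majority of inter-chromosomal
proposals) fast; the accepted move is then applied to the genome and the
flat arrays are rebuilt. Batch evaluation is semantically identical to
one-at-a-time proposing: within a batch the first acceptable proposal is
taken and the rest are discarded unseen.

Randomness is split into three child streams of one seed: genome
initialization, proposal draws, and model acceptance draws (the pfix
Bernoulli trials). Keeping the acceptance draws on their own stream makes
every model reproduce the plain-DCJ accepted-move sequence bit for bit at
its limiting parameter value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .genome import DCJMove, Genome, MoveLog, apply_move, init_genome
from .models import ModelConfig

__all__ = ["run_simulation", "SimulationResult", "SimulationStalledError"]

# class codes used in batch evaluation
_INV, _EXC, _TRA, _FUS, _REI, _FIS = range(6)
_CLASS_NAMES = ("inversion", "excision", "translocation", "fusion",
                "reintegration", "fission")
_INTER_CODES = (_EXC, _TRA, _FUS, _REI, _FIS)


class SimulationStalledError(RuntimeError):
    """Raised when the proposal budget is exhausted without progress."""


class _FlatState:
    """Concatenated per-chromosome arrays for vectorized move evaluation."""

    __slots__ = ("lengths", "circ", "starts", "prefix", "slot_offsets",
                 "total_slots")

    def __init__(self, genome: Genome, telomeric: bool) -> None:
        self.rebuild(genome, telomeric)

    def rebuild(self, genome: Genome, telomeric: bool) -> None:
        chroms = genome.chromosomes
        self.lengths = np.fromiter((len(c) for c in chroms), dtype=np.int64,
                                   count=len(chroms))
        self.circ = np.fromiter((c.circular for c in chroms), dtype=bool,
                                count=len(chroms))
        self.starts = np.concatenate(([0], np.cumsum(self.lengths)))
        if chroms:
            order = np.concatenate([c.genes for c in chroms])
            sens = genome.sensitive[np.abs(order)].astype(np.int64)
        else:
            sens = np.empty(0, dtype=np.int64)
        self.prefix = np.concatenate(([0], np.cumsum(sens)))
        if telomeric:
            slots = self.lengths + (~self.circ)
        else:
            # internal adjacencies only: L-1 for linear, L for circular
            slots = self.lengths - (~self.circ)
        self.slot_offsets = np.concatenate(([0], np.cumsum(slots)))
        self.total_slots = int(self.slot_offsets[-1])


def _evaluate_batch(state: _FlatState, config: ModelConfig,
                    s1, s2, r, gate_u):
    """Classify a batch of proposals and apply the model's acceptance rule.

    Returns (valid, accept, cls, k1, loc1, k2, loc2, r_eff) arrays. A
    proposal is invalid if its two cut points coincide (resampled) or its
    geometry is degenerate.
    """
    off = state.slot_offsets
    P = state.prefix
    starts, lengths, circ = state.starts, state.lengths, state.circ
    telo = config.allow_telomeric_cuts

    valid = s1 != s2
    k1 = np.searchsorted(off, s1, side="right") - 1
    k2 = np.searchsorted(off, s2, side="right") - 1
    loc1 = s1 - off[k1]
    loc2 = s2 - off[k2]
    if not telo:
        # local slot i maps to internal gap i+1 on linear chromosomes
        loc1 = loc1 + (~circ[k1])
        loc2 = loc2 + (~circ[k2])

    # canonical order: same chromosome -> pos1 < pos2; else chrom1 < chrom2
    swap = (k1 > k2) | ((k1 == k2) & (loc1 > loc2))
    k1, k2 = np.where(swap, k2, k1), np.where(swap, k1, k2)
    loc1, loc2 = np.where(swap, loc2, loc1), np.where(swap, loc1, loc2)
    valid &= ~((k1 == k2) & (loc1 == loc2))

    st1, st2 = starts[k1], starts[k2]
    L1, L2 = lengths[k1], lengths[k2]
    c1, c2 = circ[k1], circ[k2]

    same = (k1 == k2) & valid
    same_lin = same & ~c1
    same_circ = same & c1
    diff = (k1 != k2) & valid
    ll = diff & ~c1 & ~c2
    lc = diff & (c1 ^ c2)
    cc = diff & c1 & c2

    # sensitive counts of the canonical fragments
    Sa1 = P[st1 + loc1] - P[st1]
    Sb1 = P[st1 + L1] - P[st1 + loc1]
    Sa2 = P[st2 + loc2] - P[st2]
    Sb2 = P[st2 + L2] - P[st2 + loc2]
    Stot1 = P[st1 + L1] - P[st1]
    Stot2 = P[st2 + L2] - P[st2]
    Sm = P[st1 + loc2] - P[st1 + loc1]          # same-chromosome middle
    Srest = Stot1 - Sm                           # same-chromosome remainder
    lm = loc2 - loc1                             # middle length (same chrom)

    la, lb = loc1, L1 - loc1
    lc_, ld = loc2, L2 - loc2

    # identity handling on two linear chromosomes: when the chosen rejoin
    # reconstructs the original adjacencies, take the other one (which is
    # then a fusion). Both identities at once cannot happen on non-empty
    # chromosomes, but guard anyway.
    sw_id = ((la == 0) & (lc_ == 0)) | ((lb == 0) & (ld == 0))
    cr_id = ((la == 0) & (ld == 0)) | ((lb == 0) & (lc_ == 0))
    valid &= ~(ll & sw_id & cr_id)
    r_eff = r.astype(np.int64).copy()
    r_eff[ll & (r == 0) & sw_id & ~cr_id] = 1
    r_eff[ll & (r == 1) & cr_id & ~sw_id] = 0

    cls = np.zeros(len(s1), dtype=np.int64)
    cls[same_lin] = np.where(r_eff[same_lin] == 0, _INV, _EXC)
    cls[same_circ] = np.where(r_eff[same_circ] == 0, _INV, _FIS)
    ll_fus = np.where(r_eff == 0, cr_id, sw_id)  # other rejoin's identity
    cls[ll] = np.where(ll_fus[ll], _FUS, _TRA)
    cls[lc] = _REI
    cls[cc] = _FUS

    model = config.model
    accept = np.ones(len(s1), dtype=bool)
    if model == "ds":
        acc = np.ones(len(s1), dtype=bool)
        cut_out = (Sm == 0) | (Srest == 0)       # excision / circular fission
        acc[same & (r_eff == 1)] = cut_out[same & (r_eff == 1)]
        swap_ok = ((Sb1 == 0) & (Sb2 == 0)) | ((Sa1 == 0) & (Sa2 == 0))
        cross_ok = ((Sb1 == 0) & (Sa2 == 0)) | ((Sa1 == 0) & (Sb2 == 0))
        acc[ll] = np.where(r_eff[ll] == 0, swap_ok[ll], cross_ok[ll])
        whole_ok = (Stot1 == 0) | (Stot2 == 0)   # circle moves as one block
        acc[lc | cc] = whole_ok[lc | cc]
        accept = acc
    elif model in ("maxT", "maxL"):
        t = config.t_max if model == "maxT" else config.l_max
        acc = np.ones(len(s1), dtype=bool)
        exc = same & (r_eff == 1) & ~c1          # excised fragment size cap
        acc[exc] = lm[exc] <= t
        tra = ll & (cls == _TRA)
        swap_ok = ((la <= t) & (lc_ <= t)) | ((lb <= t) & (ld <= t))
        cross_ok = ((lb <= t) & (lc_ <= t)) | ((la <= t) & (ld <= t))
        acc[tra] = np.where(r_eff[tra] == 0, swap_ok[tra], cross_ok[tra])
        if model == "maxL":
            inv = same & (r_eff == 0)            # inverted fragment size cap
            acc[inv] = lm[inv] <= t
        accept = acc
    elif model == "pfix":
        if config.gate_all_inter:
            gated = cls != _INV
        else:
            gated = (cls == _TRA) | (cls == _EXC)
        accept = ~gated | (gate_u < config.p_fix)
    # model == "dcj": accept everything

    return valid, accept & valid, cls, k1, loc1, k2, loc2, r_eff


@dataclass
class SimulationResult:
    """Start and end genomes plus the move tally of one run."""

    start: Genome
    end: Genome
    log: MoveLog


def run_simulation(
    config: ModelConfig,
    n_moves: int,
    c: int = 20,
    n_genes: int = 20000,
    seed: int | np.random.SeedSequence | None = None,
    genome: Genome | None = None,
    max_proposals: int = 10**9,
    checkpoint_every: int | None = None,
    checkpoint_fn: Callable[[int, Genome], bool | None] | None = None,
    move_callback: Callable[[DCJMove, Genome], None] | None = None,
) -> SimulationResult:
    """Run one DCJ-[C] simulation until ``n_moves`` moves are accepted.

    Parameters
    ----------
    config
        The model variant and its parameter.
    n_moves
        Number of accepted moves to apply.
    c, n_genes
        Starting genome shape (ignored when ``genome`` is given).
    seed
        Seed for all three random streams (init / proposals / acceptance).
    genome
        Evolve a copy of this genome instead of initializing a fresh one;
        its sensitive flags are kept (used for shared-constraint
        multi-lineage simulations).
    checkpoint_every, checkpoint_fn
        Call ``checkpoint_fn(n_accepted, genome)`` after every
        ``checkpoint_every`` accepted moves (and once at move 0); a truthy
        return stops the run early.
    move_callback
        Called as ``move_callback(move, genome)`` after each accepted move
        is applied — used by tests to drive mirror data structures.

    Returns
    -------
    SimulationResult with a deep copy of the start genome, the evolved
    genome, and the move log.
    """
    if n_moves < 0:
        raise ValueError("n_moves must be >= 0")
    ss = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence) else seed
    init_ss, prop_ss, model_ss = ss.spawn(3)
    if genome is None:
        genome = init_genome(c, n_genes, config.mu,
                             np.random.default_rng(init_ss))
    else:
        genome = genome.copy()
    start = genome.copy()
    prop_rng = np.random.default_rng(prop_ss)
    model_rng = np.random.default_rng(model_ss)

    log = MoveLog()
    state = _FlatState(genome, config.allow_telomeric_cuts)
    if state.total_slots < 2:
        raise ValueError("genome has fewer than 2 cuttable adjacencies")

    if checkpoint_fn is not None and checkpoint_fn(0, genome):
        return SimulationResult(start, genome, log)

    accepted = 0
    batch = 16
    while accepted < n_moves:
        if log.proposed + log.resampled_coincident > max_proposals:
            raise SimulationStalledError(
                f"no acceptable move found within {max_proposals} proposals "
                f"({accepted}/{n_moves} accepted)")
        draws = prop_rng.integers(0, state.total_slots, size=(batch, 2))
        r = prop_rng.integers(0, 2, size=batch)
        gate_u = (model_rng.random(batch) if config.model == "pfix"
                  else np.empty(0))
        valid, ok, cls, k1, loc1, k2, loc2, r_eff = _evaluate_batch(
            state, config, draws[:, 0], draws[:, 1], r, gate_u)
        hits = np.flatnonzero(ok)
        if hits.size:
            i = int(hits[0])
            examined = i + 1
        else:
            i = -1
            examined = batch
        n_invalid = int(np.count_nonzero(~valid[:examined]))
        log.resampled_coincident += n_invalid
        log.proposed += examined - n_invalid
        log.rejected_by_model += int(
            np.count_nonzero(valid[:examined] & ~ok[:examined]))
        if i < 0:
            # widen the batch when acceptance is rare
            batch = min(4096, batch * 2)
            continue
        move = DCJMove(int(k1[i]), int(loc1[i]), int(k2[i]), int(loc2[i]),
                       int(r_eff[i]), _CLASS_NAMES[int(cls[i])])
        apply_move(genome, move)
        log.accepted_by_class[move.move_class] += 1
        accepted += 1
        state.rebuild(genome, config.allow_telomeric_cuts)
        if move_callback is not None:
            move_callback(move, genome)
        if (checkpoint_fn is not None and checkpoint_every
                and accepted % checkpoint_every == 0):
            if checkpoint_fn(accepted, genome):
                break
        # keep the batch size near twice the observed proposals-per-accept
        target = 2 * max(1, (log.proposed + log.resampled_coincident)
                         // max(1, accepted))
        batch = int(min(4096, max(8, target)))
    return SimulationResult(start, genome, log)
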