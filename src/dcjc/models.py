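"""Acceptance rules for DCJ and its one-parameter constrained extensions.

Each model proposes DCJ moves uniformly at random and accepts or rejects
them:

``dcj``
    Unconstrained: every proposal is accepted.
``ds``
    Dosage-sensitivity: a fraction ``mu`` of genes is flagged sensitive;
    a move is accepted only if the partition of sensitive genes among
    chromosomes is unchanged, i.e. one side of each breakpoint is free of
    sensitive genes both before and after the move.
``maxT``
    Translocations are allowed only if one pair of exchanged fragments
    are both no longer than ``t_max`` genes; excisions only if the
    excised fragment is no longer than ``t_max``. All other moves pass.
``maxL``
    The ``maxT`` rules (with ``l_max`` as the threshold) plus rejection
    of inversions whose inverted fragment exceeds ``l_max``.
``pfix``
    Inter-chromosomal moves are accepted by a Bernoulli trial with
    success probability ``p_fix``; intra-chromosomal moves always pass.

Every model reduces to plain DCJ at a limiting parameter (mu=0,
t_max=inf, l_max=inf, p_fix=1).

The functions here are the scalar reference implementations, written for
clarity; the simulation loop uses the vectorized equivalents in
:mod:`dcjc.engine`, which are tested against these.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome import DCJMove, Genome, classify_move, segment_summary

__all__ = [
    "ModelConfig",
    "accept_ds",
    "accept_maxT",
    "accept_maxL",
    "accept_pfix",
    "accept_move",
    "sensitive_partition_unchanged",
]

MODEL_NAMES = ("dcj", "ds", "maxT", "maxL", "pfix")


@dataclass(frozen=True)
class ModelConfig:
    """Which DCJ-[C] variant to run, plus its single parameter.

    ``gate_all_inter`` controls the scope of the ``pfix`` Bernoulli gate:
    by default every inter-chromosomal class (translocation, excision,
    reintegration, fission, fusion) is gated, consistent with the model's
    purpose of reducing the frequency, not the size, of inter-chromosomal
    rearrangement; set it to False to gate only the literal
    translocation/excision classes.

    ``allow_telomeric_cuts`` keeps telomeric ends in the cut-point
    universe (so fusions are proposable); disable to restrict cuts to
    internal adjacencies.
    """

    model: str = "dcj"
    mu: float = 0.0
    t_max: float = math.inf
    l_max: float = math.inf
    p_fix: float = 1.0
    gate_all_inter: bool = True
    allow_telomeric_cuts: bool = True

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODEL_NAMES}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if not 0.0 <= self.p_fix <= 1.0:
            raise ValueError("p_fix must be in [0, 1]")
        if self.t_max < 0 or self.l_max < 0:
            raise ValueError("size thresholds must be non-negative")

    # -- constructors ------------------------------------------------------

    @classmethod
    def dcj(cls) -> "ModelConfig":
        return cls("dcj")

    @classmethod
    def ds(cls, mu: float) -> "ModelConfig":
        return cls("ds", mu=mu)

    @classmethod
    def max_t(cls, t_max: float) -> "ModelConfig":
        return cls("maxT", t_max=t_max)

    @classmethod
    def max_l(cls, l_max: float) -> "ModelConfig":
        return cls("maxL", l_max=l_max)

    @classmethod
    def pfix(cls, p_fix: float) -> "ModelConfig":
        return cls("pfix", p_fix=p_fix)

    @property
    def parameter(self) -> float:
        """The model's single free parameter value."""
        return {
            "dcj": math.nan,
            "ds": self.mu,
            "maxT": self.t_max,
            "maxL": self.l_max,
            "pfix": self.p_fix,
        }[self.model]

    def with_parameter(self, value: float) -> "ModelConfig":
        field = {"ds": "mu", "maxT": "t_max", "maxL": "l_max", "pfix": "p_fix"}
        if self.model == "dcj":
            return self
        kwargs = {
            "mu": self.mu,
            "t_max": self.t_max,
            "l_max": self.l_max,
            "p_fix": self.p_fix,
            "gate_all_inter": self.gate_all_inter,
            "allow_telomeric_cuts": self.allow_telomeric_cuts,
        }
        kwargs[field[self.model]] = value
        return ModelConfig(self.model, **kwargs)


def _fragment_stats(genome: Genome, move: DCJMove):
    """Lengths and sensitive counts of the fragments a move creates.

    Returns a dict keyed by fragment label; labels depend on geometry:
    same-chromosome cuts give ``a`` (prefix), ``m`` (middle), ``b``
    (suffix); two-chromosome cuts give ``a``/``b`` around cut 1 and
    ``c``/``d`` around cut 2 (whole circles count as single fragments
    ``m`` and ``y`` in the mixed case).
    """
    ch1 = genome.chromosomes[move.chrom1]
    if move.same_chromosome:
        i, j = move.pos1, move.pos2
        la, sa = segment_summary(genome, move.chrom1, 0, i)
        lm, sm = segment_summary(genome, move.chrom1, i, j)
        lb, sb = segment_summary(genome, move.chrom1, j, len(ch1))
        return {"a": (la, sa), "m": (lm, sm), "b": (lb, sb)}
    ch2 = genome.chromosomes[move.chrom2]
    if ch1.circular or ch2.circular:
        circ_k, lin_k = (
            (move.chrom1, move.chrom2) if ch1.circular else (move.chrom2, move.chrom1)
        )
        if ch1.circular and ch2.circular:
            lm, sm = segment_summary(genome, move.chrom1, 0, len(ch1))
            ly, sy = segment_summary(genome, move.chrom2, 0, len(ch2))
        else:
            lm, sm = segment_summary(genome, circ_k, 0, len(genome.chromosomes[circ_k]))
            ly, sy = segment_summary(genome, lin_k, 0, len(genome.chromosomes[lin_k]))
        return {"m": (lm, sm), "y": (ly, sy)}
    la, sa = segment_summary(genome, move.chrom1, 0, move.pos1)
    lb, sb = segment_summary(genome, move.chrom1, move.pos1, len(ch1))
    lc, sc = segment_summary(genome, move.chrom2, 0, move.pos2)
    ld, sd = segment_summary(genome, move.chrom2, move.pos2, len(ch2))
    return {"a": (la, sa), "b": (lb, sb), "c": (lc, sc), "d": (ld, sd)}


def accept_ds(genome: Genome, move: DCJMove) -> bool:
    """Dosage-sensitivity rule: sensitive partition must be unchanged."""
    cls = classify_move(genome, move)
    fr = _fragment_stats(genome, move)
    if cls == "inversion":
        return True
    if cls in ("excision", "fission"):
        if cls == "excision":
            sm = fr["m"][1]
            srest = fr["a"][1] + fr["b"][1]
        else:  # circular fission: middle arc vs the rest of the circle
            sm = fr["m"][1]
            srest = fr["a"][1] + fr["b"][1]
        return sm == 0 or srest == 0
    if cls == "reintegration":
        return fr["m"][1] == 0 or fr["y"][1] == 0
    if cls == "fusion" and "m" in fr:  # circle + circle
        return fr["m"][1] == 0 or fr["y"][1] == 0
    # translocation or linear fusion: products are (a+d, c+b) for rejoin 0
    # and (a+rev(c), rev(b)+d) for rejoin 1; the sensitive partition is
    # unchanged iff one side of each breakpoint carries no sensitive gene.
    sa, sb, sc, sd = fr["a"][1], fr["b"][1], fr["c"][1], fr["d"][1]
    if move.rejoin == 0:
        return (sb == 0 and sd == 0) or (sa == 0 and sc == 0)
    return (sb == 0 and sc == 0) or (sa == 0 and sd == 0)


def accept_maxT(genome: Genome, move: DCJMove, t_max: float) -> bool:
    """Size cap on exchanged translocation fragments and excised fragments."""
    cls = classify_move(genome, move)
    if cls == "translocation":
        fr = _fragment_stats(genome, move)
        la, lb, lc, ld = fr["a"][0], fr["b"][0], fr["c"][0], fr["d"][0]
        if move.rejoin == 0:
            return (la <= t_max and lc <= t_max) or (lb <= t_max and ld <= t_max)
        return (lb <= t_max and lc <= t_max) or (la <= t_max and ld <= t_max)
    if cls == "excision":
        return _fragment_stats(genome, move)["m"][0] <= t_max
    return True  # all other moves are accepted


def accept_maxL(genome: Genome, move: DCJMove, l_max: float) -> bool:
    """maxT rules plus a cap on the inverted fragment length."""
    cls = classify_move(genome, move)
    if cls == "inversion":
        return _fragment_stats(genome, move)["m"][0] <= l_max
    return accept_maxT(genome, move, l_max)


def accept_pfix(
    genome: Genome,
    move: DCJMove,
    p_fix: float,
    rng: np.random.Generator,
    gate_all_inter: bool = True,
) -> bool:
    """Bernoulli gate on inter-chromosomal moves."""
    if not 0.0 <= p_fix <= 1.0:
        raise ValueError("p_fix must be in [0, 1]")
    cls = classify_move(genome, move)
    gated = (
        cls != "inversion"
        if gate_all_inter
        else cls in ("translocation", "excision")
    )
    if not gated:
        return True
    return bool(rng.random() < p_fix)


def accept_move(
    genome: Genome,
    move: DCJMove,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
) -> bool:
    """Dispatch to the configured model's acceptance rule."""
    if config.model == "dcj":
        return True
    if config.model == "ds":
        return accept_ds(genome, move)
    if config.model == "maxT":
        return accept_maxT(genome, move, config.t_max)
    if config.model == "maxL":
        return accept_maxL(genome, move, config.l_max)
    if rng is None:
        raise ValueError("pfix model needs an RNG for its Bernoulli trial")
    return accept_pfix(genome, move, config.p_fix, rng, config.gate_all_inter)


def sensitive_partition_unchanged(before: Genome, after: Genome) -> bool:
    """Brute-force check of the DCJ-DS invariant (test oracle)."""
    return before.sensitive_partition() == after.sensitive_partition()
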