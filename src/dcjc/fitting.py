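"""Chi-square model fitting of rearrangement simulations to observed synteny.

Given an observed pair of synteny statistics (macro-synteny ``p`` and
micro-synteny ``s`` on a known marker count), a model's free parameter
and the accepted-move count ``n`` are estimated by minimizing

    chi2(n, theta) = ((mean_s - s_obs)/sigma_s)^2 + ((mean_p - p_obs)/sigma_p)^2

where means and standard deviations are taken over replicate seeded
simulation runs. Estimation runs in two phases: alternating
one-dimensional Brent minimizations over ``n`` and the parameter,
then a 7x7 grid spanning +/-15% of the phase-one optimum with a
least-squares quadratic surface whose stationary point is reported.

The entry point follows the statsmodels convention: construct a
:class:`SyntenyDivergenceModel`, call :meth:`~SyntenyDivergenceModel.fit`,
inspect the returned :class:`SyntenyFitResult`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .engine import run_simulation
from .models import ModelConfig
from .synteny import compare_genomes, sample_markers

__all__ = [
    "ObservedPair",
    "ChiSquare",
    "chi_square",
    "SyntenyDivergenceModel",
    "SyntenyFitResult",
    "fit_parameters",
]

logger = logging.getLogger(__name__)

#: Brent bracketing intervals for the free parameter of each model.
_PARAM_BOUNDS = {
    "ds": (0.0, 0.5),
    "maxT": (1.0, 2000.0),
    "maxL": (1.0, 2000.0),
    "pfix": (-7.0, 0.0),  # log10(p_fix)
}
_N_BOUNDS = (1e2, 1e5)


@dataclass(frozen=True)
class ObservedPair:
    """Observed synteny statistics for one genome pair."""

    name: str
    markers: int
    p: float
    s: float

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 and 0 <= self.s <= 1):
            raise ValueError("p and s must lie in [0, 1]")
        if self.markers < 2:
            raise ValueError("markers must be >= 2")


@dataclass(frozen=True)
class ChiSquare:
    """One chi-square evaluation with its replicate summaries."""

    chi2: float
    mean_s: float
    mean_p: float
    sigma_s: float
    sigma_p: float
    mean_n_t: float
    replicates: int


def chi_square(
    config: ModelConfig,
    n: int,
    observed: ObservedPair,
    replicates: int = 10,
    seed: int = 0,
    c: int = 20,
    n_genes: int = 20000,
    sigma_floor: float = 1e-4,
) -> ChiSquare:
    """Chi-square distance between replicate simulations and an observation.

    Runs ``replicates`` seeded simulations of ``n`` accepted moves,
    measures (s, p) on ``observed.markers`` sampled markers per run, and
    returns the squared normalized deviations of the replicate means.
    Replicate standard deviations below ``sigma_floor`` are floored (and
    logged) so degenerate settings such as ``n = 0`` stay finite.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    ss = np.empty(replicates)
    ps = np.empty(replicates)
    nts = np.empty(replicates)
    root = np.random.SeedSequence(seed)
    children = root.spawn(replicates)
    for i, child in enumerate(children):
        sim_seed, marker_seed = (int(s.generate_state(1)[0] % (2**31))
                                 for s in child.spawn(2))
        res = run_simulation(config, int(round(n)), c=c, n_genes=n_genes,
                             seed=sim_seed)
        markers = sample_markers(res.start, observed.markers, marker_seed)
        stats = compare_genomes(res.start, res.end, markers=markers)
        ss[i], ps[i], nts[i] = stats.s, stats.p, res.log.n_t
    sigma_s = float(np.std(ss, ddof=1))
    sigma_p = float(np.std(ps, ddof=1))
    if sigma_s < sigma_floor or sigma_p < sigma_floor:
        logger.info("sigma floored at %g (sigma_s=%g, sigma_p=%g)",
                    sigma_floor, sigma_s, sigma_p)
    sig_s = max(sigma_s, sigma_floor)
    sig_p = max(sigma_p, sigma_floor)
    chi2 = (((ss.mean() - observed.s) / sig_s) ** 2
            + ((ps.mean() - observed.p) / sig_p) ** 2)
    return ChiSquare(float(chi2), float(ss.mean()), float(ps.mean()),
                     sigma_s, sigma_p, float(nts.mean()), replicates)


def _quadratic_surface(x: np.ndarray, y: np.ndarray, z: np.ndarray):
    """Least-squares fit of z ~ a + bx + cy + dx^2 + ey^2 + fxy.

    Returns (coeffs, stationary (x*, y*) or None if the Hessian is not
    positive definite).
    """
    design = np.column_stack([np.ones_like(x), x, y, x * x, y * y, x * y])
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    _, b, c, d, e, f = coef
    hess = np.array([[2 * d, f], [f, 2 * e]])
    if hess[0, 0] <= 0 or np.linalg.det(hess) <= 0:
        return coef, None
    sol = np.linalg.solve(hess, -np.array([b, c]))
    return coef, (float(sol[0]), float(sol[1]))


@dataclass
class SyntenyFitResult:
    """Fitted (n, parameter) for one model and one observed pair."""

    model: str
    observed: ObservedPair
    n_hat: float
    param_hat: float
    chi2: float
    sigma_s: float
    sigma_p: float
    n_t_hat: float
    grid: pd.DataFrame
    phase1: tuple[float, float]
    surface_ok: bool
    n_evaluations: int
    extra: dict = field(default_factory=dict)

    @property
    def params(self) -> dict:
        return {"n": self.n_hat, self.model_param_name: self.param_hat}

    @property
    def model_param_name(self) -> str:
        return {"ds": "mu", "maxT": "t_max", "maxL": "l_max",
                "pfix": "p_fix"}[self.model]

    def summary(self) -> str:
        lines = [
            f"Synteny divergence fit: {self.model} vs {self.observed.name}",
            f"  observed: p={self.observed.p:.4g}  s={self.observed.s:.4g}  "
            f"markers={self.observed.markers}",
            f"  n_hat         {self.n_hat:.1f}",
            f"  {self.model_param_name + '_hat':<13s} {self.param_hat:.6g}",
            f"  chi2          {self.chi2:.4g}",
            f"  sigma_s       {self.sigma_s:.4g}",
            f"  sigma_p       {self.sigma_p:.4g}",
            f"  n_t_hat       {self.n_t_hat:.1f}",
            f"  surface       {'quadratic stationary point' if self.surface_ok else 'grid argmin (fallback)'}",
            f"  evaluations   {self.n_evaluations}",
        ]
        return "\n".join(lines)


class SyntenyDivergenceModel:
    """Estimate (n, parameter) of a constrained rearrangement model.

    Parameters
    ----------
    observed:
        Target (p, s, marker count).
    model:
        One of ``ds``, ``maxT``, ``maxL``, ``pfix``.
    c, n_genes:
        Simulated genome shape.
    replicates:
        Simulation runs per chi-square evaluation.

    The chi-square objective uses common random numbers: replicate seeds
    are fixed for the whole fit (derived from the ``fit`` seed only), so
    the objective is a deterministic, relatively smooth function of
    (n, parameter) and Brent's method behaves.
    """

    def __init__(
        self,
        observed: ObservedPair,
        model: str = "ds",
        c: int = 20,
        n_genes: int = 20000,
        replicates: int = 10,
        sigma_floor: float = 1e-4,
        n_bounds: tuple[float, float] = _N_BOUNDS,
        param_bounds: tuple[float, float] | None = None,
        max_sweeps: int = 10,
        rel_tol: float = 0.01,
    ) -> None:
        if model not in _PARAM_BOUNDS:
            raise ValueError(f"unknown model {model!r}")
        self.observed = observed
        self.model = model
        self.c = c
        self.n_genes = n_genes
        self.replicates = replicates
        self.sigma_floor = sigma_floor
        self.n_bounds = n_bounds
        self.param_bounds = param_bounds or _PARAM_BOUNDS[model]
        self.max_sweeps = max_sweeps
        self.rel_tol = rel_tol

    # parameter <-> optimizer coordinate (pfix optimized in log10 space)
    def _to_native(self, x: float) -> float:
        return 10.0 ** x if self.model == "pfix" else x

    def _config(self, param: float) -> ModelConfig:
        native = self._to_native(param)
        factory = {"ds": ModelConfig.ds, "maxT": ModelConfig.max_t,
                   "maxL": ModelConfig.max_l, "pfix": ModelConfig.pfix}
        return factory[self.model](native)

    def fit(self, seed: int = 0, start: tuple[float, float] | None = None
            ) -> SyntenyFitResult:
        cache: dict[tuple[int, float], ChiSquare] = {}

        def evaluate(n: float, param: float) -> ChiSquare:
            key = (int(round(n)), round(float(param), 10))
            if key not in cache:
                cache[key] = chi_square(
                    self._config(param), key[0], self.observed,
                    replicates=self.replicates, seed=seed,
                    c=self.c, n_genes=self.n_genes,
                    sigma_floor=self.sigma_floor)
            return cache[key]

        lo_n, hi_n = self.n_bounds
        lo_p, hi_p = self.param_bounds
        if start is None:
            n_cur = math.sqrt(lo_n * hi_n)
            p_cur = 0.5 * (lo_p + hi_p)
        else:
            n_cur, p_cur = start
            if self.model == "pfix":
                p_cur = math.log10(p_cur)

        # phase 1: alternating Brent, n first
        for _ in range(self.max_sweeps):
            prev = (n_cur, p_cur)
            res_n = minimize_scalar(
                lambda n: evaluate(n, p_cur).chi2,
                bounds=(lo_n, hi_n), method="bounded",
                options={"xatol": max(self.rel_tol * n_cur, 1.0),
                         "maxiter": 30})
            n_cur = float(res_n.x)
            res_p = minimize_scalar(
                lambda p: evaluate(n_cur, p).chi2,
                bounds=(lo_p, hi_p), method="bounded",
                options={"xatol": self.rel_tol * max(abs(p_cur), 1e-3),
                         "maxiter": 30})
            p_cur = float(res_p.x)
            dn = abs(n_cur - prev[0]) / max(abs(prev[0]), 1.0)
            dp = abs(p_cur - prev[1]) / max(abs(prev[1]), 1e-9)
            if dn < self.rel_tol and dp < self.rel_tol:
                break
        phase1 = (n_cur, self._to_native(p_cur))

        # phase 2: 7x7 grid spanning +/-15% of the phase-one optimum
        n_axis = np.linspace(0.85 * n_cur, 1.15 * n_cur, 7)
        if self.model == "pfix":
            p_native = self._to_native(p_cur)
            p_axis_native = np.linspace(0.85 * p_native, 1.15 * p_native, 7)
            p_axis = np.log10(p_axis_native)
        else:
            p_axis = np.linspace(0.85 * p_cur, 1.15 * p_cur, 7)
            p_axis = np.clip(p_axis, lo_p, hi_p)
            p_axis_native = np.array([self._to_native(p) for p in p_axis])
        rows = []
        for ni in n_axis:
            for pj, pj_native in zip(p_axis, p_axis_native):
                ev = evaluate(ni, pj)
                rows.append({"n": int(round(ni)), "param": pj_native,
                             "chi2": ev.chi2, "mean_s": ev.mean_s,
                             "mean_p": ev.mean_p, "sigma_s": ev.sigma_s,
                             "sigma_p": ev.sigma_p, "n_t": ev.mean_n_t})
        grid = pd.DataFrame(rows)

        # quadratic surface in normalized coordinates
        x = (grid["n"].to_numpy() - n_cur) / n_cur
        pn_center = self._to_native(p_cur)
        y = (grid["param"].to_numpy() - pn_center) / max(abs(pn_center), 1e-12)
        _, stationary = _quadratic_surface(x, y, grid["chi2"].to_numpy())
        in_box = (stationary is not None
                  and abs(stationary[0]) <= 0.15 and abs(stationary[1]) <= 0.15)
        if stationary is not None and in_box:
            n_hat = n_cur * (1 + stationary[0])
            param_hat = pn_center * (1 + stationary[1])
            surface_ok = True
        else:
            if stationary is None:
                logger.warning("quadratic surface not positive definite; "
                               "falling back to grid argmin")
            else:
                logger.warning("quadratic stationary point outside grid; "
                               "falling back to grid argmin")
            best = grid.loc[grid["chi2"].idxmin()]
            n_hat, param_hat = float(best["n"]), float(best["param"])
            surface_ok = False

        opt_param = (math.log10(param_hat) if self.model == "pfix"
                     else param_hat)
        final = evaluate(n_hat, opt_param)
        return SyntenyFitResult(
            model=self.model, observed=self.observed,
            n_hat=float(n_hat), param_hat=float(param_hat),
            chi2=final.chi2, sigma_s=final.sigma_s, sigma_p=final.sigma_p,
            n_t_hat=final.mean_n_t, grid=grid, phase1=phase1,
            surface_ok=surface_ok, n_evaluations=len(cache))


def fit_parameters(
    model: str,
    observed: ObservedPair,
    seed: int = 0,
    **kwargs,
) -> SyntenyFitResult:
    """Functional wrapper around :class:`SyntenyDivergenceModel`."""
    start = kwargs.pop("start", None)
    return SyntenyDivergenceModel(observed, model=model, **kwargs).fit(
        seed=seed, start=start)
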