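"""Parameter estimation: sum-of-squares loss and hybrid genetic algorithm.

The estimator follows the classic hybrid scheme: a real-coded genetic
algorithm explores the box ``[0, 2]^n`` — fitness evaluation, rank-based
expectation scaling, stochastic-uniform (line-walk) parent selection, elite
carry-over, scattered crossover and Gaussian mutation — and a gradient-based
constrained local search (L-BFGS-B on numerical gradients) polishes the best
individual found.

Because every observed variable is max-scaled into [0, 1], the default loss
is the unweighted sum of squared differences between simulated and observed
values over mice, variables and time points; a weight matrix can be supplied
for robustness studies. Initial conditions are the observed week-6 states.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .dataset import ObservedDataset
from .model import IntegrationError, simulate
from .params import PARAM_NAMES, HypoxiaParams, ParameterSet

__all__ = ["GAConfig", "FitResult", "loss", "ga_minimize", "local_refine", "fit_hga"]

logger = logging.getLogger(__name__)

#: Finite penalty returned when the ODE solver fails at a candidate.
PENALTY_LOSS = 1e6


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the genetic algorithm stage.

    The mutation scale is the initial standard deviation of the Gaussian
    mutation relative to the box width; it shrinks geometrically to one tenth
    of its initial value over the run.
    """

    population_size: int = 200
    max_generations: int = 500
    elite_frac: float = 0.05
    crossover_frac: float = 0.8
    mutation_scale: float = 0.1
    mutation_shrink: float = 10.0
    stall_generations: int = 50
    fun_tol: float = 1e-8
    lower: float = 0.0
    upper: float = 2.0
    seed: int | None = None

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        for name in ("elite_frac", "crossover_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.upper <= self.lower:
            raise ValueError("upper bound must exceed lower bound")


@dataclass
class FitResult:
    """Outcome of an estimation run."""

    params: ParameterSet | None
    x: np.ndarray
    fun: float
    ga_fun: float
    history: np.ndarray  # per-generation best loss (non-increasing with elitism)
    refinement_delta: float
    n_evaluations: int
    seed: int | None
    config: GAConfig
    free_names: tuple[str, ...] | None = None

    def summary_lines(self) -> list[str]:
        lines = [
            f"final loss          {self.fun:.6g}",
            f"GA-stage loss       {self.ga_fun:.6g}",
            f"refinement delta    {self.refinement_delta:.6g}",
            f"generations run     {len(self.history)}",
            f"loss evaluations    {self.n_evaluations}",
            f"seed                {self.seed}",
        ]
        return lines


def loss(
    params: ParameterSet | Mapping[str, float],
    data: ObservedDataset,
    hyp: HypoxiaParams,
    *,
    x0_policy: str = "observed",
    weights: Mapping | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> float:
    """Sum of squared simulated-minus-observed differences.

    For each mouse the model is integrated from the observed initial state
    (``x0_policy='observed'``) across the observation grid and compared
    entry-wise to the data. Integration failures contribute a large finite
    penalty rather than an exception so population-based search can continue.
    """
    if x0_policy != "observed":
        raise ValueError("only the 'observed' initial-condition policy is built in")
    total = 0.0
    for mouse, obs in data.values.items():
        try:
            traj = simulate(
                params, hyp, obs[0], data.times, rtol=rtol, atol=atol
            )
        except (IntegrationError, ValueError) as exc:
            logger.warning("integration failed for mouse %s: %s", mouse, exc)
            return PENALTY_LOSS
        resid = traj.states - obs
        if weights is not None and mouse in weights:
            resid = resid * np.asarray(weights[mouse])
        total += float(np.sum(resid * resid))
    return total


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

def _rank_expectations(fitness: np.ndarray) -> np.ndarray:
    """Rank-based expectation scaling: expectation ~ 1/sqrt(rank)."""
    order = np.argsort(fitness)  # ascending loss = best first
    n = fitness.size
    expect = np.empty(n)
    expect[order] = 1.0 / np.sqrt(np.arange(1, n + 1))
    return expect * (n / expect.sum())


def _stochastic_uniform(expect: np.ndarray, n_picks: int, rng) -> np.ndarray:
    """Line-walk selection: one uniform step per pick along the expectation line."""
    cum = np.cumsum(expect)
    total = cum[-1]
    step = total / n_picks
    start = rng.uniform(0.0, step)
    points = start + step * np.arange(n_picks)
    idx = np.searchsorted(cum, points, side="left")
    rng.shuffle(idx)
    return idx


def ga_minimize(
    loss_fn: Callable[[np.ndarray], float],
    n_dim: int,
    config: GAConfig,
) -> FitResult:
    """Genetic-algorithm minimisation over the configured box.

    Deterministic given ``config.seed``. Returns a :class:`FitResult` whose
    ``history`` is the per-generation best loss; with at least one elite the
    sequence is non-increasing.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.lower, config.upper
    pop = rng.uniform(lo, hi, size=(config.population_size, n_dim))
    fitness = np.array([loss_fn(x) for x in pop])
    n_evals = pop.shape[0]

    n_elite = max(1, int(round(config.elite_frac * config.population_size)))
    n_elite = min(n_elite, config.population_size - 1)
    n_children = config.population_size - n_elite
    n_xover = int(round(config.crossover_frac * n_children))

    history = []
    best_prev = np.inf
    stall = 0
    for gen in range(config.max_generations):
        best_idx = int(np.argmin(fitness))
        best = float(fitness[best_idx])
        history.append(best)
        if best_prev - best < config.fun_tol:
            stall += 1
        else:
            stall = 0
        best_prev = min(best_prev, best)
        if stall >= config.stall_generations:
            break
        if gen == config.max_generations - 1:
            break

        expect = _rank_expectations(fitness)
        # mutation sigma shrinks geometrically over the run
        frac = gen / max(1, config.max_generations - 1)
        sigma = (
            config.mutation_scale
            * (hi - lo)
            * config.mutation_shrink ** (-frac)
        )

        elite_idx = np.argsort(fitness)[:n_elite]
        elites = pop[elite_idx]

        parents = pop[_stochastic_uniform(expect, 2 * n_children, rng)]
        children = np.empty((n_children, n_dim))
        for i in range(n_children):
            p1, p2 = parents[2 * i], parents[2 * i + 1]
            if i < n_xover:
                mask = rng.random(n_dim) < 0.5  # scattered crossover
                children[i] = np.where(mask, p1, p2)
            else:
                children[i] = p1 + rng.normal(0.0, sigma, n_dim)
        np.clip(children, lo, hi, out=children)

        pop = np.vstack([elites, children])
        child_fit = np.array([loss_fn(x) for x in children])
        n_evals += n_children
        fitness = np.concatenate([fitness[elite_idx], child_fit])

    best_idx = int(np.argmin(fitness))
    return FitResult(
        params=None,
        x=pop[best_idx].copy(),
        fun=float(fitness[best_idx]),
        ga_fun=float(fitness[best_idx]),
        history=np.array(history),
        refinement_delta=0.0,
        n_evaluations=n_evals,
        seed=config.seed,
        config=config,
    )


def local_refine(
    start: np.ndarray,
    loss_fn: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    *,
    maxiter: int = 500,
    ftol: float = 1e-12,
) -> tuple[np.ndarray, float, int]:
    """Gradient-based constrained polish (L-BFGS-B, numerical gradients).

    Never returns a point worse than the start: on line-search failure or any
    uphill outcome the start is returned unchanged with a warning.
    """
    start = np.asarray(start, dtype=float)
    f0 = loss_fn(start)
    try:
        res = minimize(
            loss_fn, start, method="L-BFGS-B", bounds=list(bounds),
            options={"maxiter": maxiter, "ftol": ftol},
        )
        n_evals = int(res.nfev)
    except Exception as exc:  # pragma: no cover - defensive
        warnings.warn(f"local refinement failed: {exc}; keeping start point")
        return start, f0, 0
    if not np.isfinite(res.fun) or res.fun > f0:
        warnings.warn("local refinement did not improve the loss; keeping start")
        return start, f0, n_evals
    x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    return x, float(loss_fn(x)), n_evals + 1


def fit_hga(
    data: ObservedDataset,
    config: GAConfig | None = None,
    *,
    hyp: HypoxiaParams | None = None,
    free_names: Sequence[str] | None = None,
    fixed: Mapping[str, float] | None = None,
    weights: Mapping | None = None,
    loss_rtol: float = 1e-6,
) -> FitResult:
    """Hybrid fit: GA global search followed by local refinement.

    ``free_names`` restricts the search to a subset of the registry (the
    remaining parameters are held at ``fixed``, default 0); by default all
    estimated parameters are free. Fully reproducible from ``config.seed``.
    """
    config = config or GAConfig()
    hyp = hyp or HypoxiaParams()
    names = tuple(free_names) if free_names is not None else PARAM_NAMES
    unknown = set(names) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    base = dict.fromkeys(PARAM_NAMES, 0.0)
    if fixed:
        base.update(fixed)

    def vec_loss(x: np.ndarray) -> float:
        d = dict(base)
        d.update(zip(names, x))
        return loss(d, data, hyp, weights=weights, rtol=loss_rtol)

    ga = ga_minimize(vec_loss, len(names), config)
    bounds = [(config.lower, config.upper)] * len(names)
    x_ref, f_ref, n_ref = local_refine(ga.x, vec_loss, bounds)

    d = dict(base)
    d.update(zip(names, x_ref))
    return replace(
        ga,
        params=ParameterSet(d),
        x=x_ref,
        fun=f_ref,
        refinement_delta=ga.fun - f_ref,
        n_evaluations=ga.n_evaluations + n_ref,
        free_names=names,
    )
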