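"""Practical identifiability by profile likelihood.

For each parameter the profile loss ``PL(theta_i)`` is obtained by fixing
``theta_i`` on a scan grid over ``[0, 2 * theta_hat_i]`` and re-minimising the
loss over all remaining parameters, warm-starting each grid point from its
neighbour. A parameter is *identifiable* when the profile crosses the
threshold ``L(theta_hat) + delta_alpha`` on both sides of the estimate, where
``delta_alpha`` is the alpha-quantile of the chi-square distribution with one
degree of freedom (pointwise confidence intervals). Profiles that fail to
cross on at least one side are *practically non-identifiable*; essentially
constant profiles are additionally labelled *flat*, hinting at local
structural problems.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .dataset import ObservedDataset
from .estimation import FitResult, local_refine
from .model import simulate
from .params import PARAM_NAMES, HypoxiaParams, ParameterSet

__all__ = [
    "ProfileCurve",
    "perturbed_synthetic",
    "profile_loss",
    "profile_likelihood",
    "classify",
    "IDENTIFIABLE",
    "NON_IDENTIFIABLE",
    "FLAT",
]

IDENTIFIABLE = "identifiable"
NON_IDENTIFIABLE = "practically_non_identifiable"
FLAT = "flat"


@dataclass
class ProfileCurve:
    """Loss profile of one parameter over its scan grid."""

    name: str
    grid: np.ndarray
    values: np.ndarray          # PL(theta_i) per grid point
    theta_hat: float
    loss_hat: float
    ok: np.ndarray | None = None  # per-point re-optimisation success flags

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have matching shapes")
        if self.ok is None:
            self.ok = np.ones_like(self.grid, dtype=bool)

    def label(self, alpha: float = 0.95, flat_tol: float = 0.1) -> str:
        return classify(self, alpha=alpha, flat_tol=flat_tol)


def perturbed_synthetic(
    fit: FitResult | ParameterSet,
    hyp: HypoxiaParams,
    x0: np.ndarray,
    times: Sequence[float],
    level: float = 0.05,
    seed: int | None = None,
    mouse: int | str = 1,
) -> ObservedDataset:
    """Noisy synthetic observations from a fitted trajectory.

    Simulates at the fitted parameters, samples the observation times and
    applies independent multiplicative noise uniform in ``[1-level, 1+level]``
    per entry (level 0 returns the exact simulated values).
    """
    if level < 0:
        raise ValueError("noise level must be non-negative")
    params = fit.params if isinstance(fit, FitResult) else fit
    traj = simulate(params, hyp, x0, np.asarray(times, dtype=float))
    rng = np.random.default_rng(seed)
    factors = rng.uniform(1.0 - level, 1.0 + level, size=traj.states.shape)
    values = traj.states * factors if level > 0 else traj.states.copy()
    return ObservedDataset(traj.times, {mouse: values})


def profile_loss(
    loss_fn: Callable[[np.ndarray], float],
    theta_hat: np.ndarray,
    index: int,
    *,
    grid: np.ndarray | None = None,
    grid_size: int = 21,
    bounds: Sequence[tuple[float, float]] | None = None,
    reoptimize: bool = True,
    name: str | None = None,
) -> ProfileCurve:
    """Generic profile of ``loss_fn`` in coordinate ``index`` around ``theta_hat``.

    The scan grid defaults to ``grid_size`` points on ``[0, 2*theta_hat_i]``
    (or ``[0, 2*upper-bound-fraction]`` if the estimate is 0). With
    ``reoptimize`` the remaining coordinates are re-fitted at every grid point,
    warm-started from the previous point; a failed re-optimisation flags the
    point and the curve continues.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    n = theta_hat.size
    if not 0 <= index < n:
        raise ValueError("parameter index out of range")
    if bounds is None:
        bounds = [(0.0, 2.0)] * n
    hi_i = bounds[index][1]
    top = 2.0 * theta_hat[index] if theta_hat[index] > 0 else 0.1 * hi_i
    if grid is None:
        grid = np.linspace(0.0, top, grid_size)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3:
        raise ValueError("scan grid must have at least 3 points")

    loss_hat = loss_fn(theta_hat)
    nuisance = [b for j, b in enumerate(bounds) if j != index]
    other_idx = [j for j in range(n) if j != index]

    def fixed_loss(theta_i: float, others: np.ndarray) -> float:
        full = np.empty(n)
        full[index] = theta_i
        full[other_idx] = others
        return loss_fn(full)

    values = np.empty(grid.size)
    ok = np.ones(grid.size, dtype=bool)
    # scan outward from the grid point nearest the estimate so warm starts
    # stay in the right basin on both sides
    order = np.argsort(np.abs(grid - theta_hat[index]))
    start_others = {int(order[0]): theta_hat[other_idx].copy()}
    for k in order:
        k = int(k)
        warm = start_others.get(k, theta_hat[other_idx].copy())
        if reoptimize and len(other_idx) > 0:
            try:
                x, f, _ = local_refine(
                    warm, lambda o: fixed_loss(grid[k], o), nuisance
                )
            except Exception:
                x, f = warm, fixed_loss(grid[k], warm)
                ok[k] = False
        else:
            x, f = warm, fixed_loss(grid[k], warm)
        values[k] = f
        # propagate the warm start outward
        for nb in (k - 1, k + 1):
            if 0 <= nb < grid.size and nb not in start_others:
                start_others[nb] = x.copy()

    return ProfileCurve(
        name=name or f"theta[{index}]",
        grid=grid,
        values=values,
        theta_hat=float(theta_hat[index]),
        loss_hat=float(loss_hat),
        ok=ok,
    )


def profile_likelihood(
    param_name: str,
    fit: FitResult,
    data: ObservedDataset,
    grid_size: int = 21,
    *,
    hyp: HypoxiaParams | None = None,
    reoptimize: bool = True,
    loss_rtol: float = 1e-6,
) -> ProfileCurve:
    """Profile the model loss in one named parameter around a fit.

    Only the parameters that were free in ``fit`` are re-optimised as
    nuisances; everything else stays at its fitted value.
    """
    from .estimation import loss as model_loss

    hyp = hyp or HypoxiaParams()
    free = fit.free_names or PARAM_NAMES
    if param_name not in free:
        raise ValueError(f"{param_name!r} was not free in this fit")
    base = fit.params.to_dict()
    idx = free.index(param_name)

    def vec_loss(x: np.ndarray) -> float:
        d = dict(base)
        d.update(zip(free, x))
        return model_loss(d, data, hyp, rtol=loss_rtol)

    theta_hat = np.array([fit.params[nm] for nm in free])
    cfg = fit.config
    bounds = [(cfg.lower, cfg.upper)] * len(free)
    return profile_loss(
        vec_loss, theta_hat, idx,
        grid_size=grid_size, bounds=bounds, reoptimize=reoptimize,
        name=param_name,
    )


def classify(
    curve: ProfileCurve, alpha: float = 0.95, flat_tol: float = 0.1
) -> str:
    """Label a profile curve.

    ``identifiable`` iff the profile exceeds ``L(theta_hat) + delta_alpha`` on
    both sides of the estimate within the scan grid; otherwise practically
    non-identifiable, and additionally ``flat`` when the whole profile varies
    by less than ``flat_tol * delta_alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if curve.grid.size < 3 or np.allclose(curve.grid, curve.grid[0]):
        raise ValueError("degenerate scan grid")
    delta = float(chi2.ppf(alpha, df=1))
    threshold = curve.loss_hat + delta
    left = curve.grid < curve.theta_hat
    right = curve.grid > curve.theta_hat
    crosses_left = bool(np.any(curve.values[left] > threshold))
    crosses_right = bool(np.any(curve.values[right] > threshold))
    if crosses_left and crosses_right:
        return IDENTIFIABLE
    # flat is the degenerate sub-case of practical non-identifiability
    if np.max(curve.values) - np.min(curve.values) < flat_tol * delta:
        return FLAT
    return NON_IDENTIFIABLE
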