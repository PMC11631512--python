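"""Principal-component global sensitivity analysis (SVD of the trajectory Jacobian).

The map from parameter perturbations ``dk`` to trajectory changes ``dX`` is
linearised by stacking, on a fine time grid, the partial derivatives of every
output variable with respect to every parameter into a matrix
``M = dX/dk`` of shape ``(n_times * n_outputs, n_params)``. A thin singular
value decomposition ``M = U S V^T`` then yields:

* principal components ``U_i`` — time/variable patterns of system response;
* the singular spectrum ``sigma_1 >= sigma_2 >= ...`` — how many patterns
  matter;
* principal sensitivity values ``S_ij = sigma_i * V_ji`` — how strongly
  parameter ``j`` drives pattern ``i``, so that
  ``dX = sum_ij S_ij dk_j U_i + o(|dk|)``.

Scalar outputs (cancer burden, total immune cells, total cells) have a single
dominant singular value, so their first-PC sensitivities coincide with the
classical signed sensitivity ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import (
    CELL_VARS,
    IMMUNE_VARS,
    STATE_VARS,
    Trajectory,
    observables,
    simulate,
)
from .params import EXTENDED_NAMES, HYPOXIA_NAMES, HypoxiaParams, ParameterSet

__all__ = [
    "SensitivityMatrix",
    "Decomposition",
    "sensitivity_matrix",
    "pc_decompose",
    "singular_spectrum",
    "variable_heatmap",
    "scalar_sensitivity",
    "perturbation_experiment",
]

SCALAR_OUTPUTS = ("cancer", "total_immune", "total_cells")


@dataclass
class SensitivityMatrix:
    """Stacked finite-difference Jacobian of outputs w.r.t. parameters.

    Row blocks are ordered output-variable-major, time-minor: rows
    ``[i*n_t : (i+1)*n_t]`` hold output ``outputs[i]`` on ``t_grid``.
    """

    matrix: np.ndarray
    t_grid: np.ndarray
    outputs: tuple[str, ...]
    param_names: tuple[str, ...]
    scaling: str = "raw"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n_rows = len(self.outputs) * self.t_grid.size
        if self.matrix.shape != (n_rows, len(self.param_names)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.outputs)} outputs x {self.t_grid.size} times x "
                f"{len(self.param_names)} parameters"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("sensitivity matrix contains non-finite entries")


@dataclass
class Decomposition:
    """Thin SVD of a sensitivity matrix with principal sensitivity values."""

    U: np.ndarray
    sigma: np.ndarray
    V: np.ndarray              # columns: parameter-space basis vectors
    S: np.ndarray              # S[i, j] = sigma_i * V[j, i]
    source: SensitivityMatrix

    @property
    def n_components(self) -> int:
        return self.sigma.size


def _full_vector(params: ParameterSet, hyp: HypoxiaParams) -> np.ndarray:
    return np.concatenate([params.to_array(),
                           [hyp.ox_crit1, hyp.ox_crit2, hyp.m]])


def _split_vector(vec: np.ndarray) -> tuple[ParameterSet, HypoxiaParams]:
    n = len(EXTENDED_NAMES) - len(HYPOXIA_NAMES)
    pset = ParameterSet.from_array(vec[:n])
    hyp = HypoxiaParams(ox_crit1=vec[n], ox_crit2=vec[n + 1], m=vec[n + 2])
    return pset, hyp


def _output_series(traj: Trajectory, outputs: Sequence[str]) -> np.ndarray:
    """(n_outputs, n_times) array of requested state or derived series."""
    obs = None
    rows = []
    for out in outputs:
        if out in STATE_VARS:
            rows.append(traj[out])
        elif out in SCALAR_OUTPUTS:
            obs = obs or observables(traj)
            rows.append(obs[out])
        else:
            raise ValueError(f"unknown output {out!r}")
    return np.asarray(rows)


def sensitivity_matrix(
    params: ParameterSet,
    hyp: HypoxiaParams,
    x0: np.ndarray,
    t_grid: Sequence[float],
    outputs: Sequence[str] | None = None,
    *,
    fd_rel_step: float = 1e-4,
    fd_floor: float = 1e-6,
    scaling: str = "raw",
    param_names: Sequence[str] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SensitivityMatrix:
    """Central finite-difference Jacobian of the outputs on ``t_grid``.

    Each parameter ``k_j`` is perturbed by ``h_j = fd_rel_step *
    max(k_j, fd_floor)`` in both directions. ``scaling='scaled'`` multiplies
    column ``j`` by ``k_j`` (per-log sensitivity, i.e. response to a relative
    parameter change). If an integration fails at a perturbed point the step
    is halved once before the column is re-attempted.
    """
    if scaling not in ("raw", "scaled"):
        raise ValueError("scaling must be 'raw' or 'scaled'")
    t_grid = np.asarray(t_grid, dtype=float)
    outputs = tuple(outputs) if outputs is not None else STATE_VARS
    names = tuple(param_names) if param_names is not None else EXTENDED_NAMES
    unknown = set(names) - set(EXTENDED_NAMES)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")

    vec0 = _full_vector(params, hyp)
    idx = [EXTENDED_NAMES.index(nm) for nm in names]

    def run(vec: np.ndarray) -> np.ndarray:
        pset, h = _split_vector(vec)
        traj = simulate(pset, h, x0, t_grid, rtol=rtol, atol=atol)
        return _output_series(traj, outputs).ravel()  # output-major

    n_rows = len(outputs) * t_grid.size
    M = np.empty((n_rows, len(names)))
    for col, j in enumerate(idx):
        k = vec0[j]
        h = fd_rel_step * max(abs(k), fd_floor)
        for attempt in range(2):
            try:
                vp, vm = vec0.copy(), vec0.copy()
                vp[j] = k + h
                vm[j] = max(k - h, 0.0)
                dv = vp[j] - vm[j]
                M[:, col] = (run(vp) - run(vm)) / dv
                break
            except Exception as exc:
                if attempt == 0:
                    warnings.warn(
                        f"perturbed integration failed for {names[col]}; "
                        f"halving step ({exc})"
                    )
                    h /= 2.0
                else:
                    raise
        if scaling == "scaled":
            M[:, col] *= k
    return SensitivityMatrix(M, t_grid, outputs, names, scaling=scaling)


def pc_decompose(M: SensitivityMatrix) -> Decomposition:
    """Thin SVD with principal sensitivity values ``S_ij = sigma_i V_ji``."""
    U, sigma, Vt = np.linalg.svd(M.matrix, full_matrices=False)
    V = Vt.T
    S = sigma[:, None] * Vt  # S[i, j] = sigma_i * V[j, i]
    return Decomposition(U=U, sigma=sigma, V=V, S=S, source=M)


def singular_spectrum(dec: Decomposition, cutoff: float = 0.2) -> int:
    """Number of PCs whose singular value is at least ``cutoff * sigma_1``."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    sigma = dec.sigma
    if sigma.size == 0 or sigma[0] <= 0:
        raise ValueError("degenerate (all-zero) singular spectrum")
    ratios = sigma / sigma[0]
    return int(np.max(np.nonzero(ratios >= cutoff)[0]) + 1)


def variable_heatmap(
    dec: Decomposition,
    threshold: float = 0.2,
    n_components: int | None = None,
) -> list[list[dict]]:
    """Per-PC entries ``(variable, time, magnitude)`` above the threshold.

    Magnitudes are the ``sigma_i``-scaled PC loadings ``|sigma_i U_i|`` per
    output variable and time; the threshold is relative to the global maximum
    across the retained PCs. Entries are sorted by decreasing magnitude.
    """
    src = dec.source
    n_t = src.t_grid.size
    n_pc = n_components or singular_spectrum(dec)
    n_pc = min(n_pc, dec.n_components)
    loadings = np.abs(dec.sigma[:n_pc, None] * dec.U[:, :n_pc].T)  # (pc, rows)
    global_max = float(loadings.max())
    result = []
    for i in range(n_pc):
        entries = []
        for row in np.nonzero(loadings[i] >= threshold * global_max)[0]:
            var = src.outputs[row // n_t]
            t = float(src.t_grid[row % n_t])
            entries.append(
                {"variable": var, "time": t, "magnitude": float(loadings[i, row])}
            )
        entries.sort(key=lambda e: -e["magnitude"])
        result.append(entries)
    return result


def scalar_sensitivity(
    output: str,
    params: ParameterSet,
    hyp: HypoxiaParams,
    x0: np.ndarray,
    t_grid: Sequence[float],
    *,
    scaling: str = "scaled",
    top: int = 10,
    **fd_kwargs,
) -> dict:
    """Signed first-PC sensitivity ranking of one scalar output.

    The sign convention orients the first PC so that its time-average is
    positive; a positive ``S_1j`` then means increasing parameter ``j``
    raises the output overall. Parameters with exactly zero sensitivity are
    excluded from the top list.
    """
    if output not in SCALAR_OUTPUTS:
        raise ValueError(f"output must be one of {SCALAR_OUTPUTS}")
    M = sensitivity_matrix(
        params, hyp, x0, t_grid, outputs=(output,), scaling=scaling, **fd_kwargs
    )
    dec = pc_decompose(M)
    u1 = dec.U[:, 0]
    sign = 1.0 if u1.sum() >= 0 else -1.0
    s1 = sign * dec.S[0]
    order = np.argsort(-np.abs(s1))
    ranked = [
        (M.param_names[j], float(s1[j])) for j in order if s1[j] != 0.0
    ]
    return {
        "output": output,
        "sensitivities": dict(zip(M.param_names, map(float, s1))),
        "top": ranked[:top],
        "decomposition": dec,
    }


def perturbation_experiment(
    param_name: str,
    deltas: Sequence[float],
    params: ParameterSet,
    hyp: HypoxiaParams,
    x0: np.ndarray,
    t_grid: Sequence[float],
    *,
    lower: float = 0.0,
    upper: float = 2.0,
) -> dict:
    """Re-simulate under fractional perturbations of one parameter.

    Returns the cancer and total-immune series for every perturbed value plus
    the pointwise min/max envelope. Perturbed values leaving ``[lower,
    upper]`` are clipped with a warning.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    vec0 = _full_vector(params, hyp)
    j = EXTENDED_NAMES.index(param_name)
    base = vec0[j]

    runs = {}
    for d in deltas:
        val = base * (1.0 + d)
        if not lower <= val <= upper:
            warnings.warn(
                f"{param_name} perturbed to {val:.4g} leaves "
                f"[{lower}, {upper}]; clipping"
            )
            val = min(max(val, lower), upper)
        vec = vec0.copy()
        vec[j] = val
        pset, h = _split_vector(vec)
        traj = simulate(pset, h, x0, t_grid)
        obs = observables(traj)
        runs[float(d)] = {
            "cancer": obs["cancer"],
            "total_immune": obs["total_immune"],
        }

    envelope = {}
    for key in ("cancer", "total_immune"):
        stack = np.vstack([r[key] for r in runs.values()])
        envelope[key] = {"min": stack.min(axis=0), "max": stack.max(axis=0)}
    return {
        "param": param_name,
        "t_grid": t_grid,
        "runs": runs,
        "envelope": envelope,
    }
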