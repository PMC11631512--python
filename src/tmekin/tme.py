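"""High-level modelling interface: ``TMEModel`` and ``TMEResults``.

Typical use::

    from tmekin import TMEModel, datasets

    data = datasets.load_dataset().select_mice([2])
    model = TMEModel(data)
    res = model.fit(seed=0)
    print(res.summary())
    traj = res.simulate(t_end=150)
    curve = res.profile("lambda_A")
    dec = res.sensitivity()

The model object holds the observations, hypoxia-switch settings and the
free-parameter structure; fitting runs the hybrid genetic algorithm and
returns a results object from which simulation, profile-likelihood
identifiability, sensitivity decomposition and perturbation experiments are
launched.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import ObservedDataset
from .estimation import FitResult, GAConfig, fit_hga, loss as sse_loss
from .identifiability import ProfileCurve, classify, profile_likelihood
from .model import Trajectory, simulate
from .params import PARAM_NAMES, HypoxiaParams, ParameterSet
from .sensitivity import (
    Decomposition,
    pc_decompose,
    perturbation_experiment,
    scalar_sensitivity,
    sensitivity_matrix,
)

__all__ = ["TMEModel", "TMEResults"]


class TMEModel:
    """The 18-variable tumour-microenvironment model bound to observations."""

    def __init__(
        self,
        data: ObservedDataset,
        hypoxia: HypoxiaParams | None = None,
        *,
        free_names: Sequence[str] | None = None,
        fixed: Mapping[str, float] | None = None,
        weights: Mapping | None = None,
    ):
        self.data = data
        self.hypoxia = hypoxia or HypoxiaParams()
        self.free_names = (
            tuple(free_names) if free_names is not None else PARAM_NAMES
        )
        self.fixed = dict(fixed) if fixed else {}
        self.weights = weights

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TMEModel":
        """Build from a tidy frame with ``mouse``, ``t_days`` and state columns."""
        return cls(ObservedDataset.from_dataframe(df), **kwargs)

    def loss(self, params: ParameterSet | Mapping[str, float]) -> float:
        return sse_loss(
            params, self.data, self.hypoxia, weights=self.weights
        )

    def fit(
        self, config: GAConfig | None = None, seed: int | None = None
    ) -> "TMEResults":
        """Hybrid-GA estimation; ``seed`` overrides the config seed."""
        config = config or GAConfig()
        if seed is not None:
            config = GAConfig(**{**config.__dict__, "seed": seed})
        fr = fit_hga(
            self.data, config,
            hyp=self.hypoxia,
            free_names=self.free_names,
            fixed=self.fixed,
            weights=self.weights,
        )
        return TMEResults(self, fr)


class TMEResults:
    """Fit outcome with simulation, identifiability and sensitivity methods."""

    def __init__(self, model: TMEModel, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result

    # -- estimates ----------------------------------------------------------
    @property
    def params(self) -> ParameterSet:
        return self.fit_result.params

    @property
    def fun(self) -> float:
        return self.fit_result.fun

    @property
    def history(self) -> np.ndarray:
        return self.fit_result.history

    def summary(self, top: int = 15) -> str:
        """Plain-text fit summary: loss diagnostics and leading estimates."""
        fr = self.fit_result
        lines = ["TME model fit (hybrid GA + local refinement)",
                 "=" * 46]
        lines += fr.summary_lines()
        free = fr.free_names or PARAM_NAMES
        est = sorted(
            ((nm, self.params[nm]) for nm in free), key=lambda kv: -kv[1]
        )
        lines.append("-" * 46)
        lines.append(f"largest estimates ({min(top, len(est))} of {len(est)} free)")
        for nm, v in est[:top]:
            lines.append(f"  {nm:<16s} {v:10.6f}")
        return "\n".join(lines)

    # -- simulation ---------------------------------------------------------
    def simulate(
        self,
        mouse=None,
        t_end: float = 150.0,
        dt: float = 1.0,
        t_grid: np.ndarray | None = None,
    ) -> Trajectory:
        """Integrate at the fitted parameters from a mouse's observed t=0 state."""
        mouse = mouse if mouse is not None else self.model.data.mice[0]
        if t_grid is None:
            t_grid = np.arange(0.0, t_end + dt / 2, dt)
        x0 = self.model.data.initial_state(mouse)
        return simulate(self.params, self.model.hypoxia, x0, t_grid)

    # -- identifiability ----------------------------------------------------
    def profile(
        self, param_name: str, grid_size: int = 21, **kwargs
    ) -> ProfileCurve:
        return profile_likelihood(
            param_name, self.fit_result, self.model.data, grid_size,
            hyp=self.model.hypoxia, **kwargs
        )

    def profile_all(
        self,
        names: Sequence[str] | None = None,
        grid_size: int = 21,
        alpha: float = 0.95,
        flat_tol: float = 0.1,
        **kwargs,
    ) -> dict:
        """Profile several parameters and tally identifiability labels."""
        names = tuple(names) if names is not None else (
            self.fit_result.free_names or PARAM_NAMES
        )
        curves = {
            nm: self.profile(nm, grid_size=grid_size, **kwargs) for nm in names
        }
        labels = {
            nm: classify(c, alpha=alpha, flat_tol=flat_tol)
            for nm, c in curves.items()
        }
        counts: dict[str, int] = {}
        for lab in labels.values():
            counts[lab] = counts.get(lab, 0) + 1
        return {"curves": curves, "labels": labels, "counts": counts}

    # -- sensitivity --------------------------------------------------------
    def sensitivity(
        self,
        mouse=None,
        t_grid: np.ndarray | None = None,
        outputs: Sequence[str] | None = None,
        scaling: str = "scaled",
        **kwargs,
    ) -> Decomposition:
        """PC decomposition of the trajectory sensitivity at the fit."""
        mouse = mouse if mouse is not None else self.model.data.mice[0]
        if t_grid is None:
            t_grid = np.arange(0.0, 151.0, 1.0)
        M = sensitivity_matrix(
            self.params, self.model.hypoxia,
            self.model.data.initial_state(mouse), t_grid,
            outputs=outputs, scaling=scaling, **kwargs
        )
        return pc_decompose(M)

    def scalar_sensitivity(
        self, output: str, mouse=None, t_grid: np.ndarray | None = None,
        **kwargs,
    ) -> dict:
        mouse = mouse if mouse is not None else self.model.data.mice[0]
        if t_grid is None:
            t_grid = np.arange(0.0, 151.0, 1.0)
        return scalar_sensitivity(
            output, self.params, self.model.hypoxia,
            self.model.data.initial_state(mouse), t_grid, **kwargs
        )

    def perturb(
        self,
        param_name: str,
        deltas: Sequence[float],
        mouse=None,
        t_grid: np.ndarray | None = None,
    ) -> dict:
        mouse = mouse if mouse is not None else self.model.data.mice[0]
        if t_grid is None:
            t_grid = np.arange(0.0, 151.0, 1.0)
        return perturbation_experiment(
            param_name, deltas, self.params, self.model.hypoxia,
            self.model.data.initial_state(mouse), t_grid,
        )

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the fit (estimates, loss, history, config) as JSON."""
        fr = self.fit_result
        payload = {
            "params": self.params.to_dict(),
            "hypoxia": self.model.hypoxia.to_dict(),
            "loss": fr.fun,
            "ga_loss": fr.ga_fun,
            "refinement_delta": fr.refinement_delta,
            "history": fr.history.tolist(),
            "n_evaluations": fr.n_evaluations,
            "seed": fr.seed,
            "free_names": list(fr.free_names or PARAM_NAMES),
            "config": {
                k: v for k, v in fr.config.__dict__.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path, data: ObservedDataset) -> "TMEResults":
        payload = json.loads(Path(path).read_text())
        hyp = HypoxiaParams(
            ox_crit1=payload["hypoxia"]["ox_crit1"],
            ox_crit2=payload["hypoxia"]["ox_crit2"],
            m=payload["hypoxia"]["m_hill"],
        )
        cfg = GAConfig(**payload["config"])
        model = TMEModel(
            data, hyp, free_names=payload["free_names"]
        )
        fr = FitResult(
            params=ParameterSet(payload["params"]),
            x=np.array(
                [payload["params"][nm] for nm in payload["free_names"]]
            ),
            fun=payload["loss"],
            ga_fun=payload["ga_loss"],
            history=np.array(payload["history"]),
            refinement_delta=payload["refinement_delta"],
            n_evaluations=payload["n_evaluations"],
            seed=payload["seed"],
            config=cfg,
            free_names=tuple(payload["free_names"]),
        )
        return cls(model, fr)
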