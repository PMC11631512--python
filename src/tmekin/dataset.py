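"""Container for per-mouse observations of all 18 model variables."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import N_STATES, STATE_VARS

__all__ = ["ObservedDataset", "WEEK_TO_DAY"]

#: Sampling-time mapping: week 6 is the system's initial state (t = 0 days)
#: and sampling is biweekly thereafter.
WEEK_TO_DAY: dict[int, float] = {6: 0.0, 8: 14.0, 10: 28.0, 12: 42.0}


@dataclass
class ObservedDataset:
    """Non-dimensional observations, one ``(T, 18)`` matrix per mouse.

    ``values`` maps a mouse identifier to a matrix whose columns follow the
    canonical state order and whose rows follow ``times`` (days, strictly
    ascending, starting at 0). ``scales`` optionally records the per-variable
    maxima used for non-dimensionalization so observations can be converted
    back to absolute counts / levels.
    """

    times: np.ndarray
    values: dict[int | str, np.ndarray]
    weights: dict[int | str, np.ndarray] | None = None
    scales: dict[str, float] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times[0] != 0.0:
            raise ValueError("times must be a 1-d grid starting at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for m, mat in self.values.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (self.times.size, N_STATES):
                raise ValueError(
                    f"mouse {m}: expected shape {(self.times.size, N_STATES)}, "
                    f"got {mat.shape}"
                )
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"mouse {m}: non-finite observations")
            self.values[m] = mat

    @property
    def mice(self) -> list:
        return list(self.values)

    def initial_state(self, mouse) -> np.ndarray:
        """Observed state at t = 0, used as the simulation initial condition."""
        return self.values[mouse][0].copy()

    def select_mice(self, mice) -> "ObservedDataset":
        return ObservedDataset(
            self.times.copy(),
            {m: self.values[m].copy() for m in mice},
            weights=(
                {m: self.weights[m].copy() for m in mice} if self.weights else None
            ),
            scales=dict(self.scales) if self.scales else None,
        )

    # -- tidy-frame round trip ---------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for m, mat in self.values.items():
            for i, t in enumerate(self.times):
                row = {"mouse": m, "t_days": t}
                row.update(dict(zip(STATE_VARS, mat[i])))
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ObservedDataset":
        times = np.sort(df["t_days"].unique())
        values = {}
        for m, grp in df.groupby("mouse"):
            grp = grp.sort_values("t_days")
            values[m] = grp[list(STATE_VARS)].to_numpy(dtype=float)
        return cls(times, values)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservedDataset":
        return cls.from_dataframe(pd.read_csv(path))
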