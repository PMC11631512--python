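"""Parameter registry for the tumour-microenvironment ODE model.

Naming conventions (ASCII renderings of the field's usual symbols):

``lambda_XY``
    rate at which species Y promotes production/proliferation of species X
``delta_XY``
    rate at which species Y inhibits or kills species X
``delta_XYOx`` / ``delta_XOx``
    hypoxia-proportional inhibition (multiplies a Hill switch of oxygen)
``delta_X``
    natural decay / death rate of X
``A_X``
    innate (constant) production rate of naive cell type X
``delta_1`` .. ``delta_6``
    oxygen consumption rates of the six major cell groups
    (T cells, dendritic cells, macrophages, cancer, adipocytes, endothelial)
``EN0, C0, A0``
    carrying capacities of the three logistically growing cell types

Every distinct rate symbol appearing in the model equations is registered
exactly once, including symbols shared between equations (the naive->activated
differentiation rates appear in both the naive-pool sink and the activated-pool
source; the dendritic hypoxic death rate ``delta_DNOx`` is shared by the naive
and activated pools).
"""

from __future__ import annotations

import json
from collections.abc import Iterator, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "RATE_NAMES",
    "CAPACITY_NAMES",
    "HYPOXIA_NAMES",
    "EXTENDED_NAMES",
    "ParameterSet",
    "HypoxiaParams",
]

#: Rate constants, grouped by the equation in which they first appear.
RATE_NAMES: tuple[str, ...] = (
    # endothelial cells (EN)
    "lambda_VEN", "delta_ENIL12", "delta_EN", "delta_ENOx",
    # VEGF (V)
    "lambda_VA", "lambda_VM", "lambda_VCOx", "lambda_VOx", "delta_V",
    # oxygen (Ox)
    "lambda_OxEN", "delta_1", "delta_2", "delta_3", "delta_4", "delta_5",
    "delta_6", "delta_Ox",
    # naive T cells (TN)
    "A_TN", "delta_TN", "delta_TNOx",
    # helper T cells (Th) — the three activation rates also drain TN
    "lambda_ThH", "lambda_ThD", "lambda_ThIL12",
    "delta_ThTr", "delta_ThIL10", "delta_Th", "delta_ThOx",
    # cytotoxic T cells (Tc)
    "lambda_TcD", "lambda_TcIL12",
    "delta_TcTr", "delta_TcIL10", "delta_Tc", "delta_TcOx",
    # regulatory T cells (Tr)
    "lambda_TrD", "lambda_TrOx", "delta_Tr", "delta_TrOx",
    # naive dendritic cells (DN) — activation rates shared with D;
    # delta_DNOx is the hypoxic death rate of both pools
    "A_DN", "lambda_DC", "lambda_DH", "lambda_DOx", "delta_DN", "delta_DNOx",
    # activated dendritic cells (D)
    "delta_DC", "delta_D",
    # naive macrophages (MN) — activation rates shared with M
    "A_MN", "lambda_MIL10", "lambda_MIL12", "lambda_MTh", "delta_MN",
    # activated macrophages (M)
    "delta_M",
    # cancer (C)
    "lambda_C", "lambda_CIL6", "lambda_CA",
    "delta_CTc", "delta_CTcOx", "delta_COx", "delta_C",
    # necrotic cells (N)
    "alpha_NC", "delta_N",
    # adipocytes (A)
    "lambda_A", "delta_A",
    # HMGB1 (H)
    "lambda_HD", "lambda_HN", "lambda_HM", "lambda_HTc", "lambda_HC",
    "delta_H",
    # IL-12
    "lambda_IL12M", "lambda_IL12D", "delta_IL12",
    # IL-10
    "lambda_IL10M", "lambda_IL10D", "lambda_IL10Tr", "lambda_IL10Th",
    "lambda_IL10Tc", "lambda_IL10C", "lambda_IL10Ox", "delta_IL10",
    # IL-6
    "lambda_IL6A", "lambda_IL6M", "lambda_IL6MOx", "lambda_IL6D",
    "lambda_IL6Ox", "delta_IL6",
)

CAPACITY_NAMES: tuple[str, ...] = ("EN0", "C0", "A0")

#: Estimated parameters: every rate plus the three carrying capacities.
PARAM_NAMES: tuple[str, ...] = RATE_NAMES + CAPACITY_NAMES

#: Hypoxia-switch shape parameters, kept as a separate extended block.
HYPOXIA_NAMES: tuple[str, ...] = ("ox_crit1", "ox_crit2", "m_hill")

#: Full parameter axis used by the sensitivity analysis.
EXTENDED_NAMES: tuple[str, ...] = PARAM_NAMES + HYPOXIA_NAMES

PARAM_INDEX: dict[str, int] = {n: i for i, n in enumerate(PARAM_NAMES)}


class ParameterSet(Mapping):
    """Immutable named registry of the model's estimated parameters.

    Behaves as a mapping from parameter name to non-negative float. Missing
    names default to 0 only in :meth:`from_partial`; the plain constructor
    requires the complete registry.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        missing = set(PARAM_NAMES) - set(values)
        extra = set(values) - set(PARAM_NAMES)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)[:5]}...")
        if extra:
            raise ValueError(f"unknown parameters: {sorted(extra)}")
        arr = np.array([float(values[n]) for n in PARAM_NAMES])
        if not np.all(np.isfinite(arr)):
            raise ValueError("parameters must be finite")
        if np.any(arr < 0):
            bad = [n for n, v in zip(PARAM_NAMES, arr) if v < 0]
            raise ValueError(f"negative parameters not allowed: {bad}")
        self._values = arr

    # -- mapping protocol ---------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return float(self._values[PARAM_INDEX[name]])

    def __iter__(self) -> Iterator[str]:
        return iter(PARAM_NAMES)

    def __len__(self) -> int:
        return len(PARAM_NAMES)

    def __repr__(self) -> str:
        nz = int(np.count_nonzero(self._values))
        return f"ParameterSet({len(self)} parameters, {nz} non-zero)"

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and np.array_equal(
            self._values, other._values
        )

    # -- constructors -------------------------------------------------------
    @classmethod
    def zeros(cls) -> "ParameterSet":
        return cls(dict.fromkeys(PARAM_NAMES, 0.0))

    @classmethod
    def from_partial(cls, values: Mapping[str, float]) -> "ParameterSet":
        """Build a set where every unmentioned parameter is zero."""
        full = dict.fromkeys(PARAM_NAMES, 0.0)
        full.update(values)
        return cls(full)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ParameterSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected shape ({len(PARAM_NAMES)},), got {arr.shape}")
        return cls(dict(zip(PARAM_NAMES, arr)))

    # -- conversions --------------------------------------------------------
    def to_array(self) -> np.ndarray:
        return self._values.copy()

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(PARAM_NAMES, self._values)}

    def replace(self, **updates: float) -> "ParameterSet":
        d = self.to_dict()
        d.update(updates)
        return ParameterSet(d)

    def to_json(self, path: str | Path | None = None, hypoxia: "HypoxiaParams | None" = None) -> str:
        """Serialise as flat JSON; optionally append the hypoxia block."""
        d: dict[str, float] = self.to_dict()
        if hypoxia is not None:
            d.update(hypoxia.to_dict())
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> tuple["ParameterSet", "HypoxiaParams | None"]:
        """Read a flat JSON registry, splitting off any hypoxia block."""
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        hyp = None
        if any(k in d for k in HYPOXIA_NAMES):
            hyp = HypoxiaParams(
                ox_crit1=d.pop("ox_crit1"),
                ox_crit2=d.pop("ox_crit2"),
                m=d.pop("m_hill"),
            )
        return cls(d), hyp


@dataclass(frozen=True)
class HypoxiaParams:
    """Shape of the two oxygen Hill switches.

    ``ox_crit1`` is the non-dimensional threshold between normoxia and mild
    hypoxia (HIF-pathway activation, ~1% O2); ``ox_crit2`` the threshold
    between mild and severe hypoxia (cell-cycle arrest/death, ~0.1% O2).
    ``m`` is the Hill exponent governing the sharpness of both switches.

    Defaults place the thresholds at 1% and 0.1% O2 converted through the
    aqueous ppm scale and divided by the week-6 maximum of 3.125 mol/l
    (10000 ppm -> 0.625 mol/l -> 0.2; 1000 ppm -> 0.0625 -> 0.02).
    """

    ox_crit1: float = 0.2
    ox_crit2: float = 0.02
    m: float = 5.0

    def __post_init__(self):
        if not (self.ox_crit1 > self.ox_crit2 > 0):
            raise ValueError("require ox_crit1 > ox_crit2 > 0")
        if self.m <= 0:
            raise ValueError("Hill exponent m must be positive")

    def to_dict(self) -> dict[str, float]:
        return {
            "ox_crit1": self.ox_crit1,
            "ox_crit2": self.ox_crit2,
            "m_hill": self.m,
        }
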