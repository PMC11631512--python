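"""The 18-state non-dimensional ODE system for the breast tumour microenvironment.

State variables (canonical order used everywhere in the package):

====  =========================================
EN    endothelial cells (vasculature proxy)
V     VEGF
Ox    oxygen
TN    naive T cells
Th    helper T cells
Tc    cytotoxic T cells
Tr    regulatory T cells
DN    naive dendritic cells
D     activated dendritic cells
MN    naive macrophages
M     activated macrophages
C     cancer cells
N     necrotic cells
A     adipocytes
H     HMGB1
IL12  interleukin-12
IL10  interleukin-10
IL6   interleukin-6
====  =========================================

All variables are dimensionless (scaled so the observed data lie in [0, 1]);
time is measured in days. Hypoxia acts through two Hill switches of oxygen:
``f1`` (mild hypoxia, HIF-pathway activation) and ``f2`` (severe hypoxia,
cell-cycle arrest and death), sharing the exponent ``m`` but with different
critical oxygen levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import HypoxiaParams, ParameterSet

__all__ = [
    "STATE_VARS",
    "N_STATES",
    "IMMUNE_VARS",
    "CELL_VARS",
    "hill_hypoxia",
    "rhs",
    "make_rhs",
    "simulate",
    "Trajectory",
    "observables",
    "IntegrationError",
]

STATE_VARS: tuple[str, ...] = (
    "EN", "V", "Ox", "TN", "Th", "Tc", "Tr", "DN", "D",
    "MN", "M", "C", "N", "A", "H", "IL12", "IL10", "IL6",
)
N_STATES = len(STATE_VARS)
STATE_INDEX: dict[str, int] = {v: i for i, v in enumerate(STATE_VARS)}

#: The eight immune-cell compartments (total immune count = their sum).
IMMUNE_VARS: tuple[str, ...] = ("TN", "Th", "Tc", "Tr", "DN", "D", "MN", "M")

#: All cell-type compartments (cytokines and oxygen excluded).
CELL_VARS: tuple[str, ...] = (
    "EN", "TN", "Th", "Tc", "Tr", "DN", "D", "MN", "M", "C", "N", "A",
)


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failure time."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


def hill_hypoxia(x: float | np.ndarray, ox_crit: float, m: float):
    """Decreasing Hill switch ``ox_crit^m / (ox_crit^m + x^m)``.

    Equals 1 at zero oxygen, 1/2 at ``x = ox_crit``, and decays to 0 as
    oxygen rises; ``m`` controls the sharpness of the transition.
    """
    if ox_crit <= 0:
        raise ValueError("ox_crit must be positive")
    if m <= 0:
        raise ValueError("Hill exponent m must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("oxygen level must be non-negative")
    # work in units of ox_crit for numerical range safety
    r = np.power(x / ox_crit, m)
    out = 1.0 / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def make_rhs(
    params: Mapping[str, float], hyp: HypoxiaParams
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Bind parameters into a fast ``f(t, y) -> dy`` closure.

    Parameters are captured as plain floats so repeated calls during
    integration avoid any dictionary lookups.
    """
    p = params
    lam_VEN = p["lambda_VEN"]; del_ENIL12 = p["delta_ENIL12"]
    del_EN = p["delta_EN"]; del_ENOx = p["delta_ENOx"]; EN0 = p["EN0"]
    lam_VA = p["lambda_VA"]; lam_VM = p["lambda_VM"]
    lam_VCOx = p["lambda_VCOx"]; lam_VOx = p["lambda_VOx"]; del_V = p["delta_V"]
    lam_OxEN = p["lambda_OxEN"]; del_Ox = p["delta_Ox"]
    d1 = p["delta_1"]; d2 = p["delta_2"]; d3 = p["delta_3"]
    d4 = p["delta_4"]; d5 = p["delta_5"]; d6 = p["delta_6"]
    A_TN = p["A_TN"]; del_TN = p["delta_TN"]; del_TNOx = p["delta_TNOx"]
    lam_ThH = p["lambda_ThH"]; lam_ThD = p["lambda_ThD"]
    lam_ThIL12 = p["lambda_ThIL12"]; del_ThTr = p["delta_ThTr"]
    del_ThIL10 = p["delta_ThIL10"]; del_Th = p["delta_Th"]
    del_ThOx = p["delta_ThOx"]
    lam_TcD = p["lambda_TcD"]; lam_TcIL12 = p["lambda_TcIL12"]
    del_TcTr = p["delta_TcTr"]; del_TcIL10 = p["delta_TcIL10"]
    del_Tc = p["delta_Tc"]; del_TcOx = p["delta_TcOx"]
    lam_TrD = p["lambda_TrD"]; lam_TrOx = p["lambda_TrOx"]
    del_Tr = p["delta_Tr"]; del_TrOx = p["delta_TrOx"]
    A_DN = p["A_DN"]; lam_DC = p["lambda_DC"]; lam_DH = p["lambda_DH"]
    lam_DOx = p["lambda_DOx"]; del_DN = p["delta_DN"]; del_DNOx = p["delta_DNOx"]
    del_DC = p["delta_DC"]; del_D = p["delta_D"]
    A_MN = p["A_MN"]; lam_MIL10 = p["lambda_MIL10"]
    lam_MIL12 = p["lambda_MIL12"]; lam_MTh = p["lambda_MTh"]
    del_MN = p["delta_MN"]; del_M = p["delta_M"]
    lam_C = p["lambda_C"]; lam_CIL6 = p["lambda_CIL6"]; lam_CA = p["lambda_CA"]
    C0 = p["C0"]; del_CTc = p["delta_CTc"]; del_CTcOx = p["delta_CTcOx"]
    del_COx = p["delta_COx"]; del_C = p["delta_C"]
    alpha_NC = p["alpha_NC"]; del_N = p["delta_N"]
    lam_A = p["lambda_A"]; A0 = p["A0"]; del_A = p["delta_A"]
    lam_HD = p["lambda_HD"]; lam_HN = p["lambda_HN"]; lam_HM = p["lambda_HM"]
    lam_HTc = p["lambda_HTc"]; lam_HC = p["lambda_HC"]; del_H = p["delta_H"]
    lam_IL12M = p["lambda_IL12M"]; lam_IL12D = p["lambda_IL12D"]
    del_IL12 = p["delta_IL12"]
    lam_IL10M = p["lambda_IL10M"]; lam_IL10D = p["lambda_IL10D"]
    lam_IL10Tr = p["lambda_IL10Tr"]; lam_IL10Th = p["lambda_IL10Th"]
    lam_IL10Tc = p["lambda_IL10Tc"]; lam_IL10C = p["lambda_IL10C"]
    lam_IL10Ox = p["lambda_IL10Ox"]; del_IL10 = p["delta_IL10"]
    lam_IL6A = p["lambda_IL6A"]; lam_IL6M = p["lambda_IL6M"]
    lam_IL6MOx = p["lambda_IL6MOx"]; lam_IL6D = p["lambda_IL6D"]
    lam_IL6Ox = p["lambda_IL6Ox"]; del_IL6 = p["delta_IL6"]

    oc1_m = hyp.ox_crit1 ** hyp.m
    oc2_m = hyp.ox_crit2 ** hyp.m
    m = hyp.m

    def f(t: float, y: np.ndarray) -> np.ndarray:
        (EN, V, Ox, TN, Th, Tc, Tr, DN, D,
         MN, M, C, N, A, H, IL12, IL10, IL6) = y
        xm = abs(Ox) ** m
        f1 = oc1_m / (oc1_m + xm)
        f2 = oc2_m / (oc2_m + xm)

        # logistic growth terms guard against zero capacity: a compartment
        # with zero capacity cannot grow.
        gEN = lam_VEN * V * (1.0 - EN / EN0) * EN if EN0 > 0 else 0.0
        gC = (
            (lam_C + lam_CIL6 * IL6 + lam_CA * A) * (1.0 - C / C0) * C
            if C0 > 0 else 0.0
        )
        gA = lam_A * (1.0 - A / A0) * A if A0 > 0 else 0.0

        th_act = lam_ThH * H + lam_ThD * D + lam_ThIL12 * IL12
        tc_act = lam_TcD * D + lam_TcIL12 * IL12
        tr_act = lam_TrD * D + lam_TrOx * f1
        d_act = lam_DC * C + lam_DH * H + lam_DOx * f1
        m_act = lam_MIL10 * IL10 + lam_MIL12 * IL12 + lam_MTh * Th
        c_kill = del_CTc * Tc + del_CTcOx * f1 * Tc + del_COx * f2 + del_C

        dEN = gEN - del_ENIL12 * IL12 * EN - (del_EN + del_ENOx * f2) * EN
        dV = lam_VA * A + lam_VM * M + lam_VCOx * C * f1 + lam_VOx * f1 - del_V * V
        dOx = (
            lam_OxEN * EN
            - d1 * (TN + Th + Tc + Tr) * Ox
            - d2 * (DN + D) * Ox
            - d3 * (MN + M) * Ox
            - d4 * C * Ox
            - d5 * A * Ox
            - d6 * EN * Ox
            - del_Ox * Ox
        )
        dTN = (
            A_TN
            - th_act * TN - tc_act * TN - tr_act * TN
            - (del_TN + del_TNOx * f2) * TN
        )
        dTh = (
            th_act * TN
            - (del_ThTr * Tr + del_ThIL10 * IL10) * Th
            - (del_Th + del_ThOx * f2) * Th
        )
        dTc = (
            tc_act * TN
            - (del_TcTr * Tr + del_TcIL10 * IL10) * Tc
            - (del_Tc + del_TcOx * f2) * Tc
        )
        dTr = tr_act * TN - (del_Tr + del_TrOx * f2) * Tr
        dDN = A_DN - d_act * DN - (del_DN + del_DNOx * f2) * DN
        dD = d_act * DN - (del_DC * C + del_D + del_DNOx * f2) * D
        dMN = A_MN - (m_act + del_MN) * MN
        dM = m_act * MN - del_M * M
        dC = gC - c_kill * C
        dN = alpha_NC * c_kill * C - del_N * N
        dA = gA - del_A * A
        dH = (
            lam_HD * D + lam_HN * N + lam_HM * M + lam_HTc * Tc + lam_HC * C
            - del_H * H
        )
        dIL12 = lam_IL12M * M + lam_IL12D * D - del_IL12 * IL12
        dIL10 = (
            lam_IL10M * M + lam_IL10D * D + lam_IL10Tr * Tr + lam_IL10Th * Th
            + lam_IL10Tc * Tc + lam_IL10C * C + lam_IL10Ox * f1
            - del_IL10 * IL10
        )
        dIL6 = (
            lam_IL6A * A + lam_IL6M * M + lam_IL6MOx * M * f1 + lam_IL6D * D
            + lam_IL6Ox * f1
            - del_IL6 * IL6
        )
        return np.array([
            dEN, dV, dOx, dTN, dTh, dTc, dTr, dDN, dD,
            dMN, dM, dC, dN, dA, dH, dIL12, dIL10, dIL6,
        ])

    return f


def rhs(
    t: float,
    state: Sequence[float] | np.ndarray,
    params: Mapping[str, float] | ParameterSet,
    hyp: HypoxiaParams,
) -> np.ndarray:
    """Time derivative of the 18-component state vector."""
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have shape ({N_STATES},), got {y.shape}")
    return make_rhs(params, hyp)(t, y)


@dataclass
class Trajectory:
    """An integrated solution on an ascending time grid (days)."""

    times: np.ndarray
    states: np.ndarray  # (len(times), 18)
    params: ParameterSet | None = None
    hypoxia: HypoxiaParams | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, N_STATES):
            raise ValueError(
                f"states shape {self.states.shape} inconsistent with "
                f"{self.times.size} time points"
            )
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite values")

    def __getitem__(self, var: str) -> np.ndarray:
        return self.states[:, STATE_INDEX[var]]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_VARS))
        df.insert(0, "t_days", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["t_days"].to_numpy(), df[list(STATE_VARS)].to_numpy())


def simulate(
    params: ParameterSet | Mapping[str, float],
    hyp: HypoxiaParams,
    x0: Sequence[float] | np.ndarray,
    t_grid: Sequence[float] | np.ndarray,
    *,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step: float = np.inf,
) -> Trajectory:
    """Integrate the model on ``t_grid`` (ascending, starting at the initial time).

    Uses a stiff-capable integrator (LSODA by default) because the cytokine
    time scales are much faster than the cell ones. Small negative excursions
    within the absolute tolerance are clipped to zero; larger ones are left
    untouched so genuine solver trouble stays visible.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("t_grid must be a 1-d grid with at least two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly ascending")
    y0 = np.asarray(x0, dtype=float)
    if y0.shape != (N_STATES,):
        raise ValueError(f"x0 must have shape ({N_STATES},), got {y0.shape}")

    f = make_rhs(params, hyp)
    sol = solve_ivp(
        f, (t[0], t[-1]), y0, t_eval=t, method=method,
        rtol=rtol, atol=atol, max_step=max_step,
    )
    if not sol.success or sol.y.shape[1] != t.size:
        t_fail = float(sol.t[-1]) if sol.t.size else float(t[0])
        raise IntegrationError(
            f"integration failed at t={t_fail:.3f} d: {sol.message}", t_fail
        )
    states = sol.y.T.copy()
    # clip tiny negative excursions (|value| below the solver's abs tolerance)
    mask = (states < 0) & (np.abs(states) < atol)
    states[mask] = 0.0
    pset = params if isinstance(params, ParameterSet) else None
    return Trajectory(t, states, params=pset, hypoxia=hyp)


def observables(traj: Trajectory) -> dict[str, np.ndarray]:
    """Derived scalar series: cancer, total immune cells, total cells."""
    total_immune = sum(traj[v] for v in IMMUNE_VARS)
    total_cells = sum(traj[v] for v in CELL_VARS)
    return {
        "cancer": traj["C"].copy(),
        "total_immune": np.asarray(total_immune, dtype=float),
        "total_cells": np.asarray(total_cells, dtype=float),
    }
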