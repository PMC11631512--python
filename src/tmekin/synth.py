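"""Synthetic ground truths and observations for end-to-end pipeline testing.

The generator emulates the shape of the real study inputs without any
download: ground-truth parameter sets drawn from a box prior (optionally
sparse so the active subsystem stays well conditioned), noisy observations of
all 18 variables at the four biweekly sampling times, and fraction/volume
tables in exactly the schema the data-preparation stage consumes — so the
whole pipeline closes: counts -> fractions -> counts round-trips exactly, and
a noiseless observation set has zero loss at the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataprep import (
    STAGE_WEEKS,
    STAGES,
    CellSizeTable,
    StageAnchors,
    mouse_anchor,
    stage_estimate,
)
from .dataset import WEEK_TO_DAY, ObservedDataset
from .model import IMMUNE_VARS, N_STATES, STATE_VARS, IntegrationError, simulate
from .params import PARAM_NAMES, HypoxiaParams, ParameterSet

__all__ = [
    "SynthConfig",
    "DEFAULT_X0",
    "sample_ground_truth",
    "make_observations",
    "make_truth_counts",
    "make_fraction_tables",
    "RECOVERY_TRUTH",
    "recovery_experiment",
]

#: Default synthetic initial state: the mean-anchored mouse's week-6
#: non-dimensional values (mouse 2 of the bundled dataset), state order
#: EN, V, Ox, TN, Th, Tc, Tr, DN, D, MN, M, C, N, A, H, IL12, IL10, IL6.
DEFAULT_X0 = np.array([
    0.16293646, 0.71692877, 1.0, 0.45469693, 0.54943724, 0.21749785,
    0.19479133, 0.48006054, 0.55437945, 0.57197455, 0.30586025,
    0.43421053, 0.43421053, 0.08265668, 0.76307295, 0.0,
    0.62240664, 0.51041667,
])


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for synthetic generation.

    Defaults mirror the real design: three mice, biweekly sampling at
    t = 0/14/28/42 days, 5% multiplicative observation noise and a uniform
    [0, 2] box prior over the estimated parameters.
    """

    seed: int | None = None
    n_mice: int = 3
    times: tuple[float, ...] = (0.0, 14.0, 28.0, 42.0)
    noise: float = 0.05
    lower: float = 0.0
    upper: float = 2.0
    sparsity: Mapping[str, tuple[float, float]] | Sequence[str] | None = None
    retry_cap: int = 50
    t_check: float = 150.0

    def __post_init__(self):
        if self.noise < 0:
            raise ValueError("noise must be non-negative")
        t = np.asarray(self.times)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must ascend from 0")


def sample_ground_truth(
    config: SynthConfig,
    hyp: HypoxiaParams | None = None,
    x0: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> ParameterSet:
    """Seeded draw of an integrable ground-truth parameter set.

    ``config.sparsity`` may be a list of free parameter names (all others
    zero) or a mapping name -> (low, high) overriding the box prior for those
    names, zeroing the rest. Draws that fail to integrate over
    ``[0, t_check]`` are rejected and redrawn, up to ``retry_cap`` attempts.
    """
    hyp = hyp or HypoxiaParams()
    x0 = DEFAULT_X0 if x0 is None else np.asarray(x0, dtype=float)
    rng = rng or np.random.default_rng(config.seed)

    if config.sparsity is None:
        prior = {nm: (config.lower, config.upper) for nm in PARAM_NAMES}
    elif isinstance(config.sparsity, Mapping):
        prior = dict(config.sparsity)
    else:
        prior = {nm: (config.lower, config.upper) for nm in config.sparsity}
    unknown = set(prior) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameters in prior: {sorted(unknown)}")

    t_grid = np.array([0.0, config.t_check / 2, config.t_check])
    for _ in range(config.retry_cap):
        vals = dict.fromkeys(PARAM_NAMES, 0.0)
        for nm, (lo, hi) in prior.items():
            vals[nm] = rng.uniform(lo, hi)
        truth = ParameterSet(vals)
        try:
            simulate(truth, hyp, x0, t_grid, rtol=1e-6, atol=1e-8)
        except (IntegrationError, ValueError):
            continue
        return truth
    raise RuntimeError(
        f"no integrable parameter set found in {config.retry_cap} draws"
    )


def make_observations(
    truth: ParameterSet,
    config: SynthConfig,
    hyp: HypoxiaParams | None = None,
    x0: np.ndarray | None = None,
    *,
    noise_model: str = "uniform",
    rescale: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[ObservedDataset, ObservedDataset]:
    """Noisy observations plus the noiseless reference dataset.

    Simulates the truth, samples ``config.times``, applies multiplicative
    noise per entry (uniform in ``[1-noise, 1+noise]`` by default, or
    lognormal with matching scale) and clips at zero. With ``rescale`` the
    max-scaling rule is applied afterwards; it is off by default because the
    simulated states are already non-dimensional, so a noiseless dataset
    evaluates to exactly zero loss at the truth.
    """
    hyp = hyp or HypoxiaParams()
    x0 = DEFAULT_X0 if x0 is None else np.asarray(x0, dtype=float)
    rng = rng or np.random.default_rng(config.seed)
    times = np.asarray(config.times, dtype=float)

    traj = simulate(truth, hyp, x0, times)
    ref = traj.states.copy()

    noisy_values: dict[int, np.ndarray] = {}
    ref_values: dict[int, np.ndarray] = {}
    for mouse in range(1, config.n_mice + 1):
        if config.noise == 0:
            vals = ref.copy()
        elif noise_model == "uniform":
            factors = rng.uniform(
                1.0 - config.noise, 1.0 + config.noise, size=ref.shape
            )
            vals = ref * factors
        elif noise_model == "lognormal":
            # sigma chosen so the log-sd matches the uniform half-width
            vals = ref * rng.lognormal(0.0, config.noise, size=ref.shape)
        else:
            raise ValueError("noise_model must be 'uniform' or 'lognormal'")
        vals = np.clip(vals, 0.0, None)
        if rescale:
            mx = vals.max(axis=0)
            mx[mx == 0] = 1.0
            vals = vals / mx
        noisy_values[mouse] = vals
        ref_values[mouse] = ref.copy()

    return (
        ObservedDataset(times, noisy_values),
        ObservedDataset(times, ref_values),
    )


# ---------------------------------------------------------------------------
# count / fraction tables shaped like the data-preparation inputs
# ---------------------------------------------------------------------------

#: Stage-typical oxygen levels in ppm (normoxia down to severe hypoxia).
STAGE_O2_PPM: dict[str, float] = {
    "hyperplasia": 50000.0,
    "adenoma": 10000.0,
    "early_carcinoma": 1000.0,
    "late_carcinoma": 10.0,
}


def make_truth_counts(
    config: SynthConfig,
    anchors: StageAnchors | None = None,
    sizes: CellSizeTable | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Ground-truth absolute counts consistent with the anchor arithmetic.

    Cancer and TAM totals follow the stage/mouse anchor rule exactly; immune
    counts are a random split of the TAM-anchored immune panel; necrotic is
    half of cancer; adipocyte and endothelial counts exactly fill the
    residual caliper volume so the volume budget closes. Cytokine expression
    levels are drawn at realistic magnitudes and oxygen follows the
    normoxia-to-severe-hypoxia stage progression (stored in mol/l).
    """
    anchors = anchors or StageAnchors()
    sizes = sizes or CellSizeTable()
    rng = rng or np.random.default_rng(config.seed)
    rows = []
    for mouse in range(1, config.n_mice + 1):
        for stage in STAGES:
            d = anchors.diameter_mm(stage)
            C = mouse_anchor(*stage_estimate(*anchors.cancer_yield, d), mouse)
            tam = mouse_anchor(*stage_estimate(*anchors.tam_yield, d), mouse)
            mn_share = rng.uniform(0.3, 0.7)
            counts = {"MN": tam * mn_share, "M": tam * (1.0 - mn_share)}
            # other immune pools: comparable order of magnitude to TAMs
            for v in ("TN", "Th", "Tc", "Tr", "DN", "D"):
                counts[v] = tam * rng.uniform(0.2, 2.0)
            counts["C"] = C
            counts["N"] = C / 2.0
            # adipocytes/endothelial cells fill the residual tumour volume
            used = sum(
                counts[v] * sizes.var_volume_um3(v) for v in IMMUNE_VARS
            ) + C * sizes.var_volume_um3("C")
            residual = anchors.volumes_mm3[stage] * 1e9 - used
            if residual <= 0:
                raise RuntimeError("immune/cancer volume exceeds stage volume")
            a_share = rng.uniform(0.2, 0.8)
            denom = (
                a_share * sizes.var_volume_um3("A")
                + (1.0 - a_share) * sizes.var_volume_um3("EN")
            )
            counts["A"] = a_share * residual / denom
            counts["EN"] = (1.0 - a_share) * residual / denom
            cyt = {
                "H": rng.uniform(700, 1600),
                "IL12": rng.uniform(0, 70),
                "IL10": rng.uniform(250, 750),
                "IL6": rng.uniform(30, 400),
                "V": rng.uniform(300, 1100),
                "Ox": STAGE_O2_PPM[stage] / 1000.0 / 16.0,
            }
            rows.append({"mouse": mouse, "stage": stage,
                         "week": STAGE_WEEKS[stage], **counts, **cyt})
    return pd.DataFrame(rows)


def make_fraction_tables(
    truth_counts: pd.DataFrame,
    sizes: CellSizeTable | None = None,
    config: SynthConfig | None = None,
) -> dict:
    """Invert a count table into the inputs the data-preparation stage reads.

    Emits immune fractions (normalised within the immune panel), TAM totals,
    non-immune fractions, caliper volumes equal to the exact volume sum of
    immune + cancer + non-immune cells, and oxygen in ppm — such that
    reassembling counts from these tables reproduces ``truth_counts`` up to
    arithmetic precision.
    """
    sizes = sizes or CellSizeTable()
    frac_rows = []
    vol_rows = []
    cyt_rows = []
    for r in truth_counts.itertuples():
        immune_total = sum(getattr(r, v) for v in IMMUNE_VARS)
        if immune_total <= 0:
            raise ValueError("immune counts must be positive")
        for v in IMMUNE_VARS:
            frac_rows.append({
                "mouse": r.mouse, "stage": r.stage, "cell_type": v,
                "fraction": getattr(r, v) / immune_total,
            })
        nonimmune_total = r.A + r.EN
        for v in ("A", "EN"):
            frac_rows.append({
                "mouse": r.mouse, "stage": r.stage, "cell_type": v,
                "fraction": (getattr(r, v) / nonimmune_total
                             if nonimmune_total > 0 else 0.0),
            })
        vol_um3 = (
            sum(getattr(r, v) * sizes.var_volume_um3(v) for v in IMMUNE_VARS)
            + r.C * sizes.var_volume_um3("C")
            + r.A * sizes.var_volume_um3("A")
            + r.EN * sizes.var_volume_um3("EN")
        )
        vol_rows.append({
            "mouse": r.mouse, "stage": r.stage,
            "tam_total": r.MN + r.M,
            "volume_mm3": vol_um3 / 1e9,
        })
        cyt_rows.append({
            "mouse": r.mouse, "stage": r.stage,
            "H": r.H, "IL12": r.IL12, "IL10": r.IL10, "IL6": r.IL6,
            "V": r.V, "Ox_ppm": r.Ox * 16.0 * 1000.0,
        })
    return {
        "fractions": pd.DataFrame(frac_rows),
        "totals": pd.DataFrame(vol_rows),
        "cytokines": pd.DataFrame(cyt_rows),
    }


# ---------------------------------------------------------------------------
# parameter-recovery benchmark
# ---------------------------------------------------------------------------

#: Sparse, structurally identifiable ground truth for recovery benchmarks:
#: an adipocyte logistic drives IL-6 production, a cancer logistic drives
#: HMGB1 production, so each free rate leaves a distinct fingerprint in the
#: four-time-point data.
RECOVERY_TRUTH: dict[str, float] = {
    "lambda_A": 0.15, "A0": 0.8,
    "lambda_C": 0.25, "C0": 0.9,
    "lambda_IL6A": 0.5, "delta_IL6": 0.4,
    "lambda_HC": 0.6, "delta_H": 0.3,
}

#: Initial state for the benchmark subsystem (all other compartments empty).
RECOVERY_X0 = np.zeros(N_STATES)
RECOVERY_X0[STATE_VARS.index("A")] = 0.1
RECOVERY_X0[STATE_VARS.index("C")] = 0.05
RECOVERY_X0[STATE_VARS.index("IL6")] = 0.05
RECOVERY_X0[STATE_VARS.index("H")] = 0.05


def recovery_experiment(
    seed: int,
    noise: float = 0.0,
    ga_config=None,
    truth: Mapping[str, float] | None = None,
    x0: np.ndarray | None = None,
) -> dict:
    """Fit the free subsystem parameters to synthetic data from a known truth.

    Returns the fit result, the per-parameter relative errors and their
    median. With zero noise the hybrid fit should land within a few percent
    of every generating value.
    """
    from .estimation import GAConfig, fit_hga

    truth = dict(truth if truth is not None else RECOVERY_TRUTH)
    x0 = RECOVERY_X0 if x0 is None else np.asarray(x0, dtype=float)
    free = tuple(truth)
    pset = ParameterSet.from_partial(truth)
    cfg = SynthConfig(seed=seed, n_mice=1, noise=noise)
    data, _ = make_observations(pset, cfg, x0=x0)
    ga = ga_config or GAConfig(
        population_size=40, max_generations=60, stall_generations=30,
        seed=seed,
    )
    fit = fit_hga(data, ga, free_names=free)
    rel = {
        nm: abs(fit.params[nm] - truth[nm]) / abs(truth[nm]) for nm in free
    }
    return {
        "fit": fit,
        "truth": pset,
        "rel_errors": rel,
        "median_rel_error": float(np.median(list(rel.values()))),
        "data": data,
    }
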