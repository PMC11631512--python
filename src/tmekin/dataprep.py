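"""Cell-count data preparation: from tumour geometry and cell fractions to model inputs.

The observation pipeline works from three ingredients:

1. *Tumour geometry.* Caliper volumes (``L x W^2 / 2``) at the four
   progression stages of the MMTV-PyMT mouse model — hyperplasia (week 6),
   adenoma/MIN (week 8), early carcinoma (week 10), late carcinoma
   (week 12) — are converted to an equivalent diameter assuming ``L ~ W``.
2. *Reference yields.* A dissociation protocol recovers ``4.5±0.9e7`` cancer
   cells and ``2.2±0.6e6`` tumour-associated macrophages (TAMs) per gram of
   tumour, where 1 g corresponds to two tumours of ~10 mm diameter. Scaling
   half the per-gram yield by ``d/10`` gives per-stage absolute estimates;
   per-mouse values take the mean plus ``k`` standard deviations with
   ``k = -1, 0, +1`` for mice 1, 2, 3.
3. *Deconvolved fractions.* Immune-cell fractions (summing to 1 within the
   immune panel) are turned into absolute counts by anchoring on the TAM
   total; adipocyte and endothelial counts fill the tumour volume left over
   after immune and cancer cells, split according to the non-immune fractions
   and single-cell caliper volumes.

All reported values reproduce the printed reference estimates only under
*truncation* (floor), not rounding: diameters are truncated to two decimals
and counts to three significant figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dataset import WEEK_TO_DAY, ObservedDataset
from .model import IMMUNE_VARS, STATE_VARS

__all__ = [
    "STAGES",
    "STAGE_WEEKS",
    "CellSizeTable",
    "StageAnchors",
    "truncate_sig",
    "truncate_decimals",
    "caliper_volume",
    "diameter_from_caliper_volume",
    "stage_count",
    "stage_estimate",
    "mouse_anchor",
    "immune_counts_from_fractions",
    "nonimmune_counts",
    "o2_ppm_to_molar",
    "nondimensionalize",
    "assemble_dataset",
]

STAGES: tuple[str, ...] = (
    "hyperplasia", "adenoma", "early_carcinoma", "late_carcinoma",
)
STAGE_WEEKS: dict[str, int] = {
    "hyperplasia": 6, "adenoma": 8, "early_carcinoma": 10, "late_carcinoma": 12,
}

#: Characteristic cell lengths in micrometres (midpoints of reported ranges).
#: Stromal/fibroblast populations are folded into the adipocyte compartment
#: at 20 um, the intersection of the adipocyte and fibroblast sizes.
DEFAULT_CELL_LENGTHS_UM: dict[str, float] = {
    "dendritic": 12.5,
    "macrophage": 21.0,
    "granulocyte_monocyte": 14.0,
    "lymphocyte": 12.5,
    "stem": 12.0,
    "endothelial": 20.0,
    "luminal_epithelial": 30.0,
    "cancer": 12.0,
    "adipose_stem": 28.0,
    "stromal": 20.0,
    "adipocyte": 20.0,
}

#: Model compartment -> cell-size class.
VAR_CELL_CLASS: dict[str, str] = {
    "TN": "lymphocyte", "Th": "lymphocyte", "Tc": "lymphocyte",
    "Tr": "lymphocyte",
    "DN": "dendritic", "D": "dendritic",
    "MN": "macrophage", "M": "macrophage",
    "C": "cancer", "N": "cancer",
    "A": "adipocyte", "EN": "endothelial",
}

NONIMMUNE_VARS: tuple[str, ...] = ("A", "EN")


@dataclass(frozen=True)
class CellSizeTable:
    """Characteristic lengths (um) and caliper volumes (um^3, ``L^3/2``)."""

    lengths_um: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELL_LENGTHS_UM)
    )

    def __post_init__(self):
        for k, v in self.lengths_um.items():
            if v <= 0:
                raise ValueError(f"non-positive cell length for {k!r}")

    def length(self, cell_class: str) -> float:
        return float(self.lengths_um[cell_class])

    def volume_um3(self, cell_class: str) -> float:
        """Single-cell caliper volume ``L^3 / 2``."""
        L = self.length(cell_class)
        return L ** 3 / 2.0

    def var_volume_um3(self, var: str) -> float:
        return self.volume_um3(VAR_CELL_CLASS[var])


@dataclass(frozen=True)
class StageAnchors:
    """Stage caliper volumes (mm^3) and per-gram reference yields (cells/g)."""

    volumes_mm3: Mapping[str, float] = field(
        default_factory=lambda: {
            "hyperplasia": 200.0,
            "adenoma": 400.0,
            "early_carcinoma": 700.0,
            "late_carcinoma": 1400.0,
        }
    )
    cancer_yield: tuple[float, float] = (4.5e7, 0.9e7)  # (mean, sd)
    tam_yield: tuple[float, float] = (2.2e6, 0.6e6)

    def __post_init__(self):
        vols = [self.volumes_mm3[s] for s in STAGES]
        if any(b <= a for a, b in zip(vols, vols[1:])):
            raise ValueError("stage volumes must be strictly increasing")

    def diameter_mm(self, stage: str) -> float:
        return diameter_from_caliper_volume(self.volumes_mm3[stage])


# ---------------------------------------------------------------------------
# elementary arithmetic
# ---------------------------------------------------------------------------

def truncate_decimals(x: float, nd: int) -> float:
    """Truncate (floor towards zero) to ``nd`` decimal places.

    A tiny pre-round guards against representation error: a value that is an
    exact decimal up to floating-point noise (e.g. 9.999999999999998 for 10)
    truncates to that decimal, not one ulp below it.
    """
    f = 10.0 ** nd
    return math.trunc(round(x * f, 6)) / f


def truncate_sig(x: float, sig: int = 3) -> float:
    """Truncate towards zero to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    e = math.floor(math.log10(abs(x)))
    f = 10.0 ** (e - sig + 1)
    return math.trunc(round(x / f, 6)) * f


def caliper_volume(L: float, W: float) -> float:
    """Caliper tumour volume ``L x W^2 / 2`` (mm^3)."""
    if L <= 0 or W <= 0:
        raise ValueError("caliper dimensions must be positive")
    return L * W * W / 2.0


def diameter_from_caliper_volume(V: float) -> float:
    """Equivalent diameter ``(2V)^(1/3)`` (mm), truncated to 2 decimals.

    Assumes the long and short caliper diameters are roughly equal, so
    ``V = L^3 / 2``.
    """
    if V <= 0:
        raise ValueError("volume must be positive")
    return truncate_decimals((2.0 * V) ** (1.0 / 3.0), 2)


def stage_count(yield_per_gram: float, d_stage: float) -> float:
    """Absolute cell count at a stage: ``(yield/2) * (d/10)``, truncated to 3 s.f.

    Half the per-gram yield corresponds to one reference tumour of 10 mm
    diameter; the count scales linearly with the stage diameter.
    """
    if yield_per_gram < 0 or d_stage <= 0:
        raise ValueError("yield must be non-negative and diameter positive")
    return truncate_sig(yield_per_gram / 2.0 * d_stage / 10.0, 3)


def stage_estimate(
    mean_yield: float, sd_yield: float, d_stage: float
) -> tuple[float, float]:
    """Stage (mean, sd) cell estimate.

    The mean is truncated to three significant figures; the sd is truncated on
    the mean's last-digit grid (e.g. a mean of 1.02e6 reported to 0.01e6 gives
    an sd of 0.2784e6 -> 0.27e6), matching how the per-mouse anchor columns
    are constructed.
    """
    mean = stage_count(mean_yield, d_stage)
    raw_sd = sd_yield / 2.0 * d_stage / 10.0
    if mean == 0:
        return 0.0, truncate_sig(raw_sd, 3)
    grid = 10.0 ** (math.floor(math.log10(mean)) - 2)
    return mean, math.trunc(raw_sd / grid) * grid


def mouse_anchor(mean: float, sd: float, mouse_id: int) -> float:
    """Per-mouse anchor ``mean + k*sd`` with ``k = -1, 0, +1`` for mice 1-3."""
    if mouse_id not in (1, 2, 3):
        raise ValueError("mouse_id must be 1, 2 or 3")
    if not mean > sd >= 0:
        raise ValueError("require mean > sd >= 0")
    return mean + (mouse_id - 2) * sd


# ---------------------------------------------------------------------------
# fractions -> counts
# ---------------------------------------------------------------------------

def immune_counts_from_fractions(
    fracs: Mapping[str, float], tam_total: float
) -> dict[str, float]:
    """Scale immune fractions so the macrophage compartments sum to ``tam_total``.

    ``fracs`` maps immune compartment names (subset of the eight immune
    variables) to panel fractions. The scale factor is
    ``tam_total / (f_MN + f_M)``.
    """
    mac_frac = fracs.get("MN", 0.0) + fracs.get("M", 0.0)
    if mac_frac <= 0:
        raise ValueError("macrophage fraction must be positive to anchor counts")
    if tam_total < 0:
        raise ValueError("TAM total must be non-negative")
    s = tam_total / mac_frac
    return {v: s * fracs.get(v, 0.0) for v in IMMUNE_VARS}


def nonimmune_counts(
    total_volume_mm3: float,
    immune_counts: Mapping[str, float],
    cancer_count: float,
    sizes: CellSizeTable,
    nonimmune_fracs: Mapping[str, float],
) -> dict[str, float]:
    """Fill the residual tumour volume with adipocytes and endothelial cells.

    The residual volume (total minus immune minus cancer; necrotic cells are
    excluded from the budget because the reported volumes exclude them) is
    distributed across the non-immune types proportionally to their panel
    fractions: ``N_j = f_j * R / sum_j' f_j' * V_j'``, the unique non-negative
    solution of the volume-budget equation with fixed relative proportions.
    """
    total_um3 = total_volume_mm3 * 1e9
    used = cancer_count * sizes.var_volume_um3("C")
    used += sum(
        immune_counts.get(v, 0.0) * sizes.var_volume_um3(v) for v in IMMUNE_VARS
    )
    residual = total_um3 - used
    if residual < 0:
        raise ValueError(
            f"immune + cancer volume exceeds tumour volume by "
            f"{-residual:.3g} um^3"
        )
    denom = sum(
        nonimmune_fracs.get(v, 0.0) * sizes.var_volume_um3(v)
        for v in NONIMMUNE_VARS
    )
    if denom == 0:
        if residual == 0:
            return {v: 0.0 for v in NONIMMUNE_VARS}
        raise ValueError("zero non-immune fractions with positive residual volume")
    return {
        v: nonimmune_fracs.get(v, 0.0) * residual / denom for v in NONIMMUNE_VARS
    }


def o2_ppm_to_molar(ppm: float, *, molar_mass: float = 16.0) -> float:
    """Convert oxygen ppm (read as mg per litre of tissue water) to mol/l.

    The default molar mass of 16 g/mol treats the measurement atomically;
    pass ``molar_mass=32`` for molecular O2.
    """
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    return (ppm / 1000.0) / molar_mass


# ---------------------------------------------------------------------------
# non-dimensionalization
# ---------------------------------------------------------------------------

def nondimensionalize(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Divide each variable by its maximum across all mice and stages.

    Returns the scaled table and a scale registry ``{var: max}`` for
    back-conversion; time columns are never touched. Raises on an all-zero
    variable (its scale would be degenerate).
    """
    cols = columns if columns is not None else [
        c for c in table.columns if c in STATE_VARS
    ]
    out = table.copy()
    scales: dict[str, float] = {}
    for c in cols:
        mx = float(table[c].max())
        if mx <= 0:
            raise ValueError(f"variable {c!r} has no positive entry; cannot scale")
        scales[c] = mx
        out[c] = table[c] / mx
    return out, scales


# ---------------------------------------------------------------------------
# end-to-end assembly
# ---------------------------------------------------------------------------

def assemble_dataset(
    fractions: pd.DataFrame,
    cytokines: pd.DataFrame,
    sizes: CellSizeTable | None = None,
    anchors: StageAnchors | None = None,
    *,
    o2_molar_mass: float = 16.0,
    return_counts: bool = False,
    nondim: bool = True,
):
    """Build a non-dimensional :class:`ObservedDataset` from raw tables.

    Parameters
    ----------
    fractions
        Tidy table with columns ``mouse, stage, cell_type, fraction``. Immune
        rows (the eight immune compartments) must sum to 1 per mouse/stage
        within the immune panel; non-immune rows (``A``, ``EN``) within the
        non-immune panel.
    cytokines
        Table with columns ``mouse, stage, H, IL12, IL10, IL6, V, Ox_ppm``.
    sizes, anchors
        Cell-size table and stage anchors; defaults reproduce the reference
        mouse study.
    o2_molar_mass
        Molar mass used for the ppm -> mol/l conversion (16 by convention).
    return_counts
        Also return the absolute-count table (shaped like the per-mouse
        cell-count reference table).

    Per mouse and stage: cancer and TAM counts come from the stage/mouse
    anchor rule; immune counts from the fractions anchored on the TAM total;
    necrotic cells are exactly half the cancer cells; adipocytes and
    endothelial cells fill the residual volume; cytokines pass through and
    oxygen is converted to mol/l. Everything is then scaled by its maximum
    across mice and stages.
    """
    sizes = sizes or CellSizeTable()
    anchors = anchors or StageAnchors()

    mice = sorted(cytokines["mouse"].unique())
    records = []
    for mouse in mice:
        for stage in STAGES:
            week = STAGE_WEEKS[stage]
            d = anchors.diameter_mm(stage)
            c_mean, c_sd = stage_estimate(*anchors.cancer_yield, d)
            t_mean, t_sd = stage_estimate(*anchors.tam_yield, d)
            C = mouse_anchor(c_mean, c_sd, int(mouse))
            tam_total = mouse_anchor(t_mean, t_sd, int(mouse))

            sel = fractions[
                (fractions["mouse"] == mouse) & (fractions["stage"] == stage)
            ]
            ifr = {
                r.cell_type: r.fraction
                for r in sel.itertuples()
                if r.cell_type in IMMUNE_VARS
            }
            nfr = {
                r.cell_type: r.fraction
                for r in sel.itertuples()
                if r.cell_type in NONIMMUNE_VARS
            }
            _check_panel(ifr, f"immune panel mouse {mouse} {stage}")
            _check_panel(nfr, f"non-immune panel mouse {mouse} {stage}")

            immune = immune_counts_from_fractions(ifr, tam_total)
            nonimm = nonimmune_counts(
                anchors.volumes_mm3[stage], immune, C, sizes, nfr
            )

            cyt = cytokines[
                (cytokines["mouse"] == mouse) & (cytokines["stage"] == stage)
            ]
            if len(cyt) != 1:
                raise ValueError(
                    f"expected one cytokine row for mouse {mouse} {stage}"
                )
            cyt = cyt.iloc[0]

            rec = {
                "mouse": int(mouse), "stage": stage, "week": week,
                "t_days": WEEK_TO_DAY[week],
                "C": C, "N": C / 2.0, **immune, **nonimm,
                "H": float(cyt["H"]), "IL12": float(cyt["IL12"]),
                "IL10": float(cyt["IL10"]), "IL6": float(cyt["IL6"]),
                "V": float(cyt["V"]),
                "Ox": o2_ppm_to_molar(
                    float(cyt["Ox_ppm"]), molar_mass=o2_molar_mass
                ),
            }
            records.append(rec)

    counts = pd.DataFrame(records)
    if not nondim:
        # counts-only mode, for inspection of degenerate panels whose
        # all-zero variables cannot be max-scaled
        return counts
    scaled, scales = nondimensionalize(counts)

    values = {}
    for mouse in mice:
        grp = scaled[scaled["mouse"] == mouse].sort_values("t_days")
        values[int(mouse)] = grp[list(STATE_VARS)].to_numpy(dtype=float)
    ds = ObservedDataset(
        np.array(sorted(WEEK_TO_DAY.values())), values, scales=scales
    )
    if return_counts:
        return ds, counts
    return ds


def _check_panel(fracs: Mapping[str, float], label: str, tol: float = 1e-6):
    total = sum(fracs.values())
    if fracs and abs(total - 1.0) > tol:
        raise ValueError(f"{label}: fractions sum to {total}, expected 1")
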