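"""Bundled per-mouse cell-count and cytokine tables for three MMTV-PyMT mice.

The cell counts are derived quantities (deconvolved fractions anchored on
dissociation-yield estimates; see :mod:`tmekin.dataprep`), sampled at weeks
6, 8, 10 and 12 of tumour progression. Cytokine entries are gene-expression
levels and oxygen is in mol/l. ``load_counts`` returns the absolute tables;
``load_dataset`` the max-scaled :class:`~tmekin.dataset.ObservedDataset`
ready for fitting (week 6 maps to t = 0 days).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import WEEK_TO_DAY, ObservedDataset
from .dataprep import nondimensionalize
from .model import STATE_VARS

__all__ = ["load_counts", "load_cytokines", "load_dataset"]

_COUNT_COLS = ("TN", "Th", "Tc", "Tr", "DN", "D", "MN", "M", "C", "N", "A", "EN")

# mouse, week, then the 12 cell compartments
_COUNTS = [
    (1, 6, 1382527, 663086, 228615, 92289, 1227231, 886534, 389295, 397821, 13200000, 6600000, 416120, 915268),
    (1, 8, 1615524, 641814, 265967, 176412, 1574935, 1057404, 577007, 710944, 16700000, 8350000, 1582762, 916916),
    (1, 10, 2569211, 689479, 310204, 292578, 1636578, 1328095, 612205, 942441, 20100000, 10050000, 2763480, 769340),
    (1, 12, 2199247, 937204, 222401, 147089, 2324486, 1686078, 787834, 1171025, 25400000, 12700000, 5222452, 3028739),
    (2, 6, 1441964, 529513, 128158, 79395, 1115894, 934727, 450621, 358170, 16500000, 8250000, 461103, 493492),
    (2, 8, 1545885, 583058, 589238, 407590, 1152659, 1411717, 292503, 455659, 20800000, 10400000, 1080624, 185467),
    (2, 10, 1311444, 478978, 183104, 69789, 1243110, 859137, 430970, 458725, 30100000, 15050000, 2464786, 931836),
    (2, 12, 2297591, 426244, 127776, 181325, 1396820, 1057303, 559029, 562339, 31700000, 15850000, 5578533, 1469427),
    (3, 6, 1399198, 430269, 405214, 79316, 1021227, 924575, 395039, 435495, 19800000, 9900000, 333365, 366687),
    (3, 8, 1467427, 507931, 395476, 81323, 1268459, 836283, 439574, 575209, 24900000, 12450000, 1514664, 785294),
    (3, 10, 2161705, 340691, 272777, 188039, 1232740, 1346494, 554893, 664238, 25100000, 12550000, 2885384, 1196948),
    (3, 12, 3171264, 963737, 381975, 162666, 1909543, 1177989, 658718, 884036, 38000000, 19000000, 5437350, 2937968),
]

_CYTO_COLS = ("H", "IL12", "IL10", "IL6", "V", "Ox")

# mouse, week, H, IL12, IL10, IL6, V (expression units), Ox (mol/l)
_CYTOKINES = [
    (1, 6, 1000, 63, 417, 384, 776, 3.125),
    (1, 8, 940, 41, 351, 197, 536, 0.625),
    (1, 10, 1103, 3, 404, 184, 494, 0.0625),
    (1, 12, 1050, 2, 455, 193, 798, 0.000625),
    (2, 6, 1182, 0, 450, 196, 775, 3.125),
    (2, 8, 932, 16, 723, 35, 721, 0.625),
    (2, 10, 945, 0, 429, 162, 313, 0.0625),
    (2, 12, 807, 4, 319, 127, 384, 0.000625),
    (3, 6, 1521, 27, 511, 336, 1081, 3.125),
    (3, 8, 1549, 22, 566, 312, 1054, 0.625),
    (3, 10, 957, 3, 349, 229, 565, 0.0625),
    (3, 12, 779, 10, 278, 163, 909, 0.000625),
]


def load_counts() -> pd.DataFrame:
    """Absolute cell counts per mouse and week (12 compartments)."""
    return pd.DataFrame(_COUNTS, columns=("mouse", "week", *_COUNT_COLS))


def load_cytokines() -> pd.DataFrame:
    """Cytokine expression levels and oxygen concentration per mouse/week."""
    return pd.DataFrame(_CYTOKINES, columns=("mouse", "week", *_CYTO_COLS))


def load_dataset() -> ObservedDataset:
    """Max-scaled 18-variable dataset for the three mice at t = 0/14/28/42 d."""
    wide = load_counts().merge(load_cytokines(), on=("mouse", "week"))
    wide["t_days"] = wide["week"].map({w: d for w, d in WEEK_TO_DAY.items()})
    scaled, scales = nondimensionalize(wide)
    values = {
        int(m): grp.sort_values("t_days")[list(STATE_VARS)].to_numpy(dtype=float)
        for m, grp in scaled.groupby("mouse")
    }
    return ObservedDataset(
        np.array(sorted(WEEK_TO_DAY.values())), values, scales=scales
    )
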