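"""Independent computer-algebra transcription of the 18-equation system.

Built directly from the published equation table with sympy, term by term,
without reference to the package's numerical right-hand side. Serves as the
oracle the implementation is checked against.
"""

from __future__ import annotations

import numpy as np
import sympy as sp

STATE_ORDER = (
    "EN", "V", "Ox", "TN", "Th", "Tc", "Tr", "DN", "D",
    "MN", "M", "C", "N", "A", "H", "IL12", "IL10", "IL6",
)

PARAM_ORDER = (
    "lambda_VEN", "delta_ENIL12", "delta_EN", "delta_ENOx",
    "lambda_VA", "lambda_VM", "lambda_VCOx", "lambda_VOx", "delta_V",
    "lambda_OxEN", "delta_1", "delta_2", "delta_3", "delta_4", "delta_5",
    "delta_6", "delta_Ox",
    "A_TN", "delta_TN", "delta_TNOx",
    "lambda_ThH", "lambda_ThD", "lambda_ThIL12",
    "delta_ThTr", "delta_ThIL10", "delta_Th", "delta_ThOx",
    "lambda_TcD", "lambda_TcIL12",
    "delta_TcTr", "delta_TcIL10", "delta_Tc", "delta_TcOx",
    "lambda_TrD", "lambda_TrOx", "delta_Tr", "delta_TrOx",
    "A_DN", "lambda_DC", "lambda_DH", "lambda_DOx", "delta_DN", "delta_DNOx",
    "delta_DC", "delta_D",
    "A_MN", "lambda_MIL10", "lambda_MIL12", "lambda_MTh", "delta_MN",
    "delta_M",
    "lambda_C", "lambda_CIL6", "lambda_CA",
    "delta_CTc", "delta_CTcOx", "delta_COx", "delta_C",
    "alpha_NC", "delta_N",
    "lambda_A", "delta_A",
    "lambda_HD", "lambda_HN", "lambda_HM", "lambda_HTc", "lambda_HC",
    "delta_H",
    "lambda_IL12M", "lambda_IL12D", "delta_IL12",
    "lambda_IL10M", "lambda_IL10D", "lambda_IL10Tr", "lambda_IL10Th",
    "lambda_IL10Tc", "lambda_IL10C", "lambda_IL10Ox", "delta_IL10",
    "lambda_IL6A", "lambda_IL6M", "lambda_IL6MOx", "lambda_IL6D",
    "lambda_IL6Ox", "delta_IL6",
    "EN0", "C0", "A0",
)


def build_oracle():
    """Return ``f(state, params, ox_crit1, ox_crit2, m) -> 18 derivatives``."""
    s = {nm: sp.Symbol(nm) for nm in STATE_ORDER}
    p = {nm: sp.Symbol("p_" + nm) for nm in PARAM_ORDER}
    oc1, oc2, m = sp.symbols("oc1 oc2 m_exp")

    EN, V, Ox, TN, Th, Tc, Tr, DN, D, MN, M, C, N, A, H, IL12, IL10, IL6 = (
        s[nm] for nm in STATE_ORDER
    )
    f1 = oc1**m / (oc1**m + Ox**m)
    f2 = oc2**m / (oc2**m + Ox**m)

    eqs = {
        "EN": (
            p["lambda_VEN"] * V * (1 - EN / p["EN0"]) * EN
            - p["delta_ENIL12"] * IL12 * EN
            - (p["delta_EN"] + p["delta_ENOx"] * f2) * EN
        ),
        "V": (
            p["lambda_VA"] * A + p["lambda_VM"] * M
            + p["lambda_VCOx"] * C * f1 + p["lambda_VOx"] * f1
            - p["delta_V"] * V
        ),
        "Ox": (
            p["lambda_OxEN"] * EN
            - p["delta_1"] * (TN + Th + Tc + Tr) * Ox
            - p["delta_2"] * (DN + D) * Ox
            - p["delta_3"] * (MN + M) * Ox
            - p["delta_4"] * C * Ox
            - p["delta_5"] * A * Ox
            - p["delta_6"] * EN * Ox
            - p["delta_Ox"] * Ox
        ),
        "TN": (
            p["A_TN"]
            - (p["lambda_ThH"] * H + p["lambda_ThD"] * D
               + p["lambda_ThIL12"] * IL12) * TN
            - (p["lambda_TcD"] * D + p["lambda_TcIL12"] * IL12) * TN
            - (p["lambda_TrD"] * D + p["lambda_TrOx"] * f1) * TN
            - (p["delta_TN"] + p["delta_TNOx"] * f2) * TN
        ),
        "Th": (
            (p["lambda_ThH"] * H + p["lambda_ThD"] * D
             + p["lambda_ThIL12"] * IL12) * TN
            - (p["delta_ThTr"] * Tr + p["delta_ThIL10"] * IL10) * Th
            - (p["delta_Th"] + p["delta_ThOx"] * f2) * Th
        ),
        "Tc": (
            (p["lambda_TcD"] * D + p["lambda_TcIL12"] * IL12) * TN
            - (p["delta_TcTr"] * Tr + p["delta_TcIL10"] * IL10) * Tc
            - (p["delta_Tc"] + p["delta_TcOx"] * f2) * Tc
        ),
        "Tr": (
            (p["lambda_TrD"] * D + p["lambda_TrOx"] * f1) * TN
            - (p["delta_Tr"] + p["delta_TrOx"] * f2) * Tr
        ),
        "DN": (
            p["A_DN"]
            - (p["lambda_DC"] * C + p["lambda_DH"] * H
               + p["lambda_DOx"] * f1) * DN
            - (p["delta_DN"] + p["delta_DNOx"] * f2) * DN
        ),
        "D": (
            (p["lambda_DC"] * C + p["lambda_DH"] * H
             + p["lambda_DOx"] * f1) * DN
            - (p["delta_DC"] * C + p["delta_D"] + p["delta_DNOx"] * f2) * D
        ),
        "MN": (
            p["A_MN"]
            - (p["lambda_MIL10"] * IL10 + p["lambda_MIL12"] * IL12
               + p["lambda_MTh"] * Th + p["delta_MN"]) * MN
        ),
        "M": (
            (p["lambda_MIL10"] * IL10 + p["lambda_MIL12"] * IL12
             + p["lambda_MTh"] * Th) * MN
            - p["delta_M"] * M
        ),
        "C": (
            (p["lambda_C"] + p["lambda_CIL6"] * IL6 + p["lambda_CA"] * A)
            * (1 - C / p["C0"]) * C
            - (p["delta_CTc"] * Tc + p["delta_CTcOx"] * f1 * Tc) * C
            - (p["delta_COx"] * f2 + p["delta_C"]) * C
        ),
        "N": (
            p["alpha_NC"]
            * (p["delta_CTc"] * Tc + p["delta_CTcOx"] * f1 * Tc
               + p["delta_COx"] * f2 + p["delta_C"]) * C
            - p["delta_N"] * N
        ),
        "A": p["lambda_A"] * (1 - A / p["A0"]) * A - p["delta_A"] * A,
        "H": (
            p["lambda_HD"] * D + p["lambda_HN"] * N + p["lambda_HM"] * M
            + p["lambda_HTc"] * Tc + p["lambda_HC"] * C
            - p["delta_H"] * H
        ),
        "IL12": (
            p["lambda_IL12M"] * M + p["lambda_IL12D"] * D
            - p["delta_IL12"] * IL12
        ),
        "IL10": (
            p["lambda_IL10M"] * M + p["lambda_IL10D"] * D
            + p["lambda_IL10Tr"] * Tr + p["lambda_IL10Th"] * Th
            + p["lambda_IL10Tc"] * Tc + p["lambda_IL10C"] * C
            + p["lambda_IL10Ox"] * f1
            - p["delta_IL10"] * IL10
        ),
        "IL6": (
            p["lambda_IL6A"] * A + p["lambda_IL6M"] * M
            + p["lambda_IL6MOx"] * M * f1 + p["lambda_IL6D"] * D
            + p["lambda_IL6Ox"] * f1
            - p["delta_IL6"] * IL6
        ),
    }

    args = (
        [s[nm] for nm in STATE_ORDER]
        + [p[nm] for nm in PARAM_ORDER]
        + [oc1, oc2, m]
    )
    funcs = [sp.lambdify(args, eqs[nm], "numpy") for nm in STATE_ORDER]

    def evaluate(state, params, ox_crit1, ox_crit2, m_exp):
        vals = list(state) + [params[nm] for nm in PARAM_ORDER] + [
            ox_crit1, ox_crit2, m_exp,
        ]
        return np.array([f(*vals) for f in funcs])

    return evaluate
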