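"""PCGSA: finite-difference Jacobians, SVD structure, rankings, perturbations."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import tmekin as tk
from tmekin.model import STATE_VARS
from tmekin.sensitivity import (
    Decomposition,
    SensitivityMatrix,
    pc_decompose,
    perturbation_experiment,
    scalar_sensitivity,
    sensitivity_matrix,
    singular_spectrum,
    variable_heatmap,
)
from tmekin.synth import RECOVERY_TRUTH, RECOVERY_X0


@pytest.fixture(scope="module")
def sub_params():
    return tk.ParameterSet.from_partial(RECOVERY_TRUTH)


@pytest.fixture(scope="module")
def hyp_mod():
    return tk.HypoxiaParams()


T_GRID = np.linspace(0.0, 42.0, 7)


# ---------------------------------------------------------------------------
# finite-difference Jacobian
# ---------------------------------------------------------------------------

def test_linear_decay_sensitivity_closed_form(hyp_mod):
    """For dV/dt = -k V the parameter derivative is -t V(t)."""
    k, v0 = 0.3, 0.8
    p = tk.ParameterSet.from_partial({"delta_V": k})
    x0 = np.zeros(18)
    x0[STATE_VARS.index("V")] = v0
    M = sensitivity_matrix(
        p, hyp_mod, x0, T_GRID, outputs=("V",), param_names=("delta_V",)
    )
    expected = -T_GRID * v0 * np.exp(-k * T_GRID)
    np.testing.assert_allclose(M.matrix[:, 0], expected, atol=1e-6)


def test_fd_matches_forward_sensitivity_ode(hyp_mod):
    """Adipocyte-logistic + IL-6 subsystem: central differences agree with
    the augmented forward-sensitivity ODE solved independently."""
    lam_A, A0, lam_I, del_I = 0.15, 0.8, 0.5, 0.4
    p = tk.ParameterSet.from_partial({
        "lambda_A": lam_A, "A0": A0, "lambda_IL6A": lam_I, "delta_IL6": del_I,
    })
    x0 = np.zeros(18)
    x0[STATE_VARS.index("A")] = 0.1
    x0[STATE_VARS.index("IL6")] = 0.05

    # forward sensitivities s = d(A, IL6)/d lambda_A
    def aug(t, z):
        A, I, sA, sI = z
        dA = lam_A * (1 - A / A0) * A
        dI = lam_I * A - del_I * I
        dsA = (1 - A / A0) * A + lam_A * (1 - 2 * A / A0) * sA
        dsI = lam_I * sA - del_I * sI
        return [dA, dI, dsA, dsI]

    sol = solve_ivp(aug, (0, 42), [0.1, 0.05, 0.0, 0.0], t_eval=T_GRID,
                    rtol=1e-10, atol=1e-12)
    M = sensitivity_matrix(
        p, hyp_mod, x0, T_GRID, outputs=("A", "IL6"),
        param_names=("lambda_A",),
    )
    n = T_GRID.size
    np.testing.assert_allclose(M.matrix[:n, 0], sol.y[2], atol=1e-5)
    np.testing.assert_allclose(M.matrix[n:, 0], sol.y[3], atol=1e-5)


def test_inactive_parameter_gives_zero_column(sub_params, hyp_mod):
    """A rate multiplying a compartment that never leaves zero has exactly
    zero sensitivity."""
    M = sensitivity_matrix(
        sub_params, hyp_mod, RECOVERY_X0, T_GRID,
        outputs=STATE_VARS, param_names=("delta_Tr", "lambda_A"),
    )
    np.testing.assert_allclose(M.matrix[:, 0], 0.0, atol=1e-12)
    assert np.abs(M.matrix[:, 1]).max() > 0


def test_scaled_mode_multiplies_columns_by_parameter(sub_params, hyp_mod):
    names = ("lambda_A", "delta_IL6")
    raw = sensitivity_matrix(sub_params, hyp_mod, RECOVERY_X0, T_GRID,
                             outputs=("A", "IL6"), param_names=names)
    scaled = sensitivity_matrix(sub_params, hyp_mod, RECOVERY_X0, T_GRID,
                                outputs=("A", "IL6"), param_names=names,
                                scaling="scaled")
    for j, nm in enumerate(names):
        np.testing.assert_allclose(
            scaled.matrix[:, j], raw.matrix[:, j] * sub_params[nm], rtol=1e-9
        )


# ---------------------------------------------------------------------------
# SVD structure
# ---------------------------------------------------------------------------

def _toy_matrix(mat, n_outputs=1):
    n_t = mat.shape[0] // n_outputs
    return SensitivityMatrix(
        mat, np.arange(n_t, dtype=float),
        tuple(f"C" for _ in range(n_outputs)),
        tuple(f"p{j}" for j in range(mat.shape[1])),
    )


def test_rank_one_matrix_single_singular_value(rng):
    u = rng.normal(size=12)
    v = rng.normal(size=4)
    dec = pc_decompose(_toy_matrix(np.outer(u, v)))
    assert dec.sigma[0] > 1e-10
    np.testing.assert_allclose(dec.sigma[1:], 0.0, atol=1e-10)


def test_svd_reconstruction_and_orthonormality(rng):
    mat = rng.normal(size=(30, 8))
    dec = pc_decompose(_toy_matrix(mat))
    recon = dec.U @ np.diag(dec.sigma) @ dec.V.T
    assert np.linalg.norm(recon - mat) < 1e-10 * np.linalg.norm(mat)
    np.testing.assert_allclose(dec.U.T @ dec.U, np.eye(8), atol=1e-10)
    np.testing.assert_allclose(dec.V.T @ dec.V, np.eye(8), atol=1e-10)
    # S_ij = sigma_i V_ji
    np.testing.assert_allclose(dec.S, dec.sigma[:, None] * dec.V.T, rtol=1e-12)


def test_linearisation_matches_direct_perturbation(sub_params, hyp_mod):
    """M dk reproduces the trajectory change with relative error vanishing
    as the perturbation shrinks."""
    names = tuple(RECOVERY_TRUTH)
    outputs = ("A", "C", "IL6", "H")
    M = sensitivity_matrix(
        sub_params, hyp_mod, RECOVERY_X0, T_GRID,
        outputs=outputs, param_names=names,
    )
    rng = np.random.default_rng(8)
    direction = rng.normal(size=len(names))
    direction /= np.linalg.norm(direction)

    def direct(dk):
        vals = sub_params.to_dict()
        for nm, d in zip(names, dk):
            vals[nm] = max(vals[nm] + d, 0.0)
        traj = tk.simulate(tk.ParameterSet(vals), hyp_mod, RECOVERY_X0, T_GRID)
        base = tk.simulate(sub_params, hyp_mod, RECOVERY_X0, T_GRID)
        rows = [traj[o] - base[o] for o in outputs]
        return np.concatenate(rows)

    errs = []
    for mag in (1e-1, 1e-2, 1e-3):
        dk = mag * direction
        dX = direct(dk)
        pred = M.matrix @ dk
        errs.append(np.linalg.norm(pred - dX) / np.linalg.norm(dX))
    # first-order truncation: the relative error shrinks roughly linearly
    # with the perturbation magnitude
    assert errs[1] < 0.3 * errs[0]
    assert errs[2] < 0.3 * errs[1]
    assert errs[2] < 5e-3


# ---------------------------------------------------------------------------
# spectrum and heatmap
# ---------------------------------------------------------------------------

def _dec_from_sigma(sigma):
    n = len(sigma)
    mat = np.diag(sigma)
    return pc_decompose(_toy_matrix(np.asarray(mat, dtype=float)))


def test_singular_spectrum_counts():
    assert singular_spectrum(_dec_from_sigma([1.0, 0.5, 0.19]), 0.2) == 2
    assert singular_spectrum(_dec_from_sigma([1.0]), 0.5) == 1


def test_singular_spectrum_monotone_in_cutoff():
    dec = _dec_from_sigma([1.0, 0.7, 0.4, 0.15, 0.03])
    counts = [singular_spectrum(dec, c) for c in (0.8, 0.5, 0.3, 0.1, 0.01)]
    assert counts == sorted(counts)


def test_singular_spectrum_validates_cutoff():
    dec = _dec_from_sigma([1.0, 0.5])
    for bad in (0.0, 1.0, -0.2):
        with pytest.raises(ValueError):
            singular_spectrum(dec, bad)
    with pytest.raises(ValueError):
        singular_spectrum(_dec_from_sigma([0.0, 0.0]), 0.2)


def test_heatmap_dominant_variable_and_threshold_one(rng):
    # two outputs x 5 times; PC1 loads only on the first output block
    n_t = 5
    mat = np.zeros((2 * n_t, 3))
    mat[:n_t, 0] = [5.0, 4.0, 3.0, 2.0, 1.0]   # output block 'X'
    mat[n_t:, 1] = 0.5   # output block 'Y', far below threshold * max
    sm = SensitivityMatrix(
        mat, np.arange(n_t, dtype=float), ("X", "Y"), ("p0", "p1", "p2")
    )
    dec = pc_decompose(sm)
    heat = variable_heatmap(dec, threshold=0.2, n_components=2)
    assert {e["variable"] for e in heat[0]} == {"X"}
    # threshold 1.0 keeps only the single global-max entry
    heat_top = variable_heatmap(dec, threshold=1.0, n_components=2)
    entries = [e for pc in heat_top for e in pc]
    assert len(entries) == 1
    assert entries[0]["variable"] == "X"
    assert entries[0]["time"] == 0.0
    assert entries[0]["magnitude"] == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# scalar sensitivities and perturbation experiments
# ---------------------------------------------------------------------------

def test_cancer_growth_rate_has_positive_cancer_sensitivity(sub_params, hyp_mod):
    out = scalar_sensitivity(
        "cancer", sub_params, hyp_mod, RECOVERY_X0, T_GRID,
        param_names=tuple(RECOVERY_TRUTH),
    )
    assert out["sensitivities"]["lambda_C"] > 0


def test_inactive_parameter_excluded_from_top(sub_params, hyp_mod):
    out = scalar_sensitivity(
        "cancer", sub_params, hyp_mod, RECOVERY_X0, T_GRID,
        param_names=("lambda_C", "delta_Tr"),
    )
    assert out["sensitivities"]["delta_Tr"] == 0.0
    assert [nm for nm, _ in out["top"]] == ["lambda_C"]


def test_scalar_sensitivity_signs_agree_with_direct_perturbation(sub_params, hyp_mod):
    """For each reported top parameter, the sign matches the integrated
    output change under a +10% perturbation."""
    out = scalar_sensitivity(
        "cancer", sub_params, hyp_mod, RECOVERY_X0, T_GRID,
        param_names=tuple(RECOVERY_TRUTH),
    )
    base = tk.simulate(sub_params, hyp_mod, RECOVERY_X0, T_GRID)
    base_c = tk.observables(base)["cancer"]
    # only cancer-coupled parameters carry real signal; the rest sit at
    # finite-difference noise level and carry no meaningful sign
    floor = 1e-4 * max(abs(s) for _, s in out["top"])
    checked = 0
    for nm, s in out["top"]:
        if abs(s) < floor:
            continue
        pert = sub_params.replace(**{nm: sub_params[nm] * 1.1})
        traj = tk.simulate(pert, hyp_mod, RECOVERY_X0, T_GRID)
        diff = float(np.trapezoid(tk.observables(traj)["cancer"] - base_c, T_GRID))
        assert np.sign(diff) == np.sign(s), nm
        checked += 1
    assert checked >= 2  # lambda_C and C0 at least


def test_scalar_sensitivity_validates_output(sub_params, hyp_mod):
    with pytest.raises(ValueError):
        scalar_sensitivity("EN", sub_params, hyp_mod, RECOVERY_X0, T_GRID)


@pytest.fixture(scope="module")
def angio_params():
    """Subsystem with active endothelial/VEGF couplings for perturbations."""
    vals = dict(RECOVERY_TRUTH)
    vals.update({
        "lambda_VEN": 0.5, "EN0": 1.0, "delta_V": 0.3, "lambda_VA": 0.4,
        "lambda_OxEN": 0.2, "delta_Ox": 0.1,
    })
    return tk.ParameterSet.from_partial(vals)


def test_perturbation_zero_delta_collapses_to_baseline(angio_params, hyp_mod):
    x0 = RECOVERY_X0.copy()
    x0[STATE_VARS.index("EN")] = 0.2
    x0[STATE_VARS.index("V")] = 0.5
    exp = perturbation_experiment(
        "lambda_VEN", [0.0], angio_params, hyp_mod, x0, T_GRID
    )
    env = exp["envelope"]["cancer"]
    np.testing.assert_array_equal(env["min"], env["max"])
    # identical initial conditions: zero envelope width at t = 0 always
    exp2 = perturbation_experiment(
        "lambda_VEN", [-0.1, 0.0, 0.1], angio_params, hyp_mod, x0, T_GRID
    )
    for key in ("cancer", "total_immune"):
        e = exp2["envelope"][key]
        assert e["max"][0] - e["min"][0] == pytest.approx(0.0, abs=1e-12)


def test_perturbation_envelope_contains_baseline(angio_params, hyp_mod):
    x0 = RECOVERY_X0.copy()
    x0[STATE_VARS.index("EN")] = 0.2
    x0[STATE_VARS.index("V")] = 0.5
    exp = perturbation_experiment(
        "lambda_VEN", [-0.1, 0.0, 0.1], angio_params, hyp_mod, x0, T_GRID
    )
    base = exp["runs"][0.0]
    for key in ("cancer", "total_immune"):
        env = exp["envelope"][key]
        assert np.all(env["min"] <= base[key] + 1e-12)
        assert np.all(env["max"] >= base[key] - 1e-12)


def test_perturbation_clips_out_of_bounds(angio_params, hyp_mod):
    x0 = RECOVERY_X0.copy()
    with pytest.warns(UserWarning, match="clipping"):
        perturbation_experiment(
            "lambda_VEN", [5.0], angio_params, hyp_mod, x0, T_GRID
        )
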