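"""Model core: Hill switches, right-hand side, integration, observables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tmekin as tk
from tmekin.model import IMMUNE_VARS, STATE_INDEX, STATE_VARS

from _symbolic_oracle import build_oracle


# ---------------------------------------------------------------------------
# hypoxia switch
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "x, ox_crit, m, expected",
    [
        (0.0, 0.02, 3.0, 1.0),          # numerator equals denominator
        (0.02, 0.02, 1.0, 0.5),         # x at the critical value, any m
        (0.02, 0.02, 7.0, 0.5),
        (0.04, 0.02, 2.0, 0.2),         # 0.0004 / (0.0004 + 0.0016)
    ],
)
def test_hill_values(x, ox_crit, m, expected):
    assert tk.hill_hypoxia(x, ox_crit, m) == pytest.approx(expected, abs=1e-14)


@pytest.mark.parametrize("bad", [dict(ox_crit=0.0), dict(ox_crit=-1.0), dict(m=0.0), dict(m=-2.0)])
def test_hill_invalid_parameters(bad):
    kwargs = {"ox_crit": 0.02, "m": 3.0, **bad}
    with pytest.raises(ValueError):
        tk.hill_hypoxia(0.1, **kwargs)


@settings(deadline=None, max_examples=200)
@given(
    x=st.floats(0.0, 10.0, allow_nan=False),
    dx=st.floats(1e-6, 5.0),
    ox_crit=st.floats(1e-3, 1.0),
    m=st.floats(0.5, 8.0),
)
def test_hill_monotone_decreasing_and_bounded(x, dx, ox_crit, m):
    """The switch lies in (0, 1] and never increases with oxygen."""
    a = tk.hill_hypoxia(x, ox_crit, m)
    b = tk.hill_hypoxia(x + dx, ox_crit, m)
    assert 0.0 < a <= 1.0
    assert b <= a


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def test_rhs_zero_state_only_innate_sources(hyp):
    """With hypoxia-driven source rates off, an empty system only produces
    naive T cells, dendritic cells and macrophages at their innate rates."""
    p = tk.ParameterSet.from_partial({
        "A_TN": 0.3, "A_DN": 0.2, "A_MN": 0.1,
        # a scatter of other rates that multiply state variables
        "lambda_ThD": 1.0, "delta_C": 0.7, "lambda_HC": 0.9,
        "lambda_VA": 0.4, "delta_V": 0.2, "EN0": 1.0, "C0": 1.0, "A0": 1.0,
    })
    d = tk.rhs(0.0, np.zeros(18), p, hyp)
    expected = np.zeros(18)
    expected[STATE_INDEX["TN"]] = 0.3
    expected[STATE_INDEX["DN"]] = 0.2
    expected[STATE_INDEX["MN"]] = 0.1
    np.testing.assert_allclose(d, expected, atol=1e-15)


def test_rhs_isolated_adipocyte_logistic(hyp):
    p = tk.ParameterSet.from_partial({"lambda_A": 0.4, "delta_A": 0.1, "A0": 1.5})
    state = np.zeros(18)
    a = 0.6
    state[STATE_INDEX["A"]] = a
    d = tk.rhs(0.0, state, p, hyp)
    expected = np.zeros(18)
    expected[STATE_INDEX["A"]] = 0.4 * (1 - a / 1.5) * a - 0.1 * a
    np.testing.assert_allclose(d, expected, atol=1e-15)


def test_rhs_wrong_dimension(hyp):
    with pytest.raises(ValueError):
        tk.rhs(0.0, np.zeros(5), tk.ParameterSet.zeros(), hyp)


def test_rhs_matches_symbolic_oracle(random_params, random_state, hyp):
    """Term-by-term agreement with an independent computer-algebra expansion
    of the published equation table, at 100 random points."""
    oracle = build_oracle()
    for _ in range(100):
        p = random_params()
        y = random_state()
        expected = oracle(y, p.to_dict(), hyp.ox_crit1, hyp.ox_crit2, hyp.m)
        got = tk.rhs(0.0, y, p, hyp)
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)


def test_naive_activated_flux_balance(random_params, random_state, hyp):
    """Differentiation fluxes leaving each naive pool equal the activation
    influxes of the corresponding activated pools, term for term."""
    for _ in range(25):
        p, y = random_params(), random_state()
        EN, V, Ox, TN, Th, Tc, Tr, DN, D, MN, M, C, N, A, H, IL12, IL10, IL6 = y
        f1 = tk.hill_hypoxia(Ox, hyp.ox_crit1, hyp.m)
        th_act = (p["lambda_ThH"] * H + p["lambda_ThD"] * D
                  + p["lambda_ThIL12"] * IL12) * TN
        tc_act = (p["lambda_TcD"] * D + p["lambda_TcIL12"] * IL12) * TN
        tr_act = (p["lambda_TrD"] * D + p["lambda_TrOx"] * f1) * TN
        d_act = (p["lambda_DC"] * C + p["lambda_DH"] * H
                 + p["lambda_DOx"] * f1) * DN
        m_act = (p["lambda_MIL10"] * IL10 + p["lambda_MIL12"] * IL12
                 + p["lambda_MTh"] * Th) * MN

        # zero every non-differentiation rate so derivatives isolate the fluxes
        iso = {nm: 0.0 for nm in tk.PARAM_NAMES}
        for nm in ("lambda_ThH", "lambda_ThD", "lambda_ThIL12", "lambda_TcD",
                   "lambda_TcIL12", "lambda_TrD", "lambda_TrOx", "lambda_DC",
                   "lambda_DH", "lambda_DOx", "lambda_MIL10", "lambda_MIL12",
                   "lambda_MTh"):
            iso[nm] = p[nm]
        iso.update({"EN0": 1.0, "C0": 1.0, "A0": 1.0})
        d = tk.rhs(0.0, y, tk.ParameterSet(iso), hyp)

        assert d[STATE_INDEX["TN"]] == pytest.approx(
            -(th_act + tc_act + tr_act), rel=1e-12)
        assert d[STATE_INDEX["Th"]] == pytest.approx(th_act, rel=1e-12)
        assert d[STATE_INDEX["Tc"]] == pytest.approx(tc_act, rel=1e-12)
        assert d[STATE_INDEX["Tr"]] == pytest.approx(tr_act, rel=1e-12)
        assert d[STATE_INDEX["DN"]] == pytest.approx(-d_act, rel=1e-12)
        assert d[STATE_INDEX["D"]] == pytest.approx(d_act, rel=1e-12)
        assert d[STATE_INDEX["MN"]] == pytest.approx(-m_act, rel=1e-12)
        assert d[STATE_INDEX["M"]] == pytest.approx(m_act, rel=1e-12)
        # the three pairwise fluxes cancel in the total
        pair_sum = (d[STATE_INDEX["TN"]] + d[STATE_INDEX["Th"]]
                    + d[STATE_INDEX["Tc"]] + d[STATE_INDEX["Tr"]])
        assert pair_sum == pytest.approx(0.0, abs=1e-12)


def test_oxygen_independent_mode_reduces_to_base_model(random_params, random_state, hyp):
    """Zeroing every hypoxia-coupled rate removes all oxygen feedback from
    the immune/cancer equations: their derivatives become independent of Ox."""
    hypoxia_rates = [nm for nm in tk.PARAM_NAMES if nm.endswith("Ox")
                     and nm not in ("delta_Ox", "lambda_OxEN")]
    p = random_params()
    p = p.replace(**{nm: 0.0 for nm in hypoxia_rates})
    y = random_state()
    y2 = y.copy()
    y2[STATE_INDEX["Ox"]] = 0.77  # move oxygen only
    d1, d2 = tk.rhs(0.0, y, p, hyp), tk.rhs(0.0, y2, p, hyp)
    keep = [i for i, v in enumerate(STATE_VARS) if v != "Ox"]
    np.testing.assert_allclose(d1[keep], d2[keep], rtol=1e-12)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def test_simulate_zero_field_constant(hyp):
    x0 = np.linspace(0.1, 0.9, 18)
    traj = tk.simulate(tk.ParameterSet.zeros(), hyp, x0, np.linspace(0, 150, 16))
    np.testing.assert_allclose(traj.states, np.tile(x0, (16, 1)), atol=1e-9)


def test_simulate_logistic_closed_form(hyp):
    """Isolated adipocyte block follows the shifted-logistic solution with
    effective rate lambda-delta and capacity A0(1 - delta/lambda)."""
    lam, delta, A0, a0 = 0.2, 0.05, 1.0, 0.1
    p = tk.ParameterSet.from_partial({"lambda_A": lam, "delta_A": delta, "A0": A0})
    x0 = np.zeros(18)
    x0[STATE_INDEX["A"]] = a0
    t = np.linspace(0, 150, 151)
    traj = tk.simulate(p, hyp, x0, t)
    r = lam - delta
    K = A0 * (1 - delta / lam)
    expected = K / (1 + (K / a0 - 1) * np.exp(-r * t))
    np.testing.assert_allclose(traj["A"], expected, atol=1e-6)
    # all other compartments stay identically zero
    others = [i for i, v in enumerate(STATE_VARS) if v != "A"]
    np.testing.assert_allclose(traj.states[:, others], 0.0, atol=1e-10)


def test_simulate_linear_cytokine_steady_state(hyp):
    """H driven by constant C relaxes to lambda_HC * C / delta_H."""
    c = 0.6
    p = tk.ParameterSet.from_partial({"lambda_HC": 0.8, "delta_H": 0.2})
    x0 = np.zeros(18)
    x0[STATE_INDEX["C"]] = c  # C has zero dynamics here
    traj = tk.simulate(p, hyp, x0, np.linspace(0, 150, 51))
    assert traj["H"][-1] == pytest.approx(0.8 * c / 0.2, rel=1e-6)
    np.testing.assert_allclose(traj["C"], c, rtol=1e-9)


def test_simulate_positivity(random_params, hyp, rng):
    """Non-negative parameters and start keep every component above
    minus the solver tolerance across [0, 150]."""
    for _ in range(5):
        p = random_params()
        x0 = rng.uniform(0.0, 1.0, 18)
        traj = tk.simulate(p, hyp, x0, np.linspace(0, 150, 76))
        assert traj.states.min() >= -1e-10


def test_simulate_input_validation(hyp):
    p = tk.ParameterSet.zeros()
    with pytest.raises(ValueError):
        tk.simulate(p, hyp, np.zeros(18), [0.0])          # too short
    with pytest.raises(ValueError):
        tk.simulate(p, hyp, np.zeros(18), [0.0, 2.0, 1.0])  # not ascending
    with pytest.raises(ValueError):
        tk.simulate(p, hyp, np.zeros(7), [0.0, 1.0])      # wrong x0 shape


def test_trajectory_csv_round_trip(tmp_path, hyp):
    p = tk.ParameterSet.from_partial({"lambda_A": 0.2, "delta_A": 0.05, "A0": 1.0})
    x0 = np.zeros(18)
    x0[STATE_INDEX["A"]] = 0.1
    traj = tk.simulate(p, hyp, x0, np.linspace(0, 42, 5))
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    back = tk.Trajectory.from_csv(path)
    np.testing.assert_allclose(back.states, traj.states, rtol=1e-12)
    header = path.read_text().splitlines()[0]
    assert header == "t_days," + ",".join(STATE_VARS)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def test_observables_sums(rng):
    times = np.arange(4.0)
    states = rng.uniform(0, 1, (4, 18))
    traj = tk.Trajectory(times, states)
    obs = tk.observables(traj)
    brute_immune = sum(states[:, STATE_INDEX[v]] for v in IMMUNE_VARS)
    np.testing.assert_allclose(obs["total_immune"], brute_immune, rtol=1e-14)
    np.testing.assert_allclose(obs["cancer"], states[:, STATE_INDEX["C"]])
    # constant immune compartments: 8 x 0.1 = 0.8
    states2 = np.zeros((2, 18))
    for v in IMMUNE_VARS:
        states2[:, STATE_INDEX[v]] = 0.1
    obs2 = tk.observables(tk.Trajectory(np.array([0.0, 1.0]), states2))
    np.testing.assert_allclose(obs2["total_immune"], 0.8, rtol=1e-14)
    zero = tk.observables(tk.Trajectory(np.array([0.0, 1.0]), np.zeros((2, 18))))
    assert all(np.all(v == 0) for v in zero.values())
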