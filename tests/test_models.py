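import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal as scipy_signal

from gelsid.kinematics import KinematicSignal
from gelsid.models import (
    LinearTF,
    Model1Params,
    Model2Params,
    UnstableModelWarning,
    maxwell_to_tf,
    mr_extension,
    poles_to_time_constants,
    polynomial_input,
    relaxation_closed_form,
    simulate_hammerstein,
    simulate_lti,
    simulate_model1,
    tf_to_maxwell,
)
from gelsid.protocols import make_cycles, make_signal


# ---------------------------------------------------------------------------
# memoryless blocks
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "lam, C1, C2, expected",
    [
        (1.0, 3.7, -2.1, 0.0),                 # reference configuration
        (2.0, 1.0, 0.0, 3.5),                  # Neo Hookean form
        (0.8, -5.61, 4.4, (-5.61 + 5.5) * (0.64 - 1.25)),  # published model-1 set
    ],
)
def test_mr_extension_values(lam, C1, C2, expected):
    assert mr_extension(lam, C1, C2) == pytest.approx(expected, rel=1e-12)


def test_mr_extension_rejects_nonpositive_stretch():
    with pytest.raises(ValueError):
        mr_extension(0.0, 1.0, 1.0)


@pytest.mark.parametrize(
    "p, eps, expected",
    [
        ((3.0, -2.0, 5.0), 0.0, 0.0),
        ((0.0, 0.0, 1.0), 0.3, 0.3),
        ((10.8, -1.1, 0.0), 0.2, 10.8 * 0.008 - 1.1 * 0.04),
    ],
)
def test_polynomial_input_values(p, eps, expected):
    assert polynomial_input(eps, *p) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# parameterizations
# ---------------------------------------------------------------------------


def test_maxwell_to_tf_example():
    tf = maxwell_to_tf(1.0, 1.0, 1.0, 2.0)
    assert (tf.a1, tf.a2, tf.b0, tf.b1) == pytest.approx((1.5, 0.5, 2.0, 1.5))


def test_single_maxwell_reduction():
    tf = maxwell_to_tf(3.0, 0.0, 1.5, 7.0)
    assert tf.b0 == pytest.approx(3.0)
    assert tf.b1 == pytest.approx(3.0 / 7.0)


def test_tf_maxwell_round_trip_published_set():
    theta = (0.81, 0.13, 4.0, 70.0)
    back = tf_to_maxwell(maxwell_to_tf(*theta))
    assert back == pytest.approx(theta, rel=1e-12)


@given(
    g1=st.floats(0.01, 10.0), g2=st.floats(0.01, 10.0),
    tau1=st.floats(0.1, 5.0), tau2=st.floats(6.0, 200.0),
)
def test_tf_maxwell_round_trip_property(g1, g2, tau1, tau2):
    back = tf_to_maxwell(maxwell_to_tf(g1, g2, tau1, tau2))
    assert back == pytest.approx((g1, g2, tau1, tau2), rel=1e-8)


def test_degenerate_taus_rejected():
    with pytest.raises(ValueError):
        maxwell_to_tf(1.0, 1.0, 2.0, 2.0)
    with pytest.raises(ValueError):
        Model2Params(p0=1, p1=0, p2=0, g1=1, g2=1, tau1=3.0, tau2=3.0)


@pytest.mark.parametrize(
    "a1, a2, expected",
    [(1.05, 0.05, (1.0, 20.0)), (1.5, 0.5, (1.0, 2.0))],
)
def test_poles_to_time_constants(a1, a2, expected):
    taus = poles_to_time_constants(LinearTF(a1=a1, a2=a2, b0=1.0, b1=1.0))
    assert taus == pytest.approx(expected, rel=1e-12)


def test_poles_to_time_constants_rejects_degenerate():
    with pytest.raises(ValueError):  # repeated pole
        poles_to_time_constants(LinearTF(a1=2.0, a2=1.0, b0=1.0, b1=1.0))
    with pytest.raises(ValueError):  # complex poles
        poles_to_time_constants(LinearTF(a1=0.5, a2=1.0, b0=1.0, b1=1.0))


def test_param_record_invariants():
    p = Model1Params(C1=-5.61, C2=4.4, g1=0.63, g2=5.21, tau1=1.0, tau2=20.0)
    assert p.eta1 / p.g1 == pytest.approx(p.tau1)
    assert p.eta2 / p.g2 == pytest.approx(p.tau2)
    with pytest.raises(ValueError):
        Model1Params(C1=0, C2=0, g1=-1.0, g2=0, tau1=1, tau2=2)
    with pytest.raises(ValueError):
        Model1Params(C1=0, C2=0, g1=1.0, g2=0, tau1=-1, tau2=2)


# ---------------------------------------------------------------------------
# linear simulation vs closed forms
# ---------------------------------------------------------------------------


def test_zero_input_zero_states_gives_zero_output():
    t = np.linspace(0, 50, 501)
    tf = maxwell_to_tf(2.0, 1.0, 1.0, 10.0)
    res = simulate_lti(tf, np.zeros_like(t), t)
    assert np.all(res.y == 0)


def test_unit_step_single_maxwell_closed_form():
    t = np.arange(0, 10.0, 0.01)
    tf = maxwell_to_tf(1.0, 0.0, 1.0, 2.0)
    res = simulate_lti(tf, np.ones_like(t), t)
    np.testing.assert_allclose(res.y, np.exp(-t), atol=1e-9)
    assert res.y[0] == pytest.approx(1.0)


def test_step_two_maxwell_closed_form():
    t = np.arange(0, 60.0, 0.05)
    tf = maxwell_to_tf(2.0, 1.0, 1.0, 10.0)
    res = simulate_lti(tf, np.full_like(t, 0.5), t)
    expected = 0.5 * (2.0 * np.exp(-t) + np.exp(-t / 10.0))
    np.testing.assert_allclose(res.y, expected, atol=1e-9)


def test_state_space_step_matches_closed_form_for_random_stable_draws(rng):
    """Oracle equivalence over 100 random stable two-Maxwell parameter draws."""
    t = np.arange(0, 200.0, 0.1)
    worst = 0.0
    for _ in range(100):
        g1, g2 = rng.uniform(0.05, 10.0, size=2)
        tau1 = rng.uniform(0.2, 5.0)
        tau2 = tau1 * rng.uniform(1.5, 50.0)
        eps0 = rng.uniform(-1.0, 1.0) or 0.3
        tf = maxwell_to_tf(g1, g2, tau1, tau2)
        y = simulate_lti(tf, np.full_like(t, eps0), t).y
        ref = relaxation_closed_form(g1, g2, tau1, tau2, eps0, t)
        scale = np.max(np.abs(ref)) or 1.0
        worst = max(worst, np.max(np.abs(y - ref)) / scale)
    assert worst <= 1e-6


def test_relaxation_closed_form_limits():
    t = np.array([0.0, 1e6])
    y = relaxation_closed_form(2.0, 3.0, 1.0, 10.0, 0.4, t)
    assert y[0] == pytest.approx(0.4 * 5.0)
    assert y[1] == pytest.approx(0.0, abs=1e-12)


def test_unstable_tf_warns_but_simulates():
    t = np.linspace(0, 1, 11)
    with pytest.warns(UnstableModelWarning):
        res = simulate_lti(LinearTF(a1=-1.0, a2=0.5, b0=1.0, b1=1.0), np.ones_like(t), t)
    assert np.all(np.isfinite(res.y))


def test_simulate_lti_cross_checked_against_scipy(rng):
    t = np.arange(0, 30.0, 0.02)
    u = np.cumsum(rng.normal(size=t.size)) * 0.01
    tf = maxwell_to_tf(1.3, 0.7, 0.8, 12.0)
    sys = scipy_signal.TransferFunction([tf.b0, tf.b1, 0.0], [1.0, tf.a1, tf.a2])
    _, y_ref, _ = scipy_signal.lsim(sys.to_ss(), u, t)
    y = simulate_lti(tf, u, t).y
    np.testing.assert_allclose(y, y_ref, atol=1e-10)


# ---------------------------------------------------------------------------
# model 1
# ---------------------------------------------------------------------------


def _const_extension_signal(e, e0=5.0, T=30.0, n=601):
    t = np.linspace(0, T, n)
    return KinematicSignal(t=t, e=np.full(n, e), e0=e0)


def test_model1_equilibrium_at_reference_extension(model1_truth):
    kin = _const_extension_signal(5.0)
    res = simulate_model1(Model1Params(**model1_truth), kin)
    assert np.allclose(res.y, 0.0, atol=1e-14)
    assert np.allclose(res.x1, 0.0) and np.allclose(res.x2, 0.0)


def test_model1_single_maxwell_step_is_exponential():
    """With g2 = 0 a step in e' relaxes as a single exponential with tau1."""
    params = Model1Params(C1=1.2, C2=0.5, g1=2.0, g2=0.0, tau1=3.0, tau2=50.0)
    kin = _const_extension_signal(4.0, T=30.0, n=3001)
    lam = 4.0 / 5.0
    ep = mr_extension(lam, 1.2, 0.5)
    res = simulate_model1(params, kin)
    expected = 2.0 * ep * np.exp(-kin.t / 3.0) / lam
    np.testing.assert_allclose(res.y, expected, rtol=1e-6, atol=1e-12)


def test_model1_step_halving_converged(model1_truth, cycles_spec):
    kin = make_signal(cycles_spec)
    params = Model1Params(**model1_truth)
    y1 = simulate_model1(params, kin).y
    y2 = simulate_model1(params, kin, refine=4).y
    assert np.max(np.abs(y1 - y2)) / np.max(np.abs(y1)) < 1e-6


def test_model1_exact_and_lsoda_integrators_agree(model1_truth, small_cycles_spec):
    kin = make_signal(small_cycles_spec)
    params = Model1Params(**model1_truth)
    ya = simulate_model1(params, kin).y
    yb = simulate_model1(params, kin, method="lsoda").y
    assert np.max(np.abs(ya - yb)) / np.max(np.abs(ya)) < 1e-5


@pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
def test_model1_scale_ridge_invariance(model1_truth, small_cycles_spec, k):
    """(C, g) -> (kC, g/k) leaves the output invariant: the identifiability ridge."""
    kin = make_signal(small_cycles_spec)
    p = Model1Params(**model1_truth)
    p_ridge = p.replace(C1=k * p.C1, C2=k * p.C2, g1=p.g1 / k, g2=p.g2 / k)
    y = simulate_model1(p, kin).y
    y_ridge = simulate_model1(p_ridge, kin).y
    assert np.max(np.abs(y - y_ridge)) / np.max(np.abs(y)) < 1e-9


def test_model1_neohookean_reduction(small_cycles_spec):
    """C2 = 0 reduces e' to the Neo Hookean form C1*(lam^2 - 1/lam)."""
    kin = make_signal(small_cycles_spec)
    p = Model1Params(C1=0.22, C2=0.0, g1=5.94, g2=31.58, tau1=1.0, tau2=20.0)
    np.testing.assert_allclose(
        mr_extension(kin.lam, p.C1, 0.0), p.C1 * (kin.lam**2 - 1.0 / kin.lam), rtol=1e-14
    )
    res = simulate_model1(p, kin)
    assert np.all(np.isfinite(res.y))


def test_model1_rejects_mismatched_reference():
    kin = _const_extension_signal(4.0, e0=5.0)
    params = Model1Params(C1=1, C2=0, g1=1, g2=1, tau1=1, tau2=2, e0=4.0)
    with pytest.raises(ValueError):
        simulate_model1(params, kin)


# ---------------------------------------------------------------------------
# Hammerstein
# ---------------------------------------------------------------------------


def test_hammerstein_identity_block_equals_linear(small_cycles_spec):
    kin = make_signal(small_cycles_spec)
    params = Model2Params(p0=0, p1=0, p2=1, g1=0.8, g2=0.2, tau1=2.0, tau2=30.0)
    y_h = simulate_hammerstein(params, kin).y
    tf = maxwell_to_tf(0.8, 0.2, 2.0, 30.0)
    y_l = simulate_lti(tf, kin.eps, kin.t).y
    np.testing.assert_array_equal(y_h, y_l)


def test_hammerstein_zero_block_gives_zero_output(small_cycles_spec):
    kin = make_signal(small_cycles_spec)
    params = Model2Params(p0=0, p1=0, p2=0, g1=0.8, g2=0.2, tau1=2.0, tau2=30.0)
    assert np.all(simulate_hammerstein(params, kin).y == 0)


def test_hammerstein_composition_oracle(hammerstein_truth, cycles_spec):
    """Published parameter set on the eight-cycle protocol equals the
    independently composed static-block + scipy linear simulation."""
    kin = make_signal(cycles_spec)
    p = Model2Params(**hammerstein_truth)
    y = simulate_hammerstein(p, kin).y
    u_prime = p.p0 * kin.eps**3 + p.p1 * kin.eps**2 + p.p2 * kin.eps
    tf = maxwell_to_tf(p.g1, p.g2, p.tau1, p.tau2)
    sys = scipy_signal.TransferFunction([tf.b0, tf.b1, 0.0], [1.0, tf.a1, tf.a2])
    _, y_ref, _ = scipy_signal.lsim(sys.to_ss(), u_prime, kin.t)
    np.testing.assert_allclose(y, y_ref, atol=1e-10)


# ---------------------------------------------------------------------------
# passivity
# ---------------------------------------------------------------------------


def _last_cycle(kin, y, period, rate):
    n = int(round(period * rate))
    return kin.eps[-n - 1 :], y[-n - 1 :]


@pytest.mark.parametrize("model", ["linear", "hammerstein"])
def test_hysteresis_loop_area_nonnegative_at_steady_state(model, hammerstein_truth):
    from gelsid.metrics import hysteresis_area
    from gelsid.protocols import ProtocolSpec

    spec = ProtocolSpec(kind="cycles", crosshead_speed=2.0, n_cycles=8, sample_rate=5.0)
    kin = make_cycles(spec)
    if model == "linear":
        y = simulate_lti(maxwell_to_tf(1.0, 1.0, 1.0, 20.0), kin.eps, kin.t).y
    else:
        y = simulate_hammerstein(Model2Params(**hammerstein_truth), kin).y
    period = 2 * (0.25 - 0.15) * 5.0 / (2.0 / 60.0)  # one triangular cycle, s
    eps_c, y_c = _last_cycle(kin, y, period, 5.0)
    area = hysteresis_area(eps_c, y_c, closure_rtol=0.05)
    assert area >= 0.0
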