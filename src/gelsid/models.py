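"""Two-Maxwell viscoelastic models with nonlinear springs, and their forward maps.

Both model families consist of two Maxwell bodies (spring g_i in series with a
dashpot eta_i, relaxation time tau_i = eta_i/g_i) in parallel, driven either by

* a Mooney-Rivlin-type nonlinear spring extension (model 1)
      e'(lambda) = (C1 + C2/lambda) * (lambda^2 - 1/lambda),
  with state equations  tau_i * dx_i/dt = e' - x_i  and load
      y = [g1*(e' - x1) + g2*(e' - x2)] * e0/e,
  input u = e (extension, mm); C2 = 0 gives the Neo Hookean variant; or

* a cubic polynomial of the strain feeding a linear two-Maxwell block
  (a Hammerstein structure, model 2):
      u' = f(eps) = p0*eps^3 + p1*eps^2 + p2*eps,
      d2y/dt2 + a1*dy/dt + a2*y = b0*d2u'/dt2 + b1*du'/dt,
  with a1 = (tau1+tau2)/(tau1*tau2), a2 = 1/(tau1*tau2),
  b0 = g1+g2, b1 = g1/tau2 + g2/tau1.

The quasi-static assumption drops inertia, so both models are second-order
(two internal states).  The linear block is realized in the canonical
state-space form whose input matrix avoids differentiating the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.signal import lfilter, lfiltic

from .kinematics import KinematicSignal

__all__ = [
    "Model1Params",
    "Model2Params",
    "LinearTF",
    "SimResult",
    "mr_extension",
    "polynomial_input",
    "maxwell_to_tf",
    "tf_to_maxwell",
    "simulate_model1",
    "simulate_lti",
    "simulate_hammerstein",
    "relaxation_closed_form",
    "UnstableModelWarning",
]


class UnstableModelWarning(UserWarning):
    """Simulation of a transfer function with non-negative poles."""


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Model1Params:
    """Mooney-Rivlin-inspired two-Maxwell model (C2 = 0: Neo Hookean variant).

    C1, C2 are the hyperelastic constants (stress-like, sign-unrestricted),
    g1, g2 >= 0 the spring constants, tau1, tau2 > 0 the relaxation times in
    seconds.  e0 is the reference extension (mm) and A0 the sample
    cross-section (mm^2); viscosities eta_i = g_i*tau_i are derived.
    """

    C1: float
    C2: float
    g1: float
    g2: float
    tau1: float
    tau2: float
    e0: float = 5.0
    A0: float = 700.0

    def __post_init__(self):
        if not (self.tau1 > 0 and self.tau2 > 0):
            raise ValueError("relaxation times must be positive")
        if self.g1 < 0 or self.g2 < 0:
            raise ValueError("spring constants must be non-negative")
        if not (self.e0 > 0 and self.A0 > 0):
            raise ValueError("geometry must be positive")

    @property
    def eta1(self) -> float:
        return self.g1 * self.tau1

    @property
    def eta2(self) -> float:
        return self.g2 * self.tau2

    def replace(self, **kw) -> "Model1Params":
        return replace(self, **kw)


@dataclass(frozen=True)
class Model2Params:
    """Hammerstein model: cubic strain polynomial + linear two-Maxwell block.

    p0, p1, p2 are the cubic coefficients of f(eps) = p0*eps^3 + p1*eps^2 +
    p2*eps (no constant term, so f(0) = 0); the linear block carries
    (g1, g2, tau1, tau2) with distinct positive relaxation times.
    """

    p0: float
    p1: float
    p2: float
    g1: float
    g2: float
    tau1: float
    tau2: float

    def __post_init__(self):
        if not (self.tau1 > 0 and self.tau2 > 0):
            raise ValueError("relaxation times must be positive")
        if self.tau1 == self.tau2:
            raise ValueError("relaxation times must be distinct")

    def replace(self, **kw) -> "Model2Params":
        return replace(self, **kw)


@dataclass(frozen=True)
class LinearTF:
    """Second-order transfer function (b0*s^2 + b1*s) / (s^2 + a1*s + a2).

    For a physical two-Maxwell pair both denominator coefficients are
    positive and the poles are real and negative; unstable coefficient sets
    are representable (simulation warns) so that intermediate estimates can
    be carried around.
    """

    a1: float
    a2: float
    b0: float
    b1: float

    def poles(self) -> np.ndarray:
        return np.roots([1.0, self.a1, self.a2])

    @property
    def is_stable(self) -> bool:
        return bool(np.all(np.real(self.poles()) < 0))

    def as_theta(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.b0, self.b1], dtype=float)


@dataclass(frozen=True)
class SimResult:
    """Integrated internal states and output load on the input time grid."""

    t: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        n = len(self.t)
        if not (len(self.x1) == len(self.x2) == len(self.y) == n):
            raise ValueError("t, x1, x2, y must have equal length")


# ---------------------------------------------------------------------------
# memoryless blocks
# ---------------------------------------------------------------------------


def mr_extension(lam, C1, C2):
    """Mooney-Rivlin nonlinear spring extension e' = (C1 + C2/lam)*(lam^2 - 1/lam).

    Memoryless: depends only on the instantaneous stretch.  ``lam`` must be
    positive; C2 = 0 reduces to the Neo Hookean form C1*(lam^2 - 1/lam).
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch must be positive")
    return (C1 + C2 / lam) * (lam**2 - 1.0 / lam)


def polynomial_input(eps, p0, p1, p2):
    """Cubic static nonlinearity f(eps) = p0*eps^3 + p1*eps^2 + p2*eps (f(0)=0)."""
    eps = np.asarray(eps, dtype=float)
    return p0 * eps**3 + p1 * eps**2 + p2 * eps


# ---------------------------------------------------------------------------
# transfer-function <-> Maxwell parameterizations
# ---------------------------------------------------------------------------


def maxwell_to_tf(g1, g2, tau1, tau2) -> LinearTF:
    """Exact map from two-Maxwell constants to the second-order transfer function.

    a1 = (tau1+tau2)/(tau1*tau2), a2 = 1/(tau1*tau2),
    b0 = g1+g2, b1 = g1/tau2 + g2/tau1.  Requires distinct positive taus.
    """
    if not (tau1 > 0 and tau2 > 0):
        raise ValueError("relaxation times must be positive")
    if tau1 == tau2:
        raise ValueError("degenerate poles: tau1 == tau2")
    return LinearTF(
        a1=(tau1 + tau2) / (tau1 * tau2),
        a2=1.0 / (tau1 * tau2),
        b0=g1 + g2,
        b1=g1 / tau2 + g2 / tau1,
    )


def tf_to_maxwell(tf: LinearTF):
    """Invert :func:`maxwell_to_tf`: returns (g1, g2, tau1, tau2), tau1 <= tau2.

    Valid only for real, distinct, negative poles (a genuine two-Maxwell
    system); the labeling of the two bodies is fixed by sorting the taus.
    """
    disc = tf.a1**2 - 4.0 * tf.a2
    if disc <= 0:
        raise ValueError("poles are complex or repeated: not a two-Maxwell system")
    r = np.sqrt(disc)
    poles = np.sort(np.array([(-tf.a1 - r) / 2.0, (-tf.a1 + r) / 2.0]))
    if np.any(poles >= 0):
        raise ValueError("poles must be negative")
    tau = np.sort(-1.0 / poles)  # ascending
    tau1, tau2 = tau
    # solve g1+g2 = b0, g1/tau2 + g2/tau1 = b1
    g1 = (tf.b1 - tf.b0 / tau1) / (1.0 / tau2 - 1.0 / tau1)
    g2 = tf.b0 - g1
    return g1, g2, tau1, tau2


def poles_to_time_constants(tf: LinearTF):
    """Relaxation times from the transfer-function poles, tau_i = -1/pole_i.

    Returns (tau1, tau2) sorted ascending.  Complex or repeated poles mean
    the estimate is not a two-Maxwell system and raise ValueError.
    """
    disc = tf.a1**2 - 4.0 * tf.a2
    if disc < 0:
        raise ValueError("complex poles: not a two-Maxwell system")
    if disc == 0:
        raise ValueError("repeated pole: degenerate two-Maxwell system")
    r = np.sqrt(disc)
    poles = np.array([(-tf.a1 - r) / 2.0, (-tf.a1 + r) / 2.0])
    if np.any(poles >= 0):
        raise ValueError("non-negative pole: unstable or marginal estimate")
    return tuple(np.sort(-1.0 / poles))


# ---------------------------------------------------------------------------
# linear simulation
# ---------------------------------------------------------------------------


def _state_space(tf: LinearTF):
    """Canonical realization with x1 = y - b0*u, x2 = x1' - (b1 - a1*b0)*u."""
    beta1 = tf.b1 - tf.a1 * tf.b0
    beta2 = -tf.a1 * beta1 - tf.a2 * tf.b0
    A = np.array([[0.0, 1.0], [-tf.a2, -tf.a1]])
    B = np.array([[beta1], [beta2]])
    C = np.array([[1.0, 0.0]])
    D = np.array([[tf.b0]])
    return A, B, C, D


def _foh_step(A, B, dt):
    """First-order-hold discretization of dx = Ax + Bu for one step of length dt.

    Returns (Ad, B0, B1) such that x+ = Ad x + B0 u_k + B1 u_{k+1} for input
    linear between the samples.  Computed from the exponential of the
    augmented matrix [[A, B, 0], [0, 0, I/dt], [0, 0, 0]].
    """
    n = A.shape[0]
    m = B.shape[1]
    M = np.zeros((n + 2 * m, n + 2 * m))
    M[:n, :n] = A * dt
    M[:n, n : n + m] = B * dt
    M[n : n + m, n + m :] = np.eye(m)
    E = expm(M)
    Ad = E[:n, :n]
    G0 = E[:n, n : n + m]  # response to constant input u_k
    G1 = E[:n, n + m :]    # response to the ramp component (u_{k+1}-u_k)*s/dt
    B1 = G1
    B0 = G0 - G1
    return Ad, B0, B1


def _foh_states(A, B, u, t, x0):
    """States of dx = Ax + Bu for piecewise-linear u on grid t (exact FOH).

    Uniform grids with a diagonalizable one-step matrix are solved by two
    decoupled scalar recursions through :func:`scipy.signal.lfilter`; other
    grids fall back to a stepwise recursion with cached step matrices.
    """
    t = np.asarray(t, dtype=float)
    u = np.asarray(u, dtype=float)
    n = t.size
    x = np.zeros((n, A.shape[0]))
    x[0] = np.asarray(x0, dtype=float)
    if n == 1:
        return x
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise ValueError("time grid must be strictly increasing")
    uniform = np.allclose(dts, dts[0], rtol=1e-9, atol=0.0)
    if uniform:
        Ad, B0, B1 = _foh_step(A, B, dts[0])
        evals, V = np.linalg.eig(Ad)
        if abs(evals[0] - evals[1]) > 1e-10 * max(1.0, np.max(np.abs(evals))):
            w = B0 @ u[None, :-1] + B1 @ u[None, 1:]  # (2, n-1) drive terms
            Vi = np.linalg.inv(V)
            z0 = Vi @ x[0]
            wz = Vi @ w
            Z = np.empty((2, n), dtype=complex)
            Z[:, 0] = z0
            for i in range(2):
                d = evals[i]
                zi = lfiltic([1.0], np.array([1.0, -d]), y=[z0[i]])
                Z[i, 1:], _ = lfilter([1.0], np.array([1.0, -d]), wz[i], zi=zi)
            return np.real((V @ Z).T)
        for k in range(n - 1):
            x[k + 1] = Ad @ x[k] + (B0 * u[k] + B1 * u[k + 1]).ravel()
        return x
    cache: dict[float, tuple] = {}
    keys = np.round(dts, 12)
    for k in range(n - 1):
        key = keys[k]
        if key not in cache:
            cache[key] = _foh_step(A, B, dts[k])
        Ad, B0, B1 = cache[key]
        x[k + 1] = Ad @ x[k] + (B0 * u[k] + B1 * u[k + 1]).ravel()
    return x


def simulate_lti(tf: LinearTF, u, t, x0=(0.0, 0.0)) -> SimResult:
    """Simulate the canonical state-space realization of ``tf`` on grid ``t``.

    The input is taken piecewise linear between samples (first-order hold),
    for which the discretization is exact.  Unstable coefficient sets are
    simulated with a warning.
    """
    t = np.asarray(t, dtype=float)
    u = np.asarray(u, dtype=float)
    if u.shape != t.shape:
        raise ValueError("u and t must have the same shape")
    if tf.a1 <= 0 or tf.a2 <= 0:
        warnings.warn(
            "simulating a transfer function outside the stable region "
            f"(a1={tf.a1:g}, a2={tf.a2:g})",
            UnstableModelWarning,
        )
    A, B, C, D = _state_space(tf)
    x = _foh_states(A, B, u, t, x0)
    y = x @ C.ravel() + D[0, 0] * u
    return SimResult(t=t, x1=x[:, 0], x2=x[:, 1], y=y)


def relaxation_closed_form(g1, g2, tau1, tau2, eps0, t):
    """Analytic step response eps0*(g1*exp(-t/tau1) + g2*exp(-t/tau2)).

    This is the load relaxation of the linear two-Maxwell model under an
    ideal strain step of amplitude eps0 applied at t = 0 from rest: the
    instantaneous modulus is g1+g2 and the load fully relaxes to zero (no
    parallel equilibrium spring).
    """
    if not (tau1 > 0 and tau2 > 0):
        raise ValueError("relaxation times must be positive")
    t = np.asarray(t, dtype=float)
    return eps0 * (g1 * np.exp(-t / tau1) + g2 * np.exp(-t / tau2))


# ---------------------------------------------------------------------------
# model 1 (Mooney-Rivlin inspired)
# ---------------------------------------------------------------------------


def _first_order_foh(w, t, tau, x0=0.0):
    """Exact FOH integration of tau*dx/dt = w - x for w piecewise linear on t."""
    n = t.size
    x = np.empty(n)
    x[0] = x0
    if n == 1:
        return x
    dts = np.diff(t)
    keys = np.round(dts, 12)
    if np.all(keys == keys[0]):
        h = dts[0]
        a = np.exp(-h / tau)
        r = tau / h
        J1 = 1.0 - r * (1.0 - a)
        J0 = r * (1.0 - a) - a
        zi = lfiltic([J1, J0], [1.0, -a], y=[x0], x=[w[0]])
        x[1:], _ = lfilter([J1, J0], [1.0, -a], w[1:], zi=zi)
        return x
    for k in range(n - 1):
        h = dts[k]
        a = np.exp(-h / tau)
        r = tau / h
        J1 = 1.0 - r * (1.0 - a)
        J0 = r * (1.0 - a) - a
        x[k + 1] = a * x[k] + J0 * w[k] + J1 * w[k + 1]
    return x


def _refine_grid(t, e, refine: int):
    if refine <= 1:
        return t, e, slice(None)
    n = t.size
    tf_ = np.empty((n - 1) * refine + 1)
    for j in range(refine):
        tf_[j : -1 : refine] = t[:-1] + (t[1:] - t[:-1]) * (j / refine)
    tf_[-1] = t[-1]
    ef = np.interp(tf_, t, e)
    return tf_, ef, slice(None, None, refine)


def simulate_model1(
    params: Model1Params,
    kin: KinematicSignal,
    x0=(0.0, 0.0),
    method: str = "exact",
    refine: int = 2,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> SimResult:
    """Forward map of the Mooney-Rivlin-inspired model on an extension record.

    States are the dashpot extensions x_i driven by the memoryless spring
    extension e'(lambda(t)); the load output is
    y = [g1*(e'-x1) + g2*(e'-x2)] * e0/e.

    method='exact' (default) integrates the linear state equations with an
    exact exponential first-order-hold recursion, treating e' as piecewise
    linear between samples (``refine`` subdivides each sampling interval for
    step-halving checks); method='lsoda' uses a stiff-capable variable-step
    integrator on the same linearly interpolated extension input.
    """
    if np.any(kin.e <= 0):
        raise ValueError("extension must be positive throughout the record")
    if params.e0 != kin.e0:
        raise ValueError("params.e0 and kin.e0 disagree")
    t, e = kin.t, kin.e
    if method == "exact":
        tf_, ef, keep = _refine_grid(t, e, refine)
        lam = ef / params.e0
        ep = mr_extension(lam, params.C1, params.C2)
        x1 = _first_order_foh(ep, tf_, params.tau1, x0[0])[keep]
        x2 = _first_order_foh(ep, tf_, params.tau2, x0[1])[keep]
        ep = ep[keep]
        lam = lam[keep]
    elif method == "lsoda":
        def e_of(ti):
            return np.interp(ti, t, e)

        def rhs(ti, x):
            lam_i = e_of(ti) / params.e0
            ep_i = mr_extension(lam_i, params.C1, params.C2)
            return [
                (ep_i - x[0]) / params.tau1,
                (ep_i - x[1]) / params.tau2,
            ]

        sol = solve_ivp(
            rhs, (t[0], t[-1]), list(x0), t_eval=t, method="LSODA",
            rtol=rtol, atol=atol, max_step=np.inf,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        x1, x2 = sol.y
        lam = e / params.e0
        ep = mr_extension(lam, params.C1, params.C2)
    else:
        raise ValueError(f"unknown method {method!r}")
    y = (params.g1 * (ep - x1) + params.g2 * (ep - x2)) / lam
    return SimResult(t=t, x1=x1, x2=x2, y=y)


def simulate_hammerstein(params: Model2Params, kin: KinematicSignal, x0=(0.0, 0.0)) -> SimResult:
    """Hammerstein forward map: cubic strain block feeding the linear block.

    Exactly the composition simulate_lti(maxwell_to_tf(...), f(eps)); with
    p = (0, 0, 1) it coincides with the linear model on the strain.
    """
    u_prime = polynomial_input(kin.eps, params.p0, params.p1, params.p2)
    tf = maxwell_to_tf(params.g1, params.g2, params.tau1, params.tau2)
    return simulate_lti(tf, u_prime, kin.t, x0=x0)
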