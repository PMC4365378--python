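"""Parameter estimation from sampled compression records.

Two estimators are provided, mirroring the identification workflow used for
the gel data:

* :func:`fit_linear_ct` — continuous-time identification of the second-order
  transfer function (b0 s^2 + b1 s)/(s^2 + a1 s + a2) from {u(t_k), y(t_k)}
  by a simplified refined instrumental-variable scheme (srivc-style):
  state-variable filtering supplies noise-free derivative surrogates for the
  initial least squares, after which the instruments are rebuilt from the
  simulated model output and the prefilter from the current denominator,
  iterating to convergence.  No raw signal is ever differentiated.

* :func:`fit_greybox` — prediction-error minimization for the nonlinear
  structures (Mooney-Rivlin-inspired model, its Neo Hookean variant, and the
  Hammerstein model) by a Levenberg-Marquardt loop in which every residual
  evaluation is a full forward simulation.  Model 1 has an exact scale ridge
  (C1, C2, g1, g2) -> (k C1, k C2, g1/k, g2/k); the Hammerstein model has the
  analogous (p, g) ridge.  A parameter from the scaled group must therefore
  be held fixed (``FitConfig.fixed``) for the estimate to be unique.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import (
    LinearTF,
    Model1Params,
    Model2Params,
    poles_to_time_constants,
    simulate_hammerstein,
    simulate_lti,
    simulate_model1,
)
from .protocols import TimeSeriesDataset
from .metrics import fit_percent

__all__ = [
    "FitConfig",
    "FitResult",
    "fit_linear_ct",
    "fit_greybox",
    "validate",
    "poles_to_time_constants",
    "simulate_structure",
    "ExcitationError",
]

_STRUCTURES = ("linear_tf", "model1", "model1_neohookean", "hammerstein")

_PARAM_NAMES = {
    "model1": ("C1", "C2", "g1", "g2", "tau1", "tau2"),
    "model1_neohookean": ("C1", "g1", "g2", "tau1", "tau2"),
    "hammerstein": ("p0", "p1", "p2", "g1", "g2", "tau1", "tau2"),
}


class ExcitationError(RuntimeError):
    """The input does not excite the system enough to identify it."""


@dataclass(frozen=True)
class FitConfig:
    """Settings of one identification run.

    init maps parameter names to starting values (for grey-box fits) and
    fixed names the parameters held constant — the identifiability
    normalization.  tol is the relative convergence tolerance, seed controls
    any randomized initialization, svf_cutoff (rad/s) overrides the
    state-variable-filter cutoff sweep of the linear estimator.
    """

    structure: str
    init: dict = field(default_factory=dict)
    fixed: frozenset = frozenset()
    max_iter: int = 100
    tol: float = 1e-9
    seed: int | None = None
    svf_cutoff: float | None = None

    def __post_init__(self):
        if self.structure not in _STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        names = _PARAM_NAMES.get(self.structure, ())
        object.__setattr__(self, "fixed", frozenset(self.fixed))
        if names and not self.fixed <= set(names):
            raise ValueError(f"fixed names {set(self.fixed) - set(names)} not in structure")


@dataclass
class FitResult:
    """Estimated parameters with residuals and convergence diagnostics."""

    params: object
    residuals: np.ndarray
    n_iter: int
    converged: bool
    loss: float
    loss_history: list = field(default_factory=list)

    def __post_init__(self):
        self.residuals = np.asarray(self.residuals, dtype=float)
        # loss is the sum of squared prediction errors, by contract
        assert np.isclose(self.loss, float(self.residuals @ self.residuals), rtol=1e-12, atol=0)


# ---------------------------------------------------------------------------
# continuous-time linear identification (srivc-style)
# ---------------------------------------------------------------------------


def _filter_deriv(x, t, den, order):
    """Apply the continuous filter s^order / den(s) to the sampled signal x.

    den is [1, d1, d2]; realized in state space and integrated with the
    exact first-order-hold discretization, so the result is exact for
    piecewise-linear x and O(h^2) otherwise.  Zero initial conditions: all
    synthetic records start from rest, and the identification contract
    assumes the test does too.
    """
    if order == 0:
        return _simulate_num(x, t, den, [0.0, 0.0, 1.0])
    if order == 1:
        return _simulate_num(x, t, den, [0.0, 1.0, 0.0])
    if order == 2:
        return _simulate_num(x, t, den, [1.0, 0.0, 0.0])
    raise ValueError("order must be 0, 1 or 2")


def _simulate_num(x, t, den, num):
    """Simulate (num0 s^2 + num1 s + num2)/(s^2 + d1 s + d2) on x (FOH exact)."""
    d1, d2 = den[1], den[2]
    n0, n1, n2 = num
    # observable canonical form with direct term n0
    b0 = n0
    beta1 = n1 - d1 * n0
    beta2 = (n2 - d2 * n0) - d1 * beta1
    from .models import _foh_states  # shared discretization helper

    A = np.array([[0.0, 1.0], [-d2, -d1]])
    B = np.array([[beta1], [beta2]])
    x = np.asarray(x, float)
    t = np.asarray(t, float)
    X = _foh_states(A, B, x, t, (0.0, 0.0))
    return X[:, 0] + b0 * x


def _project_stable(a1, a2):
    """Reflect unstable poles of s^2 + a1 s + a2 into the left half plane."""
    poles = np.roots([1.0, a1, a2])
    re = np.real(poles)
    if np.all(re < 0):
        return a1, a2, False
    scale = max(np.max(np.abs(poles)), 1e-6)
    fixed = []
    for p in poles:
        r = np.real(p)
        if r >= 0:
            r = -abs(r) if r > 0 else -1e-3 * scale
        fixed.append(complex(r, np.imag(p)))
    a1n = float(np.real(-(fixed[0] + fixed[1])))
    a2n = float(np.real(fixed[0] * fixed[1]))
    return a1n, a2n, True


def _svf_ls(u, y, t, cutoff):
    """State-variable-filter least squares at a given filter cutoff (rad/s)."""
    den = [1.0, 2.0 * cutoff, cutoff**2]
    yf0 = _filter_deriv(y, t, den, 0)
    yf1 = _filter_deriv(y, t, den, 1)
    yf2 = _filter_deriv(y, t, den, 2)
    uf1 = _filter_deriv(u, t, den, 1)
    uf2 = _filter_deriv(u, t, den, 2)
    Phi = np.column_stack([-yf1, -yf0, uf2, uf1])
    theta, _, rank, _ = np.linalg.lstsq(Phi, yf2, rcond=None)
    return theta, rank


def fit_linear_ct(
    dataset: TimeSeriesDataset,
    order=(2, 2),
    cfg: FitConfig | None = None,
) -> FitResult:
    """srivc-style continuous-time estimation of the two-Maxwell transfer function.

    Input is the signed strain, output the load.  Returns a FitResult whose
    ``params`` is a :class:`LinearTF`; non-convergence is flagged rather than
    raised and unstable interim estimates are projected back into the stable
    region with a warning.
    """
    if tuple(order) != (2, 2):
        raise NotImplementedError("only the second-order two-Maxwell structure is supported")
    cfg = cfg or FitConfig(structure="linear_tf")
    u = np.asarray(dataset.eps, float)
    y = np.asarray(dataset.y, float)
    t = np.asarray(dataset.t, float)
    if t.size < 8:
        raise ValueError("record too short to identify a second-order model")
    if np.allclose(u, u[0]):
        raise ExcitationError("input is constant: system unexcited")

    T = t[-1] - t[0]
    dt = np.min(np.diff(t))
    if cfg.svf_cutoff is not None:
        cutoffs = [cfg.svf_cutoff]
    else:
        # sweep cutoffs from the record scale up to a fraction of Nyquist and
        # keep the SVF-LS candidate whose simulated output fits best
        cutoffs = np.geomspace(4.0 / T, 0.5 * np.pi / dt, num=8)
    best = None
    for wc in cutoffs:
        try:
            theta, rank = _svf_ls(u, y, t, wc)
        except np.linalg.LinAlgError:
            continue
        if rank < 4:
            continue
        a1, a2, _ = _project_stable(theta[0], theta[1])
        cand = LinearTF(a1=a1, a2=a2, b0=theta[2], b1=theta[3])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            yhat = simulate_lti(cand, u, t).y
        err = float(np.sum((y - yhat) ** 2))
        if np.isfinite(err) and (best is None or err < best[0]):
            best = (err, cand)
    if best is None:
        raise ExcitationError("state-variable-filter initialization failed on all cutoffs")
    tf = best[1]

    theta = tf.as_theta()
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        a1, a2, projected = _project_stable(theta[0], theta[1])
        if projected:
            warnings.warn("unstable interim estimate projected to the stable region")
        den = [1.0, a1, a2]
        cur = LinearTF(a1=a1, a2=a2, b0=theta[2], b1=theta[3])
        xhat = simulate_lti(cur, u, t).y
        yf0 = _filter_deriv(y, t, den, 0)
        yf1 = _filter_deriv(y, t, den, 1)
        yf2 = _filter_deriv(y, t, den, 2)
        uf1 = _filter_deriv(u, t, den, 1)
        uf2 = _filter_deriv(u, t, den, 2)
        xf0 = _filter_deriv(xhat, t, den, 0)
        xf1 = _filter_deriv(xhat, t, den, 1)
        Phi = np.column_stack([-yf1, -yf0, uf2, uf1])
        Z = np.column_stack([-xf1, -xf0, uf2, uf1])
        M = Z.T @ Phi
        rhs = Z.T @ yf2
        try:
            theta_new = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            theta_new, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        step = np.linalg.norm(theta_new - theta) / max(np.linalg.norm(theta), 1e-300)
        theta = theta_new
        if step < cfg.tol:
            converged = True
            break
    a1, a2, projected = _project_stable(theta[0], theta[1])
    if projected:
        warnings.warn("final estimate projected to the stable region")
    tf = LinearTF(a1=a1, a2=a2, b0=float(theta[2]), b1=float(theta[3]))
    residuals = y - simulate_lti(tf, u, t).y
    return FitResult(
        params=tf,
        residuals=residuals,
        n_iter=n_iter,
        converged=converged,
        loss=float(residuals @ residuals),
    )


# ---------------------------------------------------------------------------
# grey-box prediction-error minimization (Levenberg-Marquardt)
# ---------------------------------------------------------------------------


def _default_init(structure):
    if structure == "model1":
        return {"C1": -1.0, "C2": 1.0, "g1": 1.0, "g2": 1.0, "tau1": 1.0, "tau2": 20.0}
    if structure == "model1_neohookean":
        return {"C1": 1.0, "g1": 1.0, "g2": 1.0, "tau1": 1.0, "tau2": 20.0}
    if structure == "hammerstein":
        return {"p0": 1.0, "p1": 1.0, "p2": 1.0, "g1": 1.0, "g2": 1.0, "tau1": 1.0, "tau2": 20.0}
    raise ValueError(structure)


def simulate_structure(structure: str, values: dict, dataset: TimeSeriesDataset) -> np.ndarray:
    """Forward-simulate a named structure on the dataset's input signal."""
    kin = dataset.kinematics()
    if structure == "linear_tf":
        tf = values if isinstance(values, LinearTF) else LinearTF(**values)
        return simulate_lti(tf, dataset.eps, dataset.t).y
    if structure in ("model1", "model1_neohookean"):
        vals = dict(values)
        if structure == "model1_neohookean":
            vals.setdefault("C2", 0.0)
        params = Model1Params(e0=dataset.e0, A0=dataset.A0, **vals)
        return simulate_model1(params, kin).y
    if structure == "hammerstein":
        params = Model2Params(**values)
        return simulate_hammerstein(params, kin).y
    raise ValueError(f"unknown structure {structure!r}")


def _params_record(structure, values, dataset):
    if structure in ("model1", "model1_neohookean"):
        vals = dict(values)
        if structure == "model1_neohookean":
            vals.setdefault("C2", 0.0)
        return Model1Params(e0=dataset.e0, A0=dataset.A0, **vals)
    if structure == "hammerstein":
        return Model2Params(**values)
    raise ValueError(structure)


def fit_greybox(dataset: TimeSeriesDataset, cfg: FitConfig) -> FitResult:
    """Levenberg-Marquardt prediction-error fit of a nonlinear structure.

    Minimizes sum_k (y_meas(t_k) - y_model(t_k))^2 over the free parameters;
    each residual evaluation is a full forward simulation.  Trial steps whose
    simulation fails (invalid taus, numerical blow-up) are rejected and the
    damping increased.  cfg.fixed holds the identifiability normalization;
    with every parameter fixed the residuals of the initial model are
    returned unchanged.
    """
    if cfg.structure not in _PARAM_NAMES:
        raise ValueError(f"fit_greybox does not handle structure {cfg.structure!r}")
    names = _PARAM_NAMES[cfg.structure]
    values = {**_default_init(cfg.structure), **dict(cfg.init)}
    unknown = set(values) - set(names)
    if unknown - {"C2"}:
        raise ValueError(f"init names {unknown} not in structure {cfg.structure!r}")
    free = [n for n in names if n not in cfg.fixed]
    y_meas = np.asarray(dataset.y, float)

    def residual(theta):
        vals = dict(values)
        vals.update(zip(free, theta))
        y_model = simulate_structure(cfg.structure, vals, dataset)
        if not np.all(np.isfinite(y_model)):
            raise FloatingPointError("non-finite model output")
        return y_meas - y_model

    if not free:
        r = residual(np.empty(0))
        loss = float(r @ r)
        return FitResult(
            params=_params_record(cfg.structure, values, dataset),
            residuals=r, n_iter=0, converged=True, loss=loss, loss_history=[loss],
        )

    theta = np.array([values[n] for n in free], dtype=float)
    theta, loss_history, converged, n_iter = _levenberg_marquardt(
        residual, theta, max_iter=cfg.max_iter, tol=cfg.tol
    )
    vals = dict(values)
    vals.update(zip(free, theta))
    r = residual(theta)
    return FitResult(
        params=_params_record(cfg.structure, vals, dataset),
        residuals=r,
        n_iter=n_iter,
        converged=converged,
        loss=float(r @ r),
        loss_history=loss_history,
    )


def _numeric_jacobian(residual, theta, r0):
    J = np.empty((r0.size, theta.size))
    for j in range(theta.size):
        h = np.sqrt(np.finfo(float).eps) * max(abs(theta[j]), 1.0)
        tp = theta.copy()
        tp[j] += h
        try:
            rj = residual(tp)
        except (ValueError, FloatingPointError, RuntimeError):
            tp[j] = theta[j] - h
            rj = residual(tp)
            h = -h
        J[:, j] = (rj - r0) / h
    return J


def _levenberg_marquardt(residual, theta0, max_iter=100, tol=1e-9):
    """Damped Gauss-Newton with multiplicative damping adaptation.

    Accepted steps never increase the loss; steps whose residual evaluation
    raises or returns non-finite values are rejected like uphill steps.
    Convergence: relative loss decrease below tol on an accepted step, or a
    vanishing gradient.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    r = residual(theta)
    loss = float(r @ r)
    loss_history = [loss]
    lam = 1e-3
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        J = _numeric_jacobian(residual, theta, r)
        A = J.T @ J
        g = J.T @ r
        if np.linalg.norm(g, np.inf) < 1e-14 * max(loss, 1.0):
            converged = True
            break
        diagA = np.clip(np.diag(A), 1e-14, None)
        accepted = False
        for _ in range(40):
            try:
                step = np.linalg.solve(A + lam * np.diag(diagA), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = theta + step
            try:
                r_new = residual(trial)
                loss_new = float(r_new @ r_new)
                ok = np.isfinite(loss_new)
            except (ValueError, FloatingPointError, RuntimeError):
                ok = False
            if ok and loss_new < loss:
                rel_drop = (loss - loss_new) / max(loss, 1e-300)
                theta, r, loss = trial, r_new, loss_new
                loss_history.append(loss)
                lam = max(lam / 10.0, 1e-14)
                accepted = True
                if rel_drop < tol:
                    converged = True
                break
            lam *= 10.0
            if lam > 1e14:
                break
        if not accepted:
            # no downhill step found at any damping: treat as converged-in-place
            converged = loss_history[-1] == loss and len(loss_history) > 1
            break
        if converged:
            break
    return theta, loss_history, converged, n_iter


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate(structure: str, params, dataset: TimeSeriesDataset, ident_labels=()):
    """Pure forward validation: simulate the identified model on held-out data.

    No re-fitting happens here.  ``ident_labels`` lists the labels of the
    identification samples; validating on one of them is refused.  Returns
    (y_pred, FIT%).
    """
    if dataset.label and dataset.label in set(ident_labels):
        raise ValueError(
            f"dataset {dataset.label!r} was used for identification; "
            "validation requires a disjoint sample"
        )
    if isinstance(params, LinearTF):
        values = params
    else:
        if hasattr(params, "__dataclass_fields__"):
            params = {k: getattr(params, k) for k in params.__dataclass_fields__}
        keep = set(_PARAM_NAMES.get(structure, ())) | {"C2"}
        if structure == "linear_tf":
            keep = {"a1", "a2", "b0", "b1"}
        values = {k: v for k, v in dict(params).items() if k in keep}
    y_pred = simulate_structure(structure, values, dataset)
    return y_pred, fit_percent(y_pred, dataset.y)
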