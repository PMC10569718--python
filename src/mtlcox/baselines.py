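"""Single-task competitor models: unpenalized Cox, Cox-LASSO, Weibull PH.

* ``fit_cox_newton`` — Newton-Raphson on the Breslow-tie negative log partial
  likelihood with step-halving and a ridge jitter for near-singular Hessians.
* ``fit_cox_lasso`` — L1-penalized Cox in Lagrangian form; reuses the
  multitask proximal-gradient solver with K = 1, where the L2,1 row penalty
  reduces exactly to the L1 norm.
* ``fit_weibull_ph`` — parametric Weibull proportional-hazards regression,
  h(t|x) = shape * scale * t^(shape-1) * exp(theta'x), fitted by maximum
  likelihood on log-parameterized shape/scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import mtl_solver
from .cox_core import CoxLikelihoodContext, gradient, hessian, neg_log_partial_likelihood
from .data_model import FeatureRegistry, MultiTaskDataset, SurvivalTask

__all__ = [
    "NewtonResult",
    "CoxLassoModel",
    "WeibullPHModel",
    "fit_cox_newton",
    "fit_cox_lasso",
    "fit_weibull_ph",
]

_COEF_CAP = 10.0  # |beta| beyond this signals monotone likelihood / separation


@dataclass
class NewtonResult:
    coefficients: np.ndarray
    converged: bool
    n_iter: int
    final_gradient_norm: float
    nll: float


def fit_cox_newton(
    task: SurvivalTask,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 1e-8,
) -> NewtonResult:
    """Maximize the Cox partial likelihood by damped Newton-Raphson.

    Iterates beta <- beta - step * H^{-1} g with step-halving until the NLL
    decreases; stops when the gradient norm drops below ``tol``.  A ridge
    jitter stabilizes (near-)singular Hessians; coefficients running past a
    magnitude cap are truncated with a separation warning.
    """
    ctx = CoxLikelihoodContext.from_task(task)
    p = task.n_features
    beta = np.zeros(p)
    nll = neg_log_partial_likelihood(beta, ctx)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = gradient(beta, ctx)
        gnorm = float(np.linalg.norm(g))
        if gnorm < tol:
            converged = True
            break
        H = hessian(beta, ctx)
        try:
            direction = np.linalg.solve(H + ridge * np.eye(p), g)
        except np.linalg.LinAlgError:
            direction = np.linalg.solve(H + 1e-4 * np.eye(p), g)
        step = 1.0
        for _ in range(40):
            cand = beta - step * direction
            cand_nll = neg_log_partial_likelihood(cand, ctx)
            if cand_nll <= nll + 1e-14:
                break
            step *= 0.5
        else:
            converged = gnorm < 1e-6
            break
        beta, nll = cand, cand_nll
        if np.any(np.abs(beta) > _COEF_CAP):
            warnings.warn(
                f"task {task.task_name!r}: coefficient magnitude exceeded "
                f"{_COEF_CAP}; likely separation / monotone likelihood — capped"
            )
            beta = np.clip(beta, -_COEF_CAP, _COEF_CAP)
            nll = neg_log_partial_likelihood(beta, ctx)
            break
    g = gradient(beta, ctx)
    gnorm = float(np.linalg.norm(g))
    return NewtonResult(
        coefficients=beta,
        converged=converged or gnorm < tol,
        n_iter=it,
        final_gradient_norm=gnorm,
        nll=float(neg_log_partial_likelihood(beta, ctx)),
    )


# ---------------------------------------------------------------------------
# Cox-LASSO
# ---------------------------------------------------------------------------


@dataclass
class CoxLassoModel:
    coefficients: np.ndarray
    penalty: float
    converged: bool
    n_iter: int


def _as_singleton_dataset(task: SurvivalTask) -> MultiTaskDataset:
    registry = FeatureRegistry(
        tuple(f"x{j}" for j in range(task.n_features)),
        tuple("continuous" for _ in range(task.n_features)),
    )
    return MultiTaskDataset([task], registry)


def fit_cox_lasso(
    task: SurvivalTask,
    penalty: float,
    options: "mtl_solver.FitOptions | None" = None,
    *,
    B0: np.ndarray | None = None,
) -> CoxLassoModel:
    """L1-penalized Cox regression in Lagrangian form.

    Minimizes NLL(beta)/N + penalty * ||beta||_1 — the penalized counterpart
    of the constrained sum|beta_p| <= s formulation, which traces the same
    solution path.  Solved by the K=1 reduction of the multitask proximal
    solver (row group soft-thresholding collapses to scalar soft-
    thresholding).
    """
    ds = _as_singleton_dataset(task)
    res = mtl_solver.fit(ds, penalty, options, B0=B0)
    return CoxLassoModel(
        coefficients=res.coefficients.values[:, 0],
        penalty=penalty,
        converged=res.converged,
        n_iter=res.n_iter,
    )


# ---------------------------------------------------------------------------
# Weibull proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class WeibullPHModel:
    """Weibull PH fit: h(t|x) = shape * scale * t^(shape-1) * exp(theta'x).

    ``shape`` is the Weibull shape (1 = exponential), ``scale`` the rate-like
    scale of the baseline hazard h0(t) = shape * scale * t^(shape-1); the
    intercept beta0 = -log(scale)/shape expresses the same baseline on the
    location scale.  ``coefficients`` (theta) carry log-hazard-ratio
    interpretation, directly comparable with Cox coefficients.
    """

    shape: float
    scale: float
    coefficients: np.ndarray
    converged: bool
    log_likelihood: float

    @property
    def intercept(self) -> float:
        return -np.log(self.scale) / self.shape

    def cumulative_hazard(self, t: np.ndarray, x: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        eta = np.atleast_2d(x) @ self.coefficients
        return self.scale * t**self.shape * np.exp(eta)


def _weibull_negloglik(params: np.ndarray, t, delta, X):
    a, b = params[0], params[1]  # log shape, log scale
    theta = params[2:]
    shape, scale = np.exp(a), np.exp(b)
    eta = X @ theta
    logt = np.log(t)
    ll = np.sum(delta * (a + b + (shape - 1.0) * logt + eta))
    ll -= np.sum(scale * np.exp(shape * logt + eta))
    return -ll


def _weibull_grad(params: np.ndarray, t, delta, X):
    a, b = params[0], params[1]
    theta = params[2:]
    shape, scale = np.exp(a), np.exp(b)
    eta = X @ theta
    logt = np.log(t)
    H = scale * np.exp(shape * logt + eta)  # cumulative hazard per subject
    d_a = np.sum(delta * (1.0 + shape * logt)) - np.sum(H * shape * logt)
    d_b = np.sum(delta) - np.sum(H)
    d_theta = X.T @ (delta - H)
    return -np.concatenate([[d_a], [d_b], d_theta])


def fit_weibull_ph(task: SurvivalTask, *, max_iter: int = 500) -> WeibullPHModel:
    """Maximum-likelihood Weibull PH regression.

    The censored log-likelihood sum delta_i log h(t_i|x_i) - sum H(t_i|x_i)
    is maximized by BFGS over (log shape, log scale, theta); the log
    parameterization keeps positivity unconstrained.  Non-convergence is
    flagged on the returned model, not raised.
    """
    t = task.time
    delta = task.event.astype(float)
    X = task.features
    n_ev = delta.sum()
    if n_ev == 0:
        raise ValueError("Weibull PH requires at least one event")
    # moment-flavored start: exponential rate = events / total time at risk
    x0 = np.concatenate([[0.0, np.log(n_ev / t.sum())], np.zeros(task.n_features)])
    res = optimize.minimize(
        _weibull_negloglik,
        x0,
        args=(t, delta, X),
        jac=_weibull_grad,
        method="BFGS",
        options={"maxiter": max_iter, "gtol": 1e-8},
    )
    shape, scale = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    # BFGS sometimes reports precision loss at an already-stationary point
    gnorm = float(np.linalg.norm(_weibull_grad(res.x, t, delta, X)))
    converged = bool(res.success) or gnorm < 1e-3 * max(1.0, n_ev)
    return WeibullPHModel(
        shape=shape,
        scale=scale,
        coefficients=res.x[2:],
        converged=converged,
        log_likelihood=-float(res.fun),
    )
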