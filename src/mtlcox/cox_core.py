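"""Cox partial-likelihood machinery for a single task.

Implements the negative log partial likelihood, its gradient and Hessian
(Breslow handling of tied event times throughout), the Breslow cumulative
baseline-hazard estimator, and individual absolute-risk prediction under the
proportional-hazards model

    h(t | x) = h0(t) * exp(x' beta).

All risk-set sums are accumulated as reverse cumulative sums over the
time-sorted subjects, so one likelihood/gradient evaluation costs O(N * P).
Exponentials are stabilized by subtracting the maximum linear predictor
(log-sum-exp), so arbitrarily large |x' beta| cannot overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import RiskSetIndex, SurvivalTask, build_risk_sets

__all__ = [
    "CoxLikelihoodContext",
    "BaselineHazard",
    "neg_log_partial_likelihood",
    "gradient",
    "hessian",
    "breslow_baseline",
    "absolute_risk",
]


@dataclass
class CoxLikelihoodContext:
    """Precomputed sorted view of one task used by every likelihood call.

    The feature matrix is stored in time-sorted order once so that repeated
    evaluations during optimization avoid re-sorting.
    """

    task: SurvivalTask
    risk_sets: RiskSetIndex
    X_sorted: np.ndarray  # (N, P), rows in ascending-time order

    @classmethod
    def from_task(cls, task: SurvivalTask) -> "CoxLikelihoodContext":
        rs = build_risk_sets(task)
        return cls(task=task, risk_sets=rs, X_sorted=task.features[rs.order])

    @property
    def n_subjects(self) -> int:
        return self.task.n_subjects

    @property
    def n_features(self) -> int:
        return self.task.n_features


def _rev_cumsum(a: np.ndarray) -> np.ndarray:
    """Suffix sums along axis 0: out[i] = a[i] + a[i+1] + ... + a[-1]."""
    return np.cumsum(a[::-1], axis=0)[::-1]


def _stable_weights(eta: np.ndarray) -> tuple[np.ndarray, float]:
    """exp(eta - max(eta)) and the shift, guarding the log-sum-exp."""
    c = float(np.max(eta)) if eta.size else 0.0
    return np.exp(eta - c), c


def neg_log_partial_likelihood(beta: np.ndarray, ctx: CoxLikelihoodContext) -> float:
    """Negative log partial likelihood at ``beta`` (Breslow ties).

    -sum_{i: event} [ x_i' beta - log sum_{s in R(T_i)} exp(x_s' beta) ],
    where tied events at one time reuse the full risk-set denominator.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    rs = ctx.risk_sets
    eta = ctx.X_sorted @ beta
    # running log-sum-exp over the time-sorted suffix: exact for any |eta|
    log_denom = np.logaddexp.accumulate(eta[::-1])[::-1][rs.group_start]
    value = float(np.sum(rs.n_events_at * log_denom) - np.sum(eta[rs.event_positions]))
    if not np.isfinite(value):
        raise FloatingPointError("non-finite partial likelihood value")
    return value


def gradient(beta: np.ndarray, ctx: CoxLikelihoodContext) -> np.ndarray:
    """Gradient of the negative log partial likelihood.

    Each event contributes minus (its covariates minus the exp(eta)-weighted
    mean covariate over its risk set).
    """
    beta = np.asarray(beta, dtype=float).ravel()
    rs = ctx.risk_sets
    X = ctx.X_sorted
    eta = X @ beta
    w, _ = _stable_weights(eta)
    suffix_w = _rev_cumsum(w)[rs.group_start]
    suffix_xw = _rev_cumsum(X * w[:, None])[rs.group_start]
    weighted_means = suffix_xw / suffix_w[:, None]
    g = (rs.n_events_at[:, None] * weighted_means).sum(axis=0) - X[rs.event_positions].sum(axis=0)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient")
    return g


def hessian(beta: np.ndarray, ctx: CoxLikelihoodContext) -> np.ndarray:
    """Hessian of the negative log partial likelihood (P x P, symmetric PSD).

    Sum over events of the exp(eta)-weighted covariate covariance within the
    risk set.  Costs O(N * P^2); meant for the modest feature counts this
    package targets.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    rs = ctx.risk_sets
    X = ctx.X_sorted
    eta = X @ beta
    w, _ = _stable_weights(eta)
    suffix_w = _rev_cumsum(w)[rs.group_start]
    suffix_xw = _rev_cumsum(X * w[:, None])[rs.group_start]
    outer = X[:, :, None] * X[:, None, :] * w[:, None, None]
    suffix_xxw = _rev_cumsum(outer)[rs.group_start]
    mean = suffix_xw / suffix_w[:, None]
    cov = suffix_xxw / suffix_w[:, None, None] - mean[:, :, None] * mean[:, None, :]
    H = np.einsum("i,ijk->jk", rs.n_events_at.astype(float), cov)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Baseline hazard and absolute risk
# ---------------------------------------------------------------------------


@dataclass
class BaselineHazard:
    """Step-function cumulative baseline hazard H0(t) from Breslow estimation.

    H0 jumps at each distinct event time; H0(t) = 0 before the first event
    time.  Baseline survival is S0(t) = exp(-H0(t)).
    """

    task_name: str
    event_times: np.ndarray  # ascending
    cumulative_hazard: np.ndarray  # nondecreasing, same length
    max_observed_time: float = np.inf

    def cumhaz_at(self, t: float | np.ndarray) -> np.ndarray:
        """H0 evaluated at times t (right-continuous step function)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        padded = np.concatenate([[0.0], self.cumulative_hazard])
        return padded[idx]

    def survival_at(self, t: float | np.ndarray) -> np.ndarray:
        return np.exp(-self.cumhaz_at(t))

    def to_csv(self, path: str | Path) -> None:
        arr = np.column_stack([self.event_times, self.cumulative_hazard])
        np.savetxt(
            path, arr, delimiter=",", header="time,cumulative_hazard", comments=""
        )

    @classmethod
    def from_csv(cls, path: str | Path, task_name: str = "") -> "BaselineHazard":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(task_name, arr[:, 0], arr[:, 1])


def breslow_baseline(beta: np.ndarray, ctx: CoxLikelihoodContext) -> BaselineHazard:
    """Breslow estimator of the cumulative baseline hazard at a fitted beta.

    H0(t) = sum_{T_i <= t} d_i / sum_{s in R(T_i)} exp(x_s' beta).
    With beta = 0 and no ties this is exactly the Nelson-Aalen estimator.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    rs = ctx.risk_sets
    eta = ctx.X_sorted @ beta
    w, c = _stable_weights(eta)
    suffix = _rev_cumsum(w)[rs.group_start]
    increments = rs.n_events_at * np.exp(-c - np.log(suffix))
    return BaselineHazard(
        task_name=ctx.task.task_name,
        event_times=rs.event_times.copy(),
        cumulative_hazard=np.cumsum(increments),
        max_observed_time=float(ctx.task.time.max()),
    )


def absolute_risk(
    subject_features: np.ndarray,
    beta: np.ndarray,
    baseline: BaselineHazard,
    horizon: float,
) -> np.ndarray:
    """Probability of the event by ``horizon`` years for given covariates.

    AR = 1 - exp(-H0(horizon) * exp(x' beta)), the exact cumulative-incidence
    transform under proportional hazards.  Accepts a single feature vector or
    a matrix of subjects (rows).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if horizon > baseline.max_observed_time:
        warnings.warn(
            f"horizon {horizon} exceeds the last observed time "
            f"{baseline.max_observed_time}; absolute risk held at the last step"
        )
    x = np.atleast_2d(np.asarray(subject_features, dtype=float))
    eta = x @ np.asarray(beta, dtype=float).ravel()
    h0 = baseline.cumhaz_at(min(horizon, baseline.max_observed_time))
    ar = 1.0 - np.exp(-h0 * np.exp(eta))
    return ar if np.asarray(subject_features).ndim > 1 else ar[0]
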