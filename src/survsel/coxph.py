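"""Cox proportional-hazards machinery shared by all selectors and predictors.

The hazard model is ``h(t|x) = h0(t) * exp(x'beta)`` with no intercept (any
constant is absorbed by the baseline hazard). Estimation maximizes Cox's
partial likelihood; tied event times are handled with the Breslow
approximation throughout (tied events share one risk-set denominator), and
the baseline cumulative hazard is the matching Breslow step-function
estimator, right-continuous with jumps at distinct event times.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .data import SurvivalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "SurvCurveSet",
    "neg_log_partial_likelihood",
    "neg_log_partial_likelihood_eta",
    "fit_cox",
    "breslow_baseline",
    "predict_survival",
    "subject_gradient_weights",
]


@dataclasses.dataclass
class CoxFit:
    """Fitted Cox model: coefficients plus Breslow baseline cumulative hazard."""

    beta: np.ndarray
    feature_names: list[str]
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    n_iter: int
    converged: bool
    log_partial_likelihood: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.baseline_cumhaz) < -1e-12) or np.any(
            self.baseline_cumhaz < 0
        ):
            raise ValueError("baseline cumulative hazard must be non-negative, non-decreasing")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("non-finite coefficients")

    def to_dict(self) -> dict:
        return {
            "beta": dict(zip(self.feature_names, np.asarray(self.beta).tolist())),
            "baseline_times": np.asarray(self.baseline_times).tolist(),
            "baseline_cumhaz": np.asarray(self.baseline_cumhaz).tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "log_partial_likelihood": self.log_partial_likelihood,
        }


@dataclasses.dataclass
class SurvCurveSet:
    """Predicted survival curves S(t | x_i) on a common time grid."""

    eval_times: np.ndarray
    surv: np.ndarray  # (n_subjects, n_times), rows non-increasing, values in [0,1]

    def __post_init__(self) -> None:
        self.eval_times = np.asarray(self.eval_times, dtype=float)
        self.surv = np.atleast_2d(np.asarray(self.surv, dtype=float))
        if np.any(self.surv < -1e-12) or np.any(self.surv > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(self.surv, axis=1) > 1e-10):
            raise ValueError("survival curves must be non-increasing in time")

    def marginal(self) -> np.ndarray:
        """Cohort-average survival curve."""
        return self.surv.mean(axis=0)

    def at_time(self, t: float) -> np.ndarray:
        """Per-subject survival at the grid point nearest-below t (step lookup)."""
        k = int(np.searchsorted(self.eval_times, t, side="right")) - 1
        if k < 0:
            return np.ones(self.surv.shape[0])
        return self.surv[:, k]


def _event_blocks(data: SurvivalDataset):
    """Sorted times plus per-distinct-event-time bookkeeping (cached per dataset).

    Returns (order, unique event times t_k, d_k event counts, and for each
    t_k the index into the ascending-sorted arrays of the first subject with
    Y >= t_k — the risk set R_k is the suffix from that index).
    """
    cached = getattr(data, "_event_blocks_cache", None)
    if cached is not None:
        return cached
    order = np.argsort(data.times, kind="stable")
    t_sorted = data.times[order]
    e_sorted = data.events[order]
    uniq_event_times, d = np.unique(t_sorted[e_sorted == 1], return_counts=True)
    start = np.searchsorted(t_sorted, uniq_event_times, side="left")
    out = (order, t_sorted, e_sorted, uniq_event_times, d, start)
    data._event_blocks_cache = out
    return out


def neg_log_partial_likelihood_eta(eta: np.ndarray, data: SurvivalDataset) -> float:
    """Breslow-ties negative log partial likelihood / n, from the linear predictor."""
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("linear predictor must be finite")
    order, t_sorted, e_sorted, ut, d, start = _event_blocks(data)
    eta_s = eta[order]
    shift = eta_s.max()  # overflow guard: denominators shifted by max linear predictor
    w = np.exp(eta_s - shift)
    # suffix sums of w give risk-set denominators
    suffix = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    ll = eta_s[e_sorted == 1].sum() - d @ (shift + np.log(suffix[start]))
    out = -ll / data.n
    if not np.isfinite(out):
        raise FloatingPointError("non-finite partial likelihood")
    return float(out)


def neg_log_partial_likelihood(beta: np.ndarray, data: SurvivalDataset) -> float:
    """Negative log partial likelihood divided by n, Breslow ties.

    -(1/n) * sum over distinct event times t_k of
    [ sum_{events at t_k} x_i'beta  -  d_k * log sum_{l in R_k} exp(x_l'beta) ].
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    return neg_log_partial_likelihood_eta(data.covariates @ beta, data)


def subject_gradient_weights_eta(
    eta: np.ndarray, data: SurvivalDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject gradient and curvature of the log partial likelihood
    with respect to the linear predictor (unnormalized).

    u_i = delta_i - exp(eta_i) * A(Y_i)      (the martingale residual)
    w_i = exp(eta_i) * A(Y_i) - exp(2*eta_i) * B(Y_i)
    with A(t) = sum_{t_k <= t} d_k / S_k, B(t) = sum_{t_k <= t} d_k / S_k^2,
    S_k the Breslow risk-set denominator at event time t_k.
    """
    order, t_sorted, e_sorted, ut, d, start = _event_blocks(data)
    eta = np.asarray(eta, dtype=float)[order]
    shift = eta.max()
    w = np.exp(eta - shift)
    suffix = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    S = suffix[start]  # shifted-scale denominators
    incA = np.concatenate([[0.0], np.cumsum(d / S)])
    incB = np.concatenate([[0.0], np.cumsum(d / S**2)])
    pos = np.searchsorted(ut, t_sorted, side="right")
    A = incA[pos]
    B = incB[pos]
    u_sorted = e_sorted - w * A
    w_sorted = w * A - (w**2) * B
    u = np.empty(data.n)
    wdiag = np.empty(data.n)
    u[order] = u_sorted
    wdiag[order] = w_sorted
    return u, wdiag


def subject_gradient_weights(
    beta: np.ndarray, data: SurvivalDataset
) -> tuple[np.ndarray, np.ndarray]:
    """As :func:`subject_gradient_weights_eta`, from a coefficient vector."""
    beta = np.asarray(beta, dtype=float)
    return subject_gradient_weights_eta(data.covariates @ beta, data)


def _gradient_hessian(beta: np.ndarray, data: SurvivalDataset):
    """Analytic gradient and Hessian of neg_log_partial_likelihood (per-n scale)."""
    beta = np.asarray(beta, dtype=float)
    X = data.covariates
    n, p = X.shape
    order, t_sorted, e_sorted, ut, d, start = _event_blocks(data)
    Xs = X[order]
    eta = Xs @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    # accumulate suffix sums S0, S1, S2 walking event times from the latest down
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    hi = n
    for k in range(len(ut) - 1, -1, -1):
        lo = start[k]
        for i in range(hi - 1, lo - 1, -1):
            S0 += w[i]
            S1 += w[i] * Xs[i]
            S2 += w[i] * np.outer(Xs[i], Xs[i])
        hi = lo
        at_k = (t_sorted == ut[k]) & (e_sorted == 1)
        xbar = S1 / S0
        grad -= Xs[at_k].sum(axis=0) - d[k] * xbar
        hess += d[k] * (S2 / S0 - np.outer(xbar, xbar))
    return grad / n, hess / n


def fit_cox(data: SurvivalDataset, ridge_eps: float = 1e-9) -> CoxFit:
    """Newton–Raphson fit with step halving.

    Converged when the relative objective change < 1e-9 or the gradient
    max-norm < 1e-6, within 100 iterations. A coefficient norm above 50
    flags monotone likelihood (quasi-complete separation).
    """
    if ridge_eps < 0:
        raise ValueError("ridge_eps must be >= 0")
    p = data.p
    beta = np.zeros(p)
    obj = neg_log_partial_likelihood(beta, data)
    n_iter = 0
    converged = False
    for n_iter in range(1, 101):
        grad, hess = _gradient_hessian(beta, data)
        if np.max(np.abs(grad)) < 1e-6:
            converged = True
            break
        step = np.linalg.solve(hess + ridge_eps * np.eye(p), -grad)
        # step halving on the objective
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            try:
                new_obj = neg_log_partial_likelihood(cand, data)
            except FloatingPointError:
                new_obj = np.inf
            if new_obj < obj + 1e-15:
                break
            scale *= 0.5
        else:
            converged = True  # no descent direction left: at a (numerical) optimum
            break
        beta = beta + scale * step
        rel = abs(obj - new_obj) / max(abs(obj), 1e-12)
        obj = new_obj
        if rel < 1e-9:
            converged = True
            break
    if not converged:
        logger.warning("Cox fit did not converge in %d iterations", n_iter)
    if np.linalg.norm(beta) > 50:
        logger.warning("coefficient norm %.1f > 50: possible monotone likelihood", np.linalg.norm(beta))
    bt, bh = breslow_baseline(beta, data)
    return CoxFit(
        beta=beta,
        feature_names=list(data.feature_names),
        baseline_times=bt,
        baseline_cumhaz=bh,
        n_iter=n_iter,
        converged=converged,
        log_partial_likelihood=-obj * data.n,
    )


def breslow_baseline(
    beta: np.ndarray, data: SurvivalDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow cumulative baseline hazard at the distinct event times.

    H0(t) = sum_{event times t_k <= t} d_k / sum_{l in R_k} exp(x_l'beta).
    """
    beta = np.asarray(beta, dtype=float)
    order, t_sorted, e_sorted, ut, d, start = _event_blocks(data)
    eta = (data.covariates @ beta)[order]
    shift = eta.max()
    w = np.exp(eta - shift)
    suffix = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    S = suffix[start] * np.exp(shift)
    return ut.copy(), np.cumsum(d / S)


def cumhaz_at(
    baseline_times: np.ndarray, baseline_cumhaz: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Right-continuous step-function lookup of H0 at times t (H0=0 before the first jump)."""
    t = np.asarray(t, dtype=float)
    idx = np.searchsorted(baseline_times, t, side="right") - 1
    out = np.where(idx >= 0, baseline_cumhaz[np.clip(idx, 0, None)], 0.0)
    return out


def predict_survival(
    fit: CoxFit, X_new: np.ndarray, eval_times: np.ndarray
) -> SurvCurveSet:
    """Predicted curves S(t|x) = exp(-H0(t) * exp(x'beta)) on a sorted grid."""
    eval_times = np.asarray(eval_times, dtype=float)
    if np.any(eval_times < 0) or np.any(np.diff(eval_times) < 0):
        raise ValueError("eval_times must be non-negative and sorted")
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(fit.beta):
        raise ValueError("X_new column count does not match the fit")
    H0 = cumhaz_at(fit.baseline_times, fit.baseline_cumhaz, eval_times)
    risk = np.exp(X_new @ fit.beta)
    surv = np.exp(-np.outer(risk, H0))
    return SurvCurveSet(eval_times=eval_times, surv=np.clip(surv, 0.0, 1.0))
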