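"""Cox proportional hazards fitting, Kaplan-Meier and log-rank utilities.

The partial likelihood is maximized by Newton-Raphson with step-halving,
using the Breslow approximation for tied event times (generated survival
times are continuous, so ties are rare; with no ties Breslow and Efron
coincide). Kaplan-Meier estimation and the log-rank test are delegated to
lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .normalize import NormalizationParams, apply_normalizer, fit_normalizer


@dataclass
class CoxFit:
    """A fitted Cox model.

    ``coefficients`` are log hazard ratios on the (standardized, if
    ``normalization`` is set) covariate scale. ``covariance`` is the
    inverse observed information; ``se`` its diagonal square root.
    """

    coefficients: np.ndarray
    se: np.ndarray
    covariance: np.ndarray
    log_partial_likelihood: float
    n_iterations: int
    converged: bool
    max_gradient: float
    normalization: NormalizationParams | None = None
    names: tuple[str, ...] | None = None
    tie_handling: str = "breslow"
    ridged: bool = False


def _breslow_quantities(X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray):
    """Log partial likelihood, gradient and negative Hessian (information).

    Rows must be pre-sorted by ascending time. Tied times share the risk
    set anchored at the first row of the tie group (Breslow).
    """
    n, p = X.shape
    lp = X @ beta
    lp = lp - lp.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(lp)

    # extreme trial steps can underflow whole risk sets; the resulting
    # non-finite log likelihood is caught by the caller's step-halving
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        # reverse cumulative sums: S0[i] = sum_{j>=i} w_j etc.
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
        s2 = np.cumsum((w[:, None, None] * X[:, :, None] * X[:, None, :])[::-1], axis=0)[::-1]

        # anchor tied times at the first index of their group
        first = np.zeros(n, dtype=int)
        first[1:] = np.where(time[1:] == time[:-1], 0, np.arange(1, n))
        first = np.maximum.accumulate(first)

        ev = np.nonzero(event == 1)[0]
        f = first[ev]
        s0e = s0[f]
        s1e = s1[f]
        s2e = s2[f]
        xbar = s1e / s0e[:, None]

        loglik = float(lp[ev].sum() - np.log(s0e).sum())
        grad = X[ev].sum(axis=0) - xbar.sum(axis=0)
        info = (s2e / s0e[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", xbar, xbar)
    return loglik, grad, info


def fit_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    *,
    names: tuple[str, ...] | None = None,
    normalize: bool = True,
    tol: float = 1e-7,
    max_iter: int = 100,
) -> CoxFit:
    """Fit a Cox model by Newton-Raphson with step-halving.

    With ``normalize=True`` (default) covariates are standardized
    internally and the parameters stored on the fit, so
    :func:`predict_risk` re-applies the same transform to new data.
    Non-convergence (e.g. separation) is flagged rather than raised;
    singular information matrices fall back to a small ridge and set
    ``ridged``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).astype(int).ravel()
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    if event.sum() < 1:
        raise ValueError("need at least one observed event")

    norm = None
    if normalize:
        norm = fit_normalizer(X)
        X = apply_normalizer(norm, X)

    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]

    beta = np.zeros(p)
    loglik, grad, info = _breslow_quantities(Xs, ts, es, beta)
    converged = False
    ridged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            ridged = True
            step = np.linalg.solve(info + 1e-6 * np.eye(p), grad)
        # step-halving: the log partial likelihood must not decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            new_ll, new_grad, new_info = _breslow_quantities(Xs, ts, es, cand)
            if np.isfinite(new_ll) and new_ll >= loglik - 1e-12:
                break
            scale *= 0.5
        else:
            break
        beta, loglik, grad, info = cand, new_ll, new_grad, new_info
        if np.max(np.abs(grad)) < tol:
            converged = True
            break

    if ridged:
        warnings.warn("Cox information matrix was singular; ridge fallback used", stacklevel=2)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.inv(info + 1e-6 * np.eye(p))
        ridged = True
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return CoxFit(
        coefficients=beta,
        se=se,
        covariance=cov,
        log_partial_likelihood=loglik,
        n_iterations=it,
        converged=converged,
        max_gradient=float(np.max(np.abs(grad))),
        normalization=norm,
        names=names,
        ridged=ridged,
    )


def predict_risk(fit: CoxFit, X: np.ndarray) -> np.ndarray:
    """Linear predictor (prognostic index) for new data; higher = higher hazard."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != fit.coefficients.shape[0]:
        raise ValueError(
            f"expected {fit.coefficients.shape[0]} covariate columns, got {X.shape[1]}"
        )
    if fit.normalization is not None:
        X = apply_normalizer(fit.normalization, X)
    return X @ fit.coefficients


def kaplan_meier(time: np.ndarray, event: np.ndarray) -> KaplanMeierFitter:
    """Product-limit survival estimate (a fitted lifelines ``KaplanMeierFitter``)."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event).astype(int))
    return kmf


def five_year_rate(km: KaplanMeierFitter, horizon: float = 5.0) -> tuple[float, bool]:
    """Survival probability at ``horizon`` years.

    If follow-up ends before the horizon the rate at the last observed
    time is returned with ``truncated=True``.
    """
    last = float(km.timeline[-1])
    truncated = last < horizon
    at = min(horizon, last)
    return float(km.predict(at)), truncated


def log_rank(
    time_a: np.ndarray,
    event_a: np.ndarray,
    time_b: np.ndarray,
    event_b: np.ndarray,
) -> tuple[float, float]:
    """Two-sided log-rank test between two groups: (chi2 on 1 d.f., p-value)."""
    res = logrank_test(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)
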