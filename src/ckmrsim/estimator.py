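"""Maximum pseudo-likelihood fitting of sex-specific adult abundance.

The two abundances are optimised on the log scale (they are positive and the
likelihood surface is close to log-normal), standard errors come from the
inverse negative Hessian at the optimum (central finite differences on the
log scale, delta-method transform back to the abundance scale), and 95%
intervals use the standard log-normal construction

    C = exp(z_0.975 * sqrt(ln(1 + (se / N)^2))),   CI = (N / C, N * C).

Convergence failures (infeasible likelihood, optimiser failure, indefinite
Hessian, non-identifiable sex) are recorded in the result, never raised, so
a scenario grid always completes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .ckmr_likelihood import AggregatedComparisons, pseudo_log_likelihood

__all__ = ["FitResult", "fit_ckmr", "lognormal_ci"]

#: relative multipliers for the retry ladder of starting values
_START_LADDER = (1.0, 2.0, 0.5, 4.0)
_HESS_STEP = 1e-4


@dataclass(frozen=True)
class FitResult:
    """Point estimates, uncertainty and diagnostics of one model fit."""

    converged: bool
    failure_reason: Optional[str] = None   # infeasible_likelihood | optimizer_failure | non_identifiable
    N_f_hat: Optional[float] = None
    N_m_hat: Optional[float] = None
    se_f: Optional[float] = None
    se_m: Optional[float] = None
    ci_f: Optional[tuple[float, float]] = None
    ci_m: Optional[tuple[float, float]] = None
    loglik: Optional[float] = None


def lognormal_ci(point: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Log-normal confidence interval around a positive point estimate."""
    if point <= 0 or se < 0:
        raise ValueError("point must be positive and se non-negative")
    z = norm.ppf(0.5 + level / 2.0)
    c = np.exp(z * np.sqrt(np.log1p((se / point) ** 2)))
    return float(point / c), float(point * c)


def _neg_ll(x: np.ndarray, agg: AggregatedComparisons) -> float:
    ll = pseudo_log_likelihood(float(np.exp(x[0])), float(np.exp(x[1])), agg)
    return np.inf if ll == -np.inf else -ll


def _hessian(x: np.ndarray, agg: AggregatedComparisons, h: float = _HESS_STEP) -> np.ndarray:
    """Central finite-difference Hessian of the negative log-likelihood on
    the log-abundance scale."""
    n = x.size
    hess = np.empty((n, n))
    f0 = _neg_ll(x, agg)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h
        hess[i, i] = (_neg_ll(x + ei, agg) - 2.0 * f0 + _neg_ll(x - ei, agg)) / h**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h
            hess[i, j] = hess[j, i] = (
                _neg_ll(x + ei + ej, agg) - _neg_ll(x + ei - ej, agg)
                - _neg_ll(x - ei + ej, agg) + _neg_ll(x - ei - ej, agg)
            ) / (4.0 * h**2)
    return hess


def fit_ckmr(agg: AggregatedComparisons,
             start: Optional[tuple[float, float]] = None) -> FitResult:
    """Maximise the POP pseudo-log-likelihood over (N_f, N_m).

    The default start puts each abundance at twice the number of capture
    records; a short ladder of rescaled starts is tried before declaring an
    optimiser failure.  A fit converges only when the optimiser succeeds at
    a finite optimum with a positive-definite observed information.
    """
    if not agg.feasible:
        return FitResult(converged=False, failure_reason="infeasible_likelihood")
    if not (agg.identifiable(0) and agg.identifiable(1)):
        return FitResult(converged=False, failure_reason="non_identifiable")
    n0 = 2.0 * agg.n_records if start is None else None
    base = np.log([n0, n0]) if start is None else np.log(np.asarray(start, dtype=float))

    best = None
    for mult in _START_LADDER:  # first successful start wins (surface is unimodal)
        x0 = base + np.log(mult)
        if not np.isfinite(_neg_ll(x0, agg)):
            continue
        res = minimize(_neg_ll, x0, args=(agg,), method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000})
        if res.success and np.isfinite(res.fun):
            best = res
            break
    if best is None:
        return FitResult(converged=False, failure_reason="optimizer_failure")

    x_hat = best.x
    hess = _hessian(x_hat, agg)
    if not np.all(np.isfinite(hess)):
        return FitResult(converged=False, failure_reason="optimizer_failure")
    try:
        eigvals = np.linalg.eigvalsh(hess)
    except np.linalg.LinAlgError:
        return FitResult(converged=False, failure_reason="optimizer_failure")
    if np.any(eigvals <= 0):
        return FitResult(converged=False, failure_reason="optimizer_failure")
    cov_log = np.linalg.inv(hess)

    n_hat = np.exp(x_hat)
    se = n_hat * np.sqrt(np.diag(cov_log))  # delta method: Var(N) = N^2 Var(log N)
    ci_f = lognormal_ci(n_hat[0], se[0])
    ci_m = lognormal_ci(n_hat[1], se[1])
    return FitResult(
        converged=True,
        N_f_hat=float(n_hat[0]),
        N_m_hat=float(n_hat[1]),
        se_f=float(se[0]),
        se_m=float(se[1]),
        ci_f=ci_f,
        ci_m=ci_m,
        loglik=float(-best.fun),
    )
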