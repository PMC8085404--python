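"""Coordinate-descent solver for elastic-net penalized logistic regression.

Minimizes, over (beta0, beta),

    (1/n) * sum_i [ -y_i*eta_i + log(1 + exp(eta_i)) ]
        + lam * [ (1-alpha) * ||beta||_2^2 / 2 + alpha * ||beta||_1 ],

with eta_i = beta0 + x_i . beta and the intercept unpenalized. The algorithm
is the classic proximal-Newton scheme: an outer IRLS loop forms a weighted
least-squares approximation of the log-likelihood at the current point, and an
inner cyclic coordinate-descent loop solves the penalized quadratic with
soft-thresholding. Lambda paths are fit warm-started from large to small
lambda, which is what makes the resampling engine affordable.

Numerical safeguards follow the usual conventions of this solver family:
logits clipped at +/-30 when forming probabilities, IRLS weights floored at
1e-5, convergence declared on the maximum weighted squared parameter change
(max_j wx2_j * delta_j^2 < tol, the glmnet "thresh" criterion), which keeps
the objective accurate to about the tolerance itself.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["enet_logistic", "enet_logistic_path", "lambda_max", "objective"]

_WEIGHT_FLOOR = 1e-5
_LOGIT_CLIP = 30.0


def objective(
    beta0: float,
    beta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
) -> float:
    """The penalized negative average Bernoulli log-likelihood being minimized."""
    beta = np.asarray(beta, dtype=float)
    if not (np.isfinite(beta0) and np.all(np.isfinite(beta))):
        raise ValueError("non-finite parameters")
    if lam < 0 or not 0.0 <= alpha <= 1.0:
        raise ValueError("need lam >= 0 and alpha in [0, 1]")
    eta = beta0 + X @ beta
    nll = float(np.mean(-y * eta + np.logaddexp(0.0, eta)))
    penalty = lam * ((1.0 - alpha) * 0.5 * float(beta @ beta) + alpha * float(np.abs(beta).sum()))
    return nll + penalty


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float, alpha_floor: float = 1e-3) -> float:
    """Smallest penalty at which the all-zero coefficient vector is optimal.

    From the KKT conditions at beta = 0 (intercept at logit of the class
    prevalence): lam_max = max_j |<x_j, y - mean(y)>| / (n * alpha). Pure
    ridge (alpha = 0) has no finite lambda_max, so alpha is floored.
    """
    n = X.shape[0]
    resid = y - y.mean()
    score = np.abs(X.T @ resid) / n
    return float(score.max() / max(alpha, alpha_floor))


@njit(cache=True)
def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True)
def _cd_fit(X, y, lam, alpha, beta0, beta, tol, max_outer, max_inner):
    """One (lam, alpha) fit from a warm start. Returns (beta0, converged)."""
    n, p = X.shape
    for _ in range(max_outer):
        # quadratic approximation at the current point
        eta = beta0 + X @ beta
        for i in range(n):
            if eta[i] > _LOGIT_CLIP:
                eta[i] = _LOGIT_CLIP
            elif eta[i] < -_LOGIT_CLIP:
                eta[i] = -_LOGIT_CLIP
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = prob * (1.0 - prob)
        for i in range(n):
            if w[i] < _WEIGHT_FLOOR:
                w[i] = _WEIGHT_FLOOR
        z = eta + (y - prob) / w
        wx2 = np.empty(p)
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += w[i] * X[i, j] * X[i, j]
            wx2[j] = s / n
        wsum = w.sum()

        # inner CD on the penalized weighted least squares; convergence on
        # the weighted squared change max_j wx2_j * d_j^2 (glmnet's thresh)
        r = z - beta0 - X @ beta
        beta0_start = beta0
        beta_start = beta.copy()
        for sweep in range(max_inner):
            dmax = 0.0
            for j in range(p):
                bj = beta[j]
                num = bj * wx2[j]
                for i in range(n):
                    num += w[i] * X[i, j] * r[i] / n
                bj_new = _soft(num, lam * alpha) / (wx2[j] + lam * (1.0 - alpha))
                d = bj_new - bj
                if d != 0.0:
                    beta[j] = bj_new
                    for i in range(n):
                        r[i] -= X[i, j] * d
                    wd = wx2[j] * d * d
                    if wd > dmax:
                        dmax = wd
            # unpenalized intercept
            d0 = 0.0
            for i in range(n):
                d0 += w[i] * r[i]
            d0 /= wsum
            if d0 != 0.0:
                beta0 += d0
                for i in range(n):
                    r[i] -= d0
                wd0 = (wsum / n) * d0 * d0
                if wd0 > dmax:
                    dmax = wd0
            if dmax < tol:
                break
        # the whole Newton step barely moved the parameters: done
        outer_delta = (wsum / n) * (beta0 - beta0_start) ** 2
        for j in range(p):
            wd = wx2[j] * (beta[j] - beta_start[j]) ** 2
            if wd > outer_delta:
                outer_delta = wd
        if outer_delta < tol:
            return beta0, True
    return beta0, False


@njit(cache=True)
def _cd_path(X, y, lambdas, alpha, tol, max_outer, max_inner):
    n, p = X.shape
    nl = lambdas.shape[0]
    B0 = np.empty(nl)
    B = np.empty((nl, p))
    conv = np.empty(nl, dtype=np.bool_)
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        beta0 = 0.0
    else:
        beta0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    for l in range(nl):
        beta0, ok = _cd_fit(X, y, lambdas[l], alpha, beta0, beta, tol, max_outer, max_inner)
        B0[l] = beta0
        B[l] = beta
        conv[l] = ok
    return B0, B, conv


def enet_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    tol: float = 1e-8,
    max_outer: int = 200,
    max_inner: int = 1000,
) -> tuple[float, np.ndarray, bool]:
    """Fit a single (lam, alpha) point from a cold start.

    Returns ``(beta0, beta, converged)``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    ybar = y.mean()
    beta0 = float(np.log(ybar / (1.0 - ybar))) if 0.0 < ybar < 1.0 else 0.0
    beta = np.zeros(X.shape[1])
    beta0, ok = _cd_fit(X, y, float(lam), float(alpha), beta0, beta, tol, max_outer, max_inner)
    return float(beta0), beta, bool(ok)


def enet_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    tol: float = 1e-7,
    max_outer: int = 100,
    max_inner: int = 500,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Warm-started fits along a decreasing lambda path.

    Returns ``(B0, B, converged)`` with one row of ``B`` per lambda.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda path must be strictly decreasing")
    return _cd_path(X, y, lambdas, float(alpha), tol, max_outer, max_inner)
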