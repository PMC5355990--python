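"""Elastic-net regularized logistic regression for the final gene signature.

The penalized binomial likelihood

    (1/n) sum_i NLL_i(beta0, beta) + lambda * [alpha * |beta|_1
                                               + (1-alpha)/2 * |beta|_2^2]

is minimized by iteratively reweighted least squares with cyclic coordinate
descent on the quadratic approximation, warm-started along a decreasing
lambda path. Ten-fold cross-validated binomial deviance selects lambda_min;
the nonzero coefficients of the refit at lambda_min are the signature.

Genes are standardized internally (sample SD) and coefficients are reported
on the standardized scale, which is what the correlation-pattern scorer
consumes. The intercept is never penalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.model_selection import StratifiedKFold

from .centroid import normalize_labels
from .exceptions import ConfigurationError, ClassCountError
from .io import ExpressionMatrix, standardize_genes

_P_CLIP = 1e-5
_ALPHA_FLOOR = 1e-3   # used only to define a finite lambda_max when alpha ~ 0
_LAMBDA_FLOOR_RATIO = 1e-6


@njit(cache=True)
def _cd_wls(A, w, z, beta, beta0, lam_l1, lam_l2, tol, max_sweeps):
    """Cyclic coordinate descent on the weighted least-squares subproblem."""
    n, p = A.shape
    r = np.empty(n)
    for i in range(n):
        acc = z[i] - beta0
        for j in range(p):
            acc -= A[i, j] * beta[j]
        r[i] = acc
    sweeps = 0
    for _ in range(max_sweeps):
        sweeps += 1
        dmax = 0.0
        num = 0.0
        den = 0.0
        for i in range(n):
            num += w[i] * r[i]
            den += w[i]
        db0 = num / den
        beta0 += db0
        for i in range(n):
            r[i] -= db0
        if abs(db0) > dmax:
            dmax = abs(db0)
        for j in range(p):
            bj = beta[j]
            rho = 0.0
            xx = 0.0
            for i in range(n):
                aij = A[i, j]
                rho += w[i] * aij * (r[i] + aij * bj)
                xx += w[i] * aij * aij
            rho /= n
            xx = xx / n + lam_l2
            if rho > lam_l1:
                bnew = (rho - lam_l1) / xx
            elif rho < -lam_l1:
                bnew = (rho + lam_l1) / xx
            else:
                bnew = 0.0
            d = bnew - bj
            if d != 0.0:
                for i in range(n):
                    r[i] -= A[i, j] * d
                beta[j] = bnew
                if abs(d) > dmax:
                    dmax = abs(d)
        if dmax < tol:
            break
    return beta0, sweeps


@dataclass
class ElasticNetFit:
    """One point on the elastic-net path (standardized-scale coefficients)."""

    genes: list
    intercept: float
    coef: np.ndarray
    alpha: float
    lam: float
    converged: bool = True
    objective: float = np.nan

    @property
    def nonzero_genes(self) -> list:
        return [g for g, b in zip(self.genes, self.coef) if b != 0.0]

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coef))

    def predict_proba(self, A: np.ndarray) -> np.ndarray:
        eta = self.intercept + A @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))


def _nll(A, y, beta0, beta) -> float:
    eta = beta0 + A @ beta
    # log(1 + e^eta) - y*eta, computed stably
    return float(np.mean(np.logaddexp(0.0, eta) - y * eta))


def objective_value(A, y, fit: ElasticNetFit) -> float:
    pen = fit.lam * (fit.alpha * np.abs(fit.coef).sum()
                     + 0.5 * (1 - fit.alpha) * (fit.coef**2).sum())
    return _nll(A, y, fit.intercept, fit.coef) + pen


def kkt_max_violation(A, y, fit: ElasticNetFit) -> float:
    """Largest violation of the subgradient stationarity conditions."""
    p = fit.predict_proba(A)
    g = A.T @ (p - y) / len(y)
    lam_l1 = fit.lam * fit.alpha
    lam_l2 = fit.lam * (1 - fit.alpha)
    active = fit.coef != 0.0
    v_active = np.abs(np.abs(g[active] + lam_l2 * fit.coef[active]) - lam_l1)
    v_zero = np.maximum(np.abs(g[~active]) - lam_l1, 0.0)
    v_int = abs(float(np.mean(p - y)))
    parts = [np.array([v_int])]
    if v_active.size:
        parts.append(v_active)
    if v_zero.size:
        parts.append(v_zero)
    return float(np.max(np.concatenate(parts)))


def lambda_max(A, y, alpha: float) -> float:
    pbar = y.mean()
    g = np.abs(A.T @ (y - pbar)) / len(y)
    # relative epsilon keeps the fit at lambda_max exactly all-zero despite
    # floating-point ties at the subgradient boundary
    return float(g.max() / max(alpha, _ALPHA_FLOOR)) * (1.0 + 1e-9)


def make_lambda_path(A, y, alpha, n_lambda=100, lambda_min_ratio=1e-3):
    lmax = lambda_max(A, y, alpha)
    return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)


def _design(X: ExpressionMatrix, labels):
    """Standardized n x p design plus the 0/1 lobular response."""
    y = (normalize_labels(labels) == "lobular").astype(float)
    if y.min() == y.max():
        raise ClassCountError("need both classes to fit the binomial model")
    Xs, _ = standardize_genes(X)
    return np.ascontiguousarray(Xs.values.T), y


def _fit_at_lambda(A, y, alpha, lam, beta0, beta, tol=1e-7, max_outer=100):
    lam_l1 = lam * alpha
    lam_l2 = lam * (1 - alpha)
    converged = False
    for _ in range(max_outer):
        eta = beta0 + A @ beta
        prob = np.clip(1.0 / (1.0 + np.exp(-eta)), _P_CLIP, 1 - _P_CLIP)
        w = prob * (1 - prob)
        z = eta + (y - prob) / w
        b_prev = beta.copy()
        b0_prev = beta0
        beta0, _ = _cd_wls(A, w, z, beta, beta0, lam_l1, lam_l2, tol, 1000)
        if max(np.abs(beta - b_prev).max(initial=0.0),
               abs(beta0 - b0_prev)) < tol:
            converged = True
            break
    return beta0, beta, converged


def fit_elastic_net(X: ExpressionMatrix, labels, alpha: float = 0.5,
                    lambda_path=None, n_lambda: int = 100,
                    lambda_min_ratio: float = 1e-3, tol: float = 1e-7):
    """Fit the penalized binomial model along a decreasing lambda path.

    Returns one :class:`ElasticNetFit` per lambda, warm-started from the
    previous knot. ``lambda_path`` defaults to 100 log-spaced knots from
    lambda_max (all coefficients zero) down by a factor of 1e-3.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError("alpha must be in [0, 1]")
    A, y = _design(X, labels)
    if lambda_path is None:
        lambda_path = make_lambda_path(A, y, alpha, n_lambda, lambda_min_ratio)
    lambda_path = np.asarray(sorted(lambda_path, reverse=True), dtype=float)
    floor = lambda_max(A, y, alpha) * _LAMBDA_FLOOR_RATIO
    if (lambda_path < floor).any():
        warnings.warn(
            "lambda values below the stability floor were clamped "
            "(unpenalized logistic fits can diverge under separation)",
            UserWarning, stacklevel=2,
        )
        lambda_path = np.maximum(lambda_path, floor)

    pbar = y.mean()
    beta0 = float(np.log(pbar / (1 - pbar)))
    beta = np.zeros(A.shape[1])
    fits = []
    for lam in lambda_path:
        beta0, beta, ok = _fit_at_lambda(A, y, alpha, float(lam), beta0,
                                         beta.copy(), tol=tol)
        fit = ElasticNetFit(genes=list(X.gene_ids), intercept=beta0,
                            coef=beta.copy(), alpha=alpha, lam=float(lam),
                            converged=ok)
        fit.objective = objective_value(A, y, fit)
        fits.append(fit)
    return fits


def binomial_deviance(y, prob) -> np.ndarray:
    prob = np.clip(prob, _P_CLIP, 1 - _P_CLIP)
    return -2.0 * (y * np.log(prob) + (1 - y) * np.log(1 - prob))


@dataclass
class CVElasticNetResult:
    fits: list
    lambdas: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    best: ElasticNetFit
    signature_genes: list = field(default_factory=list)


def cv_select_lambda(X: ExpressionMatrix, labels, alpha: float = 0.5,
                     folds: int = 10, seed: int = 0, n_lambda: int = 100,
                     lambda_min_ratio: float = 1e-3) -> CVElasticNetResult:
    """Pick lambda by minimum mean cross-validated binomial deviance.

    The lambda path is fixed from the full data; every fold fits the whole
    path (warm starts) and held-out per-sample deviances are averaged per
    lambda. The full-data refit at lambda_min carries the signature (its
    nonzero-coefficient genes).
    """
    A, y = _design(X, labels)
    path = make_lambda_path(A, y, alpha, n_lambda, lambda_min_ratio)
    n_lob = int(y.sum())
    if folds < 2 or min(n_lob, len(y) - n_lob) < folds:
        raise ConfigurationError(
            f"stratified {folds}-fold CV infeasible with class counts "
            f"{n_lob}/{len(y) - n_lob}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.full((len(y), len(path)), np.nan)
    fold_of = np.empty(len(y), dtype=int)
    for f, (train, test) in enumerate(skf.split(A, y)):
        fold_of[test] = f
        sub = ExpressionMatrix(
            X.gene_ids, [X.sample_ids[i] for i in train],
            X.values[:, train], X.cohort[train])
        fits = fit_elastic_net(sub, np.asarray(normalize_labels(labels))[train],
                               alpha=alpha, lambda_path=path)
        for li, fit in enumerate(fits):
            dev[test, li] = binomial_deviance(y[test], fit.predict_proba(A[test]))

    cv_mean = dev.mean(axis=0)
    fold_means = np.stack([dev[fold_of == f].mean(axis=0) for f in range(folds)])
    cv_se = fold_means.std(axis=0, ddof=1) / np.sqrt(folds)
    li_min = int(np.argmin(cv_mean))
    full_fits = fit_elastic_net(X, labels, alpha=alpha, lambda_path=path)
    best = full_fits[li_min]
    return CVElasticNetResult(
        fits=full_fits, lambdas=path, cv_mean=cv_mean, cv_se=cv_se,
        lambda_min=float(path[li_min]), best=best,
        signature_genes=best.nonzero_genes,
    )
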