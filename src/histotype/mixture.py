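"""Two-component Gaussian mixture for marker (E-cadherin-like) negativity.

A 1-D EM fit with unequal variances and multiple restarts partitions marker
expression into a low and a high mode; the negativity threshold is the
point between the two means where the posterior probability of the low
component crosses 0.5. Single-marker diagnostic rules (mixture threshold,
median, first quartile) are compared against the histologic labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .centroid import normalize_labels
from .exceptions import ClassCountError, ConfigurationError, MixtureError

_VAR_FLOOR = 1e-4


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture with the low component first."""

    weights: np.ndarray          # (pi_low, pi_high), sums to 1
    means: np.ndarray            # mu_low < mu_high
    sds: np.ndarray
    loglik_trace: list = field(default_factory=list)
    threshold: float = np.nan
    ashman_d: float = np.nan

    @property
    def bimodal(self) -> bool:
        return self.ashman_d >= 2.0

    def posterior_low(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        log_d = _log_density(x, self.weights, self.means, self.sds)
        return np.exp(log_d[0] - np.logaddexp(log_d[0], log_d[1]))


def _log_density(x, w, mu, sd):
    return np.stack([
        np.log(w[k]) - 0.5 * np.log(2 * np.pi * sd[k] ** 2)
        - (x - mu[k]) ** 2 / (2 * sd[k] ** 2)
        for k in range(2)
    ])


def _em(x, w, mu, var, max_iter, tol):
    trace = []
    for _ in range(max_iter):
        log_d = _log_density(x, w, mu, np.sqrt(var))
        log_norm = np.logaddexp(log_d[0], log_d[1])
        ll = float(log_norm.sum())
        if trace and ll < trace[-1] - 1e-9:
            raise MixtureError("EM log-likelihood decreased")
        converged = bool(trace) and ll - trace[-1] < tol
        trace.append(ll)
        if converged:
            break
        resp = np.exp(log_d - log_norm)            # 2 x n responsibilities
        nk = resp.sum(axis=1)
        w = nk / len(x)
        mu = (resp @ x) / nk
        var = np.array([
            (resp[k] @ (x - mu[k]) ** 2) / nk[k] for k in range(2)])
        if (var < _VAR_FLOOR).any():
            warnings.warn("mixture component variance hit the floor",
                          UserWarning, stacklevel=3)
            var = np.maximum(var, _VAR_FLOOR)
    return w, mu, var, trace


def fit_marker_mixture(values, seed: int = 0, n_restarts: int = 10,
                       max_iter: int = 500, tol: float = 1e-8) -> MixtureFit:
    """EM fit with random restarts; the best log-likelihood solution wins.

    Raises if the data are degenerate (threshold undefined); warns and
    flags overlap when the fitted components are not clearly separated
    (Ashman D < 2).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ConfigurationError("need at least 10 values for a mixture fit")
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("marker values must be finite")
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        if r == 0:
            mu = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
        else:
            mu = rng.choice(x, 2, replace=False)
        if mu[0] == mu[1]:
            mu = mu + np.array([-1e-3, 1e-3])
        var = np.full(2, max(x.var(), _VAR_FLOOR))
        w = np.array([0.5, 0.5])
        w, mu, var, trace = _em(x, w, mu, var, max_iter, tol)
        if best is None or trace[-1] > best[-1][-1]:
            best = (w, mu, var, trace)
    w, mu, var, trace = best
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], np.sqrt(var[order])
    if mu[1] - mu[0] < 1e-8:
        raise MixtureError(
            "mixture means coincide; negativity threshold undefined")
    ashman = float(np.sqrt(2.0) * (mu[1] - mu[0]) / np.sqrt(sd[0]**2 + sd[1]**2))
    if ashman < 2.0:
        warnings.warn(
            f"mixture components overlap heavily (Ashman D = {ashman:.2f}); "
            "the negativity threshold is unreliable", UserWarning, stacklevel=2)
    fit = MixtureFit(weights=w, means=mu, sds=sd, loglik_trace=trace,
                     ashman_d=ashman)
    fit.threshold = _posterior_crossing(fit)
    return fit


def _posterior_crossing(fit: MixtureFit) -> float:
    """Solve pi_1 N(x|mu1,sd1) = pi_2 N(x|mu2,sd2) for x in (mu1, mu2)."""
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    a = 0.5 * (1 / s2**2 - 1 / s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = 0.5 * (m2**2 / s2**2 - m1**2 / s1**2) \
        + np.log(w1 / w2) + np.log(s2 / s1)
    if abs(a) < 1e-12:
        if abs(b) < 1e-12:
            raise MixtureError("posterior never crosses 0.5")
        roots = np.array([-c / b])
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            raise MixtureError("posterior never crosses 0.5")
        roots = (-b + np.array([-1.0, 1.0]) * np.sqrt(disc)) / (2 * a)
    inside = roots[(roots > m1) & (roots < m2)]
    if inside.size:
        return float(inside[0])
    # heavy overlap: fall back to the root nearest the midpoint
    return float(roots[np.argmin(np.abs(roots - (m1 + m2) / 2))])


def marker_diagnostics(values, labels, cutoff_rule: str = "mixture",
                       seed: int = 0) -> dict:
    """Single-marker diagnostic agreement under a low-expression rule.

    Values at or below the rule's cutoff call lobular. Reports the fraction
    of lobular cases correctly called, the fraction of ductal cases
    correctly called, and the fraction of lobular cases below the mixture
    negativity threshold.
    """
    x = np.asarray(values, dtype=float)
    y = normalize_labels(labels)
    for cls in ("ductal", "lobular"):
        if not (y == cls).any():
            raise ClassCountError(f"no {cls} samples")
    fit = fit_marker_mixture(x, seed=seed)
    if cutoff_rule == "mixture":
        cut = fit.threshold
    elif cutoff_rule == "median":
        cut = float(np.median(x))
    elif cutoff_rule == "quartile1":
        k = int(np.ceil(len(x) / 4))
        cut = float(np.sort(x)[k - 1])
    else:
        raise ConfigurationError(f"unknown cutoff rule {cutoff_rule!r}")
    call_lob = x <= cut
    lob = y == "lobular"
    return {
        "rule": cutoff_rule,
        "cutoff": float(cut),
        "lobular_agreement": float(call_lob[lob].mean()),
        "ductal_agreement": float((~call_lob[~lob]).mean()),
        "lobular_low_fraction": float((x[lob] <= fit.threshold).mean()),
        "mixture_threshold": float(fit.threshold),
    }
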