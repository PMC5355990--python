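"""Nearest shrunken centroid feature reduction for the two histologic classes.

Per-gene class centroid deviations are standardized by the pooled
within-class SD (plus a fudge constant s0) and soft-thresholded by a
shrinkage parameter delta; genes whose deviations survive for at least one
class form the working gene set. A stratified cross-validation path over
delta locates the largest shrinkage whose lobular-class error is still
within one standard error of the best, i.e. the smallest gene set before
lobular error starts to rise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .exceptions import (
    ClassCountError,
    ConfigurationError,
    SelectionError,
    StratificationError,
)
from .io import ExpressionMatrix

CLASSES = ("ductal", "lobular")


def normalize_labels(labels) -> np.ndarray:
    """Coerce labels to the canonical ('ductal','lobular') string array."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "biu":
        return np.where(arr.astype(int) == 1, "lobular", "ductal").astype(object)
    arr = arr.astype(object)
    bad = set(arr) - set(CLASSES)
    if bad:
        raise ClassCountError(f"unknown class labels: {sorted(map(str, bad))}")
    return arr


def soft_threshold(d: np.ndarray, delta: float) -> np.ndarray:
    """sign(d) * max(|d| - delta, 0): odd in d and a contraction."""
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


@dataclass
class CentroidModel:
    """Shrunken-centroid model for ductal (k=0) vs lobular (k=1)."""

    gene_ids: list
    overall: np.ndarray          # per-gene overall centroid
    class_centroids: np.ndarray  # genes x 2
    s: np.ndarray                # pooled within-class SD per gene
    s0: float
    mk: np.ndarray               # sqrt(1/n_k - 1/n), length 2
    dik: np.ndarray              # standardized deviations, genes x 2
    delta: float
    priors: np.ndarray
    n_per_class: np.ndarray

    @property
    def d_shrunk(self) -> np.ndarray:
        return soft_threshold(self.dik, self.delta)

    @property
    def shrunken_centroids(self) -> np.ndarray:
        scale = (self.mk[None, :] * (self.s + self.s0)[:, None])
        return self.overall[:, None] + scale * self.d_shrunk

    @property
    def surviving_mask(self) -> np.ndarray:
        return np.any(self.d_shrunk != 0.0, axis=1)

    @property
    def surviving_genes(self) -> list:
        return [g for g, keep in zip(self.gene_ids, self.surviving_mask) if keep]

    def with_delta(self, delta: float) -> "CentroidModel":
        if delta < 0:
            raise ConfigurationError("delta must be >= 0")
        return replace(self, delta=float(delta))


def fit_centroids(X: ExpressionMatrix, labels, delta: float = 0.0) -> CentroidModel:
    if delta < 0:
        raise ConfigurationError("delta must be >= 0")
    y = normalize_labels(labels)
    if len(y) != X.n_samples:
        raise ClassCountError("labels length does not match sample count")
    masks = [y == c for c in CLASSES]
    n_k = np.array([int(m.sum()) for m in masks])
    if np.any(n_k < 2):
        raise ClassCountError(
            f"both classes need >= 2 samples; counts {dict(zip(CLASSES, n_k))}"
        )
    n = X.n_samples
    V = X.values
    overall = V.mean(axis=1)
    class_centroids = np.stack([V[:, m].mean(axis=1) for m in masks], axis=1)
    # pooled within-class variance with n - K degrees of freedom
    ss = sum(((V[:, m] - class_centroids[:, [k]]) ** 2).sum(axis=1)
             for k, m in enumerate(masks))
    s = np.sqrt(ss / (n - len(CLASSES)))
    s0 = float(np.median(s))
    mk = np.sqrt(1.0 / n_k - 1.0 / n)
    dik = (class_centroids - overall[:, None]) / (mk[None, :] * (s + s0)[:, None])
    return CentroidModel(
        gene_ids=list(X.gene_ids), overall=overall,
        class_centroids=class_centroids, s=s, s0=s0, mk=mk, dik=dik,
        delta=float(delta), priors=n_k / n, n_per_class=n_k,
    )


def classify_centroid(model: CentroidModel, X: ExpressionMatrix):
    """Nearest-shrunken-centroid calls plus per-class discriminant scores.

    discriminant_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i+s0)^2 - 2 log pi_k,
    minimized over k; exact ties go to ductal (the majority class).
    """
    idx = X.gene_index(model.gene_ids)
    V = X.values[idx]
    cent = model.shrunken_centroids
    keep = model.surviving_mask
    denom = (model.s + model.s0) ** 2
    disc = np.empty((X.n_samples, 2))
    for k in range(2):
        if keep.any():
            diff = V[keep] - cent[keep, k][:, None]
            disc[:, k] = (diff**2 / denom[keep, None]).sum(axis=0)
        else:
            disc[:, k] = 0.0
        disc[:, k] -= 2.0 * np.log(model.priors[k])
    # argmin with ties resolved to ductal (index 0)
    calls = np.where(disc[:, 1] < disc[:, 0], "lobular", "ductal").astype(object)
    return calls, disc


def cv_threshold_path(X: ExpressionMatrix, labels, deltas=None,
                      folds: int = 10, seed: int = 0):
    """Stratified-CV error along a shrinkage path.

    Returns a ``ThresholdPath`` whose table has, per delta, the overall and
    per-class CV error plus the surviving-gene count of the full-data fit.
    """
    y = normalize_labels(labels)
    full = fit_centroids(X, y)
    if deltas is None:
        deltas = np.linspace(0.0, float(np.abs(full.dik).max()), 30)
    deltas = np.asarray(sorted(deltas), dtype=float)
    counts = {c: int((y == c).sum()) for c in CLASSES}
    if min(counts.values()) < folds:
        raise StratificationError(
            f"smallest class ({min(counts.values())}) < folds ({folds})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    wrong = np.zeros((len(deltas), 2), dtype=int)
    for train, test in skf.split(np.zeros(len(y)), y == "lobular"):
        sub = ExpressionMatrix(
            X.gene_ids, [X.sample_ids[i] for i in train],
            X.values[:, train], X.cohort[train])
        fold_model = fit_centroids(sub, y[train])
        Xtest = ExpressionMatrix(
            X.gene_ids, [X.sample_ids[i] for i in test],
            X.values[:, test], X.cohort[test])
        for di, d in enumerate(deltas):
            calls, _ = classify_centroid(fold_model.with_delta(d), Xtest)
            for k, c in enumerate(CLASSES):
                wrong[di, k] += int(((y[test] == c) & (calls != c)).sum())

    err_d = wrong[:, 0] / counts["ductal"]
    err_l = wrong[:, 1] / counts["lobular"]
    table = pd.DataFrame({
        "delta": deltas,
        "n_genes": [int(full.with_delta(d).surviving_mask.sum()) for d in deltas],
        "cv_err": wrong.sum(axis=1) / len(y),
        "cv_err_ductal": err_d,
        "cv_err_lobular": err_l,
        "se_lobular": np.sqrt(err_l * (1 - err_l) / counts["lobular"]),
    })
    return ThresholdPath(table=table, model=full)


@dataclass
class ThresholdPath:
    table: pd.DataFrame
    model: CentroidModel


def select_working_set(path: ThresholdPath, min_genes: int = 1):
    """Largest shrinkage whose lobular CV error is within one SE of the best.

    Operationalizes "the minimal gene set before lobular error begins to
    increase": among deltas that retain at least ``min_genes`` genes, find
    the minimum lobular error, then take the largest delta whose lobular
    error does not exceed that minimum plus its binomial standard error.
    """
    t = path.table
    if len(t) == 0:
        raise SelectionError("empty threshold path")
    ok = t["n_genes"] >= max(min_genes, 1)
    if not ok.any():
        raise SelectionError(
            f"no delta retains >= {max(min_genes, 1)} gene(s)")
    sub = t[ok]
    best = sub["cv_err_lobular"].min()
    se = float(sub.loc[sub["cv_err_lobular"].idxmin(), "se_lobular"])
    candidates = sub[sub["cv_err_lobular"] <= best + se]
    delta_star = float(candidates["delta"].max())
    genes = path.model.with_delta(delta_star).surviving_genes
    return delta_star, genes
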