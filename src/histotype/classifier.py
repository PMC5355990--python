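"""Correlation-pattern histotype classifier with an optimal cutoff and a
"strict" indeterminate band.

Each sample's signature-gene expression is standardized with the discovery
cohorts' per-gene means/SDs and Pearson-correlated with the signature's
coefficient pattern; the correlation is the lobular score (scores above the
cutoff call lobular). The optimal cutoff minimizes the misclassification
count over all discovery samples. Cutoffs whose error rate is statistically
indistinct from the optimum (two-proportion Z test, exact comparison when
the optimum makes zero errors) form a contiguous band around the cutoff;
under the strict model, samples scoring inside the band are called
indeterminate rather than forced into a diagnosis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .centroid import normalize_labels
from .exceptions import (
    CalibrationError,
    ConfigurationError,
    UndefinedScoreError,
)
from .io import ExpressionMatrix, save_json, load_json

_SCHEMA = "histotype-classifier"


@dataclass
class HistotypeClassifier:
    """Signature genes, coefficient pattern, standardization and cutoffs."""

    genes: list
    pattern: np.ndarray
    gene_means: np.ndarray
    gene_sds: np.ndarray
    cutoff: float | None = None
    band: tuple | None = None        # (c_lo, c_hi), c_lo <= cutoff <= c_hi
    strict_alpha: float = 0.05

    def __post_init__(self):
        self.pattern = np.asarray(self.pattern, dtype=float)
        self.gene_means = np.asarray(self.gene_means, dtype=float)
        self.gene_sds = np.asarray(self.gene_sds, dtype=float)
        if len(self.genes) < 2:
            raise ConfigurationError(
                "the pattern needs >= 2 genes for a correlation score"
            )
        if np.ptp(self.pattern) == 0:
            raise ConfigurationError("constant coefficient pattern")
        if self.band is not None:
            lo, hi = self.band
            if not (lo <= self.cutoff <= hi):
                raise ConfigurationError("band must contain the cutoff")

    @classmethod
    def from_elastic_net(cls, fit, standardization: pd.DataFrame,
                         strict_alpha: float = 0.05):
        """Build a scorer from an elastic-net fit's nonzero coefficients."""
        genes = fit.nonzero_genes
        coef = {g: b for g, b in zip(fit.genes, fit.coef) if b != 0.0}
        p = standardization.set_index("gene_id").loc[genes]
        return cls(genes=genes,
                   pattern=np.array([coef[g] for g in genes]),
                   gene_means=p["mean"].to_numpy(),
                   gene_sds=p["sd"].to_numpy(),
                   strict_alpha=strict_alpha)

    def to_json(self, path) -> None:
        save_json({
            "genes": self.genes, "pattern": self.pattern,
            "gene_means": self.gene_means, "gene_sds": self.gene_sds,
            "cutoff": self.cutoff,
            "band": list(self.band) if self.band else None,
            "strict_alpha": self.strict_alpha,
        }, path, schema=_SCHEMA)

    @classmethod
    def from_json(cls, path) -> "HistotypeClassifier":
        d = load_json(path, schema=_SCHEMA)
        return cls(genes=d["genes"], pattern=np.array(d["pattern"]),
                   gene_means=np.array(d["gene_means"]),
                   gene_sds=np.array(d["gene_sds"]), cutoff=d["cutoff"],
                   band=tuple(d["band"]) if d["band"] else None,
                   strict_alpha=d["strict_alpha"])


def score_samples(clf: HistotypeClassifier,
                  X: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample lobular score: Pearson r of the standardized signature
    sub-vector with the coefficient pattern.

    Samples whose signature sub-vector has zero variance (correlation
    undefined) are dropped with a warning; their ids are listed in
    ``result.attrs['excluded']``.
    """
    idx = X.gene_index(clf.genes)
    Z = (X.values[idx] - clf.gene_means[:, None]) / clf.gene_sds[:, None]
    Zc = Z - Z.mean(axis=0, keepdims=True)
    pc = clf.pattern - clf.pattern.mean()
    z_norm = np.linalg.norm(Zc, axis=0)
    p_norm = np.linalg.norm(pc)
    degenerate = z_norm == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Zc.T @ pc) / (z_norm * p_norm)
    out = pd.DataFrame({
        "sample_id": X.sample_ids,
        "cohort": X.cohort,
        "score": np.clip(r, -1.0, 1.0),
    })
    excluded = out.loc[degenerate, "sample_id"].tolist()
    if excluded:
        warnings.warn(
            f"{len(excluded)} sample(s) with zero-variance signature "
            "sub-vector were excluded from scoring", UserWarning, stacklevel=2)
        out = out[~degenerate].reset_index(drop=True)
    out.attrs["excluded"] = excluded
    if degenerate.all():
        raise UndefinedScoreError("no sample has a defined score")
    return out


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    """Midpoints of adjacent sorted unique scores, with +-1 sentinels."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([-1.0], mids, [1.0]))


def _errors_at(c: float, scores: np.ndarray, y: np.ndarray) -> int:
    calls = scores > c  # True = lobular
    return int((calls != y).sum())


def calibrate_cutoff(scores, labels) -> float:
    """Cutoff minimizing the misclassification count over discovery samples.

    Candidates are midpoints of adjacent sorted unique scores plus the
    all-lobular / all-ductal sentinels; ties in error count resolve to the
    candidate closest to the median score.
    """
    scores = np.asarray(scores, dtype=float)
    y = normalize_labels(labels) == "lobular"
    if np.unique(scores).size < 2:
        raise CalibrationError("all scores identical; cutoff undefined")
    cands = _candidate_cutoffs(scores)
    errs = np.array([_errors_at(c, scores, y) for c in cands])
    best = errs == errs.min()
    med = float(np.median(scores))
    winners = cands[best]
    return float(winners[np.argmin(np.abs(winners - med))])


def calibrate_strict_band(scores, labels, cutoff: float,
                          alpha: float = 0.05) -> tuple:
    """Contiguous range of cutoffs statistically indistinct from the optimum.

    Each candidate cutoff's error proportion is compared with the optimal
    cutoff's by a pooled two-proportion Z test over the same n discovery
    samples; when the optimum makes zero errors the comparison is exact --
    a Binomial(n, 0) null leaves any error distinct, so only other
    zero-error cutoffs are indistinct. The band is the contiguous run of
    candidates around the cutoff with two-sided p > alpha, widened to the
    scores bounding its outermost inter-score intervals (every cutoff value
    strictly inside the band is indistinct from the optimum).
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    y = normalize_labels(labels) == "lobular"
    n = len(scores)
    cands = _candidate_cutoffs(scores)
    k_star = _errors_at(cutoff, scores, y)

    def indistinct(c: float) -> bool:
        k = _errors_at(c, scores, y)
        if k_star == 0:
            # exact comparison: under an error-free null any error is
            # impossible, so the indistinct region is the zero-error gap
            return k == 0
        e, e_star = k / n, k_star / n
        pbar = (e + e_star) / 2.0
        if pbar in (0.0, 1.0):
            return True
        z = (e - e_star) / np.sqrt(pbar * (1 - pbar) * 2.0 / n)
        return 2.0 * stats.norm.sf(abs(z)) > alpha

    i_star = int(np.argmin(np.abs(cands - cutoff)))
    lo = i_star
    while lo > 0 and indistinct(cands[lo - 1]):
        lo -= 1
    hi = i_star
    while hi < len(cands) - 1 and indistinct(cands[hi + 1]):
        hi += 1
    # candidate cands[t] (t = 1..u-1) is the midpoint of unique scores
    # u[t-1], u[t]; the indistinct run of candidates corresponds to the
    # cutoff-value region bounded by those scores
    u = np.unique(scores)
    c_lo = -1.0 if lo == 0 else float(u[lo - 1])
    c_hi = 1.0 if hi == len(cands) - 1 else float(u[hi])
    c_lo, c_hi = min(c_lo, cutoff), max(c_hi, cutoff)
    if c_lo == c_hi:
        warnings.warn("strict band collapsed to the cutoff (plain == strict)",
                      UserWarning, stacklevel=2)
    return (c_lo, c_hi)


def calibrate(clf: HistotypeClassifier, scores, labels,
              alpha: float | None = None) -> HistotypeClassifier:
    """Return a copy of ``clf`` with cutoff and strict band set."""
    alpha = clf.strict_alpha if alpha is None else alpha
    c = calibrate_cutoff(scores, labels)
    band = calibrate_strict_band(scores, labels, c, alpha)
    return HistotypeClassifier(
        genes=clf.genes, pattern=clf.pattern, gene_means=clf.gene_means,
        gene_sds=clf.gene_sds, cutoff=c, band=band, strict_alpha=alpha)


def call_samples(clf: HistotypeClassifier, scores: pd.DataFrame,
                 mode: str = "plain") -> pd.DataFrame:
    """Diagnosis calls from scores.

    plain: lobular iff score > cutoff (ties to ductal). strict: lobular iff
    score >= c_hi, ductal iff score <= c_lo, otherwise indeterminate.
    """
    if clf.cutoff is None:
        raise ConfigurationError("classifier is not calibrated")
    out = scores.copy()
    s = out["score"].to_numpy()
    if mode == "plain":
        out["call"] = np.where(s > clf.cutoff, "lobular", "ductal")
    elif mode == "strict":
        if clf.band is None:
            raise ConfigurationError("no strict band calibrated")
        lo, hi = clf.band
        call = np.full(len(s), "indeterminate", dtype=object)
        call[s >= hi] = "lobular"
        call[s <= lo] = "ductal"
        out["call"] = call
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    return out


def annotate_calls(clf: HistotypeClassifier,
                   scores: pd.DataFrame) -> pd.DataFrame:
    """Score table with both plain and strict calls as extra columns."""
    out = scores.copy()
    out["call_plain"] = call_samples(clf, scores, "plain")["call"]
    out["call_strict"] = call_samples(clf, scores, "strict")["call"]
    return out
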