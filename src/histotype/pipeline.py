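"""End-to-end training and application of the histotype classifier.

Training on discovery cohorts runs: per-cohort batch centering, shrunken-
centroid feature reduction with CV threshold selection, elastic-net fitting
with CV lambda selection on the working set, correlation-pattern scoring of
the discovery samples, and cutoff + strict-band calibration. Application to
new cohorts repeats the batch centering and scores with the stored
standardization parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SelectionError

from .centroid import cv_threshold_path, select_working_set
from .classifier import (
    HistotypeClassifier,
    annotate_calls,
    calibrate,
    score_samples,
)
from .elasticnet import cv_select_lambda
from .io import ExpressionMatrix, RunConfig, cohort_mean_adjust, \
    standardize_genes, substream_seed


@dataclass
class TrainingArtifacts:
    classifier: HistotypeClassifier
    delta_star: float
    working_genes: list
    threshold_path: pd.DataFrame
    enet_result: object
    discovery_scores: pd.DataFrame


def train_classifier(X: ExpressionMatrix, labels,
                     config: RunConfig | None = None,
                     alpha_enet: float = 0.5,
                     deltas=None, n_lambda: int = 100) -> TrainingArtifacts:
    """Train and calibrate the classifier on discovery cohorts."""
    config = config or RunConfig()
    labels = np.asarray(labels)
    Xa = cohort_mean_adjust(X)

    path = cv_threshold_path(Xa, labels, deltas=deltas,
                             folds=config.cv_folds,
                             seed=substream_seed(config.seed, "reduce"))
    delta_star, working = select_working_set(path, min_genes=2)

    Xw = Xa.subset_genes(working)
    _, standardization = standardize_genes(Xw)
    enet = cv_select_lambda(Xw, labels, alpha=alpha_enet,
                            folds=config.cv_folds,
                            seed=substream_seed(config.seed, "fit"),
                            n_lambda=n_lambda)

    best = enet.best
    if best.n_nonzero < 2:
        # a correlation pattern needs >= 2 genes; take the best-CV lambda
        # among fits that keep at least two
        ok = [i for i, f in enumerate(enet.fits) if f.n_nonzero >= 2]
        if not ok:
            raise SelectionError("no lambda keeps >= 2 signature genes")
        warnings.warn(
            "lambda_min kept < 2 genes; falling back to the best "
            "cross-validated lambda with >= 2 nonzero coefficients",
            UserWarning, stacklevel=2)
        best = enet.fits[min(ok, key=lambda i: enet.cv_mean[i])]

    clf = HistotypeClassifier.from_elastic_net(
        best, standardization, strict_alpha=config.alpha_strict)
    disc_scores = score_samples(clf, Xa)
    keep = disc_scores["sample_id"].tolist()
    lab = pd.Series(labels, index=X.sample_ids).loc[keep].to_numpy()
    clf = calibrate(clf, disc_scores["score"].to_numpy(), lab)
    return TrainingArtifacts(
        classifier=clf, delta_star=delta_star, working_genes=working,
        threshold_path=path.table, enet_result=enet,
        discovery_scores=annotate_calls(clf, disc_scores))


def score_cohorts(clf: HistotypeClassifier, X: ExpressionMatrix,
                  adjust: bool = False) -> pd.DataFrame:
    """Score (and call) new cohorts as measured.

    Batch adjustment is part of discovery-cohort training only; new cohorts
    are scored with the stored standardization. Pass ``adjust=True`` to
    batch-center the new cohorts first (each cohort needs >= 2 samples).
    """
    Xa = cohort_mean_adjust(X) if adjust else X
    return annotate_calls(clf, score_samples(clf, Xa))
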