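"""Core data containers, file formats, batch adjustment and standardization.

The package works on log2-scale expression matrices (genes x samples) with a
per-sample cohort label, plus a clinical annotation table keyed by sample id.
Files are plain tab-delimited text; models are schema-versioned JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConstantGeneError,
    DegenerateCohortError,
    IdentifierError,
    JoinError,
    MatrixParseError,
    ValidationError,
)

logger = logging.getLogger("histotype")

HISTOLOGY_LEVELS = ("ductal", "lobular", "mixed", "other", "NA")

CLINICAL_COLUMNS = (
    "sample_id",
    "histology",
    "grade",
    "stage",
    "er",
    "surv_time",
    "surv_event",
    "rec_time",
    "rec_event",
)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline-wide settings; one seed drives every randomized stage."""

    seed: int = 0
    alpha_strict: float = 0.05
    cv_folds: int = 10
    k_range: tuple = tuple(range(2, 8))
    consensus_resamples: int = 250
    outdir: str = "."

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d


def substream_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived by hashing the stage name.

    Derivation by name (not by call order) means adding or reordering
    pipeline stages does not perturb the random streams of other stages.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log2-scale genes x samples matrix with per-sample cohort labels."""

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    cohort: np.ndarray

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.cohort = np.asarray(self.cohort, dtype=object)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise IdentifierError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IdentifierError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.cohort.shape != (len(self.sample_ids),):
            raise ValidationError("cohort labels must be per-sample")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            from .exceptions import GeneCoverageError

            raise GeneCoverageError(
                f"matrix is missing {len(missing)} required genes: "
                f"{missing[:10]}", missing=missing,
            )
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx], self.sample_ids,
            self.values[idx], self.cohort,
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        orphans = [s for s in samples if s not in lookup]
        if orphans:
            raise JoinError(f"unknown samples: {orphans[:10]}", orphans=orphans)
        idx = np.array([lookup[s] for s in samples], dtype=int)
        return ExpressionMatrix(
            self.gene_ids, [self.sample_ids[i] for i in idx],
            self.values[:, idx], self.cohort[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)


def read_expression(path, cohort_map: Mapping[str, str] | None = None,
                    log2: bool = False,
                    impute: str | None = None) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (gene_id column + sample columns).

    ``cohort_map`` assigns each sample id to a cohort label; samples absent
    from the map raise a join error. ``log2`` applies log2(x+1) for
    raw-count-like inputs. Missing cells are rejected unless
    ``impute='gene-median'``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    gene_ids = raw.iloc[:, 0].tolist()
    sample_ids = [str(c) for c in raw.columns[1:]]
    if len(set(gene_ids)) != len(gene_ids):
        dups = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise IdentifierError(f"duplicate gene identifiers: {dups[:10]}")
    if len(set(sample_ids)) != len(sample_ids):
        raise IdentifierError("duplicate sample identifiers in header")

    body = raw.iloc[:, 1:]
    values = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        converted = pd.to_numeric(body[col], errors="coerce")
        bad = converted.isna() & body[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise MatrixParseError(
                f"non-numeric value {body[col].iloc[i]!r} at gene "
                f"{gene_ids[i]!r} (row {i}), sample {sample_ids[j]!r} "
                f"(column {j})", row=i, column=j,
            )
        values[:, j] = converted.to_numpy()

    if np.isnan(values).any():
        if impute == "gene-median":
            med = np.nanmedian(values, axis=1)
            rows, cols = np.nonzero(np.isnan(values))
            values[rows, cols] = med[rows]
            logger.info("imputed %d missing cells with gene medians", len(rows))
        else:
            i, j = map(int, next(zip(*np.nonzero(np.isnan(values)))))
            raise ValidationError(
                f"missing value at gene {gene_ids[i]!r}, sample "
                f"{sample_ids[j]!r}; pass impute='gene-median' to fill"
            )

    if log2:
        if (values < 0).any():
            raise ValidationError("negative values are incompatible with --log2")
        values = np.log2(values + 1.0)

    if cohort_map is None:
        cohort = np.array(["all"] * len(sample_ids), dtype=object)
    else:
        orphans = [s for s in sample_ids if s not in cohort_map]
        if orphans:
            raise JoinError(
                f"samples missing from cohort map: {orphans[:10]}",
                orphans=orphans,
            )
        cohort = np.array([cohort_map[s] for s in sample_ids], dtype=object)
    return ExpressionMatrix(gene_ids, sample_ids, values, cohort)


def write_expression(X: ExpressionMatrix, path) -> None:
    df = X.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_cohorts(X: ExpressionMatrix, path) -> None:
    pd.DataFrame({"sample_id": X.sample_ids, "cohort": X.cohort}).to_csv(
        path, sep="\t", index=False
    )


def read_cohorts(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample_id"], df["cohort"]))


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical-table contract and return a normalized copy."""
    df = df.copy()
    if "sample_id" not in df.columns or "histology" not in df.columns:
        raise ValidationError("clinical table needs sample_id and histology")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise IdentifierError(f"duplicate clinical sample ids: {dups[:10]}")
    bad = ~df["histology"].astype(str).isin(HISTOLOGY_LEVELS)
    if bad.any():
        raise ValidationError(
            f"unknown histology labels: {sorted(df.loc[bad, 'histology'].unique())}"
        )
    for tcol, ecol in (("surv_time", "surv_event"), ("rec_time", "rec_event")):
        if tcol in df.columns:
            t = pd.to_numeric(df[tcol], errors="raise")
            if (t.dropna() < 0).any():
                raise ValidationError(f"{tcol} must be nonnegative")
            e = pd.to_numeric(df[ecol], errors="raise")
            if not e.dropna().isin((0, 1)).all():
                raise ValidationError(f"{ecol} must be 0/1")
    return df


def read_clinical(path) -> pd.DataFrame:
    return validate_clinical(pd.read_csv(path, sep="\t"))


def write_clinical(df: pd.DataFrame, path) -> None:
    validate_clinical(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# batch adjustment and standardization
# ---------------------------------------------------------------------------

def cohort_mean_adjust(X: ExpressionMatrix) -> ExpressionMatrix:
    """Remove per-cohort batch effects by centering every gene within cohort.

    After adjustment the mean of every gene over each cohort's samples is
    zero; differences between samples of the same cohort are untouched.
    """
    values = X.values.copy()
    for c in pd.unique(X.cohort):
        mask = X.cohort == c
        if mask.sum() < 2:
            raise DegenerateCohortError(
                f"cohort {c!r} has {int(mask.sum())} sample(s); "
                "need >= 2 for mean adjustment"
            )
        values[:, mask] -= values[:, mask].mean(axis=1, keepdims=True)
    return ExpressionMatrix(X.gene_ids, X.sample_ids, values, X.cohort)


def standardize_genes(X: ExpressionMatrix):
    """Center and scale every gene to mean 0, SD 1 (sample SD, n-1).

    Returns the standardized matrix and a parameter table (gene_id, mean, sd)
    sufficient to transform new samples identically.
    """
    mean = X.values.mean(axis=1)
    sd = X.values.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd <= 0)
    if zero.size:
        raise ConstantGeneError(
            "zero-variance gene(s): "
            f"{[X.gene_ids[i] for i in zero[:10]]}"
        )
    values = (X.values - mean[:, None]) / sd[:, None]
    params = pd.DataFrame({"gene_id": X.gene_ids, "mean": mean, "sd": sd})
    return ExpressionMatrix(X.gene_ids, X.sample_ids, values, X.cohort), params


def apply_standardization(X: ExpressionMatrix,
                          params: pd.DataFrame) -> ExpressionMatrix:
    """Standardize ``X`` with previously estimated per-gene means and SDs."""
    p = params.set_index("gene_id")
    idx = X.gene_index(list(p.index))
    sub = X.values[idx]
    values = (sub - p["mean"].to_numpy()[:, None]) / p["sd"].to_numpy()[:, None]
    return ExpressionMatrix(list(p.index), X.sample_ids, values, X.cohort)


# ---------------------------------------------------------------------------
# JSON model round-trips
# ---------------------------------------------------------------------------

def save_json(obj: dict, path, schema: str, version: int = 1) -> None:
    payload = {"schema": schema, "schema_version": version, **obj}
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonify))


def load_json(path, schema: str) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != schema:
        raise ValidationError(
            f"expected schema {schema!r}, found {payload.get('schema')!r}"
        )
    return payload


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
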