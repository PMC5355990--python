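"""Synthetic multi-cohort tumor expression data and a synthetic drug screen.

The generator emulates the statistical structure the downstream analysis
assumes: several cohorts with additive per-gene batch shifts, a minority
lobular class (~11% prevalence), a subset of class-informative genes whose
effects are shared across cohorts, a bimodal E-cadherin-like marker whose
low mode is far more common in lobular tumors, grade distributions skewed
by class, class-linked exponential survival with administrative censoring,
and an optional sequencing-like re-measurement with a wider dynamic range.

A companion generator produces a cell-line panel in which a latent
"lobular-likeness" score drives both the expression profile and, for
compounds of designated sensitive classes, the growth-inhibition readout.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import ExpressionMatrix

# class-conditional grade probabilities (grades 1, 2, 3): lobular tumors
# skew to grade 2, ductal to grade 3
GRADE_PROBS = {
    "lobular": (0.17, 0.65, 0.18),
    "ductal": (0.11, 0.41, 0.48),
}

MARKER_GENE = "CDH1"


@dataclass
class SimulationSpec:
    """Generating parameters for the multi-cohort tumor simulation.

    Effect sizes and SDs are in units of the within-class noise SD of a
    log2-expression value. The marker gene is drawn from a two-mode
    mixture whose low mode occurs in 45% of lobular vs 5% of ductal
    samples; survival is exponential (months) with a ductal hazard ratio
    >1 and administrative censoring at a 10-year horizon.
    """

    n_cohorts: int = 3
    n_per_cohort: int = 200
    lobular_fraction: float = 0.11
    n_genes: int = 2000
    n_informative: int = 100
    effect_size_sd: float = 1.0
    batch_sd: float = 0.5
    noise_sd: float = 1.0
    marker_low_mean: float = -2.0
    marker_high_mean: float = 2.0
    marker_sd: float = 0.5
    p_low_lobular: float = 0.45
    p_low_ductal: float = 0.05
    grade_na_prob: float = 0.05
    baseline_hazard: float = 0.004
    hr_ductal: float = 2.0
    rec_hazard_scale: float = 1.5
    censor_horizon: float = 120.0
    platform: str = "array"
    rnaseq_scale: float = 1.6
    rnaseq_noise_sd: float = 0.3
    rnaseq_noise_df: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.lobular_fraction < 1:
            raise ConfigurationError("lobular_fraction must be in (0,1)")
        if self.n_informative > self.n_genes - 1:
            raise ConfigurationError(
                "n_informative must leave room for the marker gene"
            )
        for name in ("batch_sd", "noise_sd", "marker_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.effect_size_sd < 0:
            raise ConfigurationError("effect_size_sd must be >= 0")
        if self.platform not in ("array", "rnaseq_like"):
            raise ConfigurationError(f"unknown platform {self.platform!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def simulate_cohorts(spec: SimulationSpec):
    """Generate (expression, clinical, truth) for a multi-cohort study.

    The truth record carries the informative gene list, the per-gene
    class-mean differences (lobular minus ductal, fixed across cohorts),
    the true class of every sample and the full generating spec, which
    together suffice to recompute the class-conditional means exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cohorts * spec.n_per_cohort

    gene_ids = [MARKER_GENE] + [f"G{i:05d}" for i in range(1, spec.n_genes)]
    informative = gene_ids[1:1 + spec.n_informative]
    sample_ids = [f"S{i:05d}" for i in range(n)]
    cohort = np.repeat([f"cohort{c + 1}" for c in range(spec.n_cohorts)],
                       spec.n_per_cohort).astype(object)

    y = (rng.random(n) < spec.lobular_fraction).astype(int)  # 1 = lobular
    effects = rng.normal(0.0, spec.effect_size_sd, spec.n_informative)

    values = rng.normal(0.0, spec.noise_sd, (spec.n_genes, n))
    # class signal: lobular mean +d/2, ductal mean -d/2, shared across cohorts
    values[1:1 + spec.n_informative] += np.outer(effects, y - 0.5)
    # marker gene: two-mode mixture, class-dependent low-mode probability
    p_low = np.where(y == 1, spec.p_low_lobular, spec.p_low_ductal)
    low = rng.random(n) < p_low
    mode_mean = np.where(low, spec.marker_low_mean, spec.marker_high_mean)
    values[0] = mode_mean + rng.normal(0.0, spec.marker_sd, n)
    # additive per-gene per-cohort batch shifts
    batch = rng.normal(0.0, spec.batch_sd, (spec.n_genes, spec.n_cohorts))
    for c in range(spec.n_cohorts):
        values[:, cohort == f"cohort{c + 1}"] += batch[:, [c]]

    X = ExpressionMatrix(gene_ids, sample_ids, values, cohort)
    if spec.platform == "rnaseq_like":
        X = rnaseq_like_transform(X, spec, seed=int(rng.integers(2**31 - 1)))

    clinical = _simulate_clinical(spec, rng, sample_ids, y)
    truth = {
        "informative_genes": list(informative),
        "effects": dict(zip(informative, effects.tolist())),
        "classes": dict(zip(sample_ids,
                            np.where(y == 1, "lobular", "ductal").tolist())),
        "marker_gene": MARKER_GENE,
        "marker_low": dict(zip(sample_ids, low.astype(int).tolist())),
        "spec": spec.to_dict(),
    }
    return X, clinical, truth


def _simulate_clinical(spec, rng, sample_ids, y) -> pd.DataFrame:
    n = len(sample_ids)
    histology = np.where(y == 1, "lobular", "ductal").astype(object)

    grade = np.empty(n, dtype=object)
    for cls in ("lobular", "ductal"):
        mask = histology == cls
        grade[mask] = rng.choice([1, 2, 3], size=int(mask.sum()),
                                 p=GRADE_PROBS[cls])
    grade[rng.random(n) < spec.grade_na_prob] = "NA"

    # lobular tumors are predominantly ER positive; ductal less so
    er = np.where(rng.random(n) < np.where(y == 1, 0.95, 0.75), "pos", "neg")
    stage = rng.choice([1, 2, 3], size=n, p=(0.35, 0.45, 0.20))

    hazard = spec.baseline_hazard * np.where(y == 1, 1.0, spec.hr_ductal)
    surv = rng.exponential(1.0 / hazard)
    rec = rng.exponential(1.0 / (hazard * spec.rec_hazard_scale))
    horizon = spec.censor_horizon
    return pd.DataFrame({
        "sample_id": sample_ids,
        "histology": histology,
        "grade": grade,
        "stage": stage,
        "er": er,
        "surv_time": np.minimum(surv, horizon),
        "surv_event": (surv <= horizon).astype(int),
        "rec_time": np.minimum(rec, horizon),
        "rec_event": (rec <= horizon).astype(int),
    })


def rnaseq_like_transform(X: ExpressionMatrix, spec: SimulationSpec,
                          seed: int = 0) -> ExpressionMatrix:
    """Re-measure the same samples on a sequencing-like platform.

    The per-gene dynamic range is widened by a multiplicative factor about
    the gene mean and heavier-tailed (Student-t) measurement noise is
    added. This is a stand-in for platform differences, not a quantitative
    model of RNA-seq; it is used to exercise cross-platform scoring.
    """
    rng = np.random.default_rng(seed)
    center = X.values.mean(axis=1, keepdims=True)
    noise = rng.standard_t(spec.rnaseq_noise_df, X.values.shape)
    values = center + spec.rnaseq_scale * (X.values - center) \
        + spec.rnaseq_noise_sd * noise
    return ExpressionMatrix(X.gene_ids, X.sample_ids, values, X.cohort)


# ---------------------------------------------------------------------------
# cell-line panel with growth-inhibition screen
# ---------------------------------------------------------------------------

def simulate_cell_panel(n_lines: int, n_compounds: int, n_classes: int,
                        coupling: float, seed: int, truth: dict | None = None,
                        n_sensitive: int = 20, noise_sd: float = 1.0):
    """Generate a cell-line expression panel and a per-compound GI50 screen.

    Each line receives a latent lobular-likeness score (standard normal).
    Expression is generated with the same informative-gene effects as the
    tumor simulation (pass its ``truth`` record so a classifier trained on
    the tumors can score the panel), scaled by the latent score. Compounds
    of the first, designated-sensitive class have -log10(GI50) correlated
    with the latent score at strength ``coupling``; all other compounds are
    independent noise.

    Returns (expression, gi50 lines x compounds DataFrame of -log10 molar
    GI50, compound class table, latent scores Series).
    """
    if not -1.0 <= coupling <= 1.0:
        raise ConfigurationError("coupling must be in [-1, 1]")
    if n_lines < 2:
        raise ConfigurationError("need at least 2 cell lines")
    if n_lines < 10:
        warnings.warn(
            f"n_lines={n_lines}: per-compound correlations are degenerate "
            "at so few lines", UserWarning, stacklevel=2,
        )
    if n_classes < 1 or n_sensitive > n_compounds:
        raise ConfigurationError("invalid class layout")

    rng = np.random.default_rng(seed)
    if truth is None:
        spec = SimulationSpec(seed=seed)
        gene_ids = [MARKER_GENE] + [f"G{i:05d}" for i in range(1, spec.n_genes)]
        informative = gene_ids[1:1 + spec.n_informative]
        effects = dict(zip(
            informative,
            rng.normal(0.0, spec.effect_size_sd, spec.n_informative).tolist(),
        ))
    else:
        spec = SimulationSpec(**truth["spec"])
        gene_ids = [truth["marker_gene"]] + [
            f"G{i:05d}" for i in range(1, spec.n_genes)]
        effects = truth["effects"]

    latent = rng.standard_normal(n_lines)
    line_ids = [f"CL{i:03d}" for i in range(n_lines)]

    values = rng.normal(0.0, noise_sd, (len(gene_ids), n_lines))
    eff = np.array([effects.get(g, 0.0) for g in gene_ids])
    values += np.outer(eff, latent) / 2.0
    # marker: low-mode probability interpolates with lobular-likeness
    from scipy.stats import norm

    p_low = spec.p_low_ductal + (spec.p_low_lobular - spec.p_low_ductal) \
        * norm.cdf(latent)
    low = rng.random(n_lines) < p_low
    values[0] = np.where(low, spec.marker_low_mean, spec.marker_high_mean) \
        + rng.normal(0.0, spec.marker_sd, n_lines)
    X = ExpressionMatrix(gene_ids, line_ids, values,
                         np.array(["panel"] * n_lines, dtype=object))

    compound_ids = [f"D{j:05d}" for j in range(n_compounds)]
    noise = rng.standard_normal((n_lines, n_compounds))
    gi50 = 5.0 + noise  # -log10 molar GI50, ~10 uM scale
    sens = slice(0, n_sensitive)
    gi50[:, sens] = 5.0 + coupling * latent[:, None] \
        + np.sqrt(max(0.0, 1.0 - coupling**2)) * noise[:, sens]
    gi50 = pd.DataFrame(gi50, index=line_ids, columns=compound_ids)

    classes = np.empty(n_compounds, dtype=object)
    classes[sens] = "sensitive_class"
    rest = np.arange(n_sensitive, n_compounds)
    others = max(1, n_classes - 1)
    classes[rest] = [f"class{1 + (j % others)}" for j in range(rest.size)]
    class_table = pd.DataFrame({"compound_id": compound_ids, "class": classes})

    return X, gi50, class_table, pd.Series(latent, index=line_ids, name="latent")
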