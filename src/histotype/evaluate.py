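"""Concordance, grade cross-tabulation and survival comparison of calls.

Concordance is reported two ways, mirroring the two columns of the
diagnosis-comparison table: over all samples forced to a call (plain) and
over called samples only, excluding indeterminates (strict). Survival uses
the Kaplan-Meier product-limit estimator truncated at a 10-year horizon and
a from-scratch logrank test; univariate Cox hazard ratios (with the
likelihood-ratio p) are delegated to lifelines for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .exceptions import GroupingError, JoinError, ValidationError

HORIZON_MONTHS = 120.0


# ---------------------------------------------------------------------------
# concordance (Table-3-style) reporting
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    table: pd.DataFrame                 # per-cohort pathology x predicted counts
    plain_concordance: float
    strict_concordance: float
    indeterminacy_rate: float
    reclassification_rate: float
    n: int
    n_excluded_histology: int


def concordance_report(calls: pd.DataFrame,
                       clinical: pd.DataFrame) -> ConcordanceReport:
    """Compare plain and strict calls against pathological diagnosis.

    ``calls`` needs sample_id, cohort, call_plain and call_strict columns
    (see :func:`histotype.classifier.annotate_calls`). Samples whose
    histology is neither ductal nor lobular are excluded from concordance
    and counted separately.
    """
    need = {"sample_id", "call_plain", "call_strict"}
    if not need <= set(calls.columns):
        raise ValidationError(f"calls table needs columns {sorted(need)}")
    clin = clinical.set_index("sample_id")
    orphans = [s for s in calls["sample_id"] if s not in clin.index]
    if orphans:
        raise JoinError(
            f"{len(orphans)} call sample(s) missing from clinical table: "
            f"{orphans[:10]}", orphans=orphans)
    df = calls.copy()
    df["histology"] = clin.loc[df["sample_id"], "histology"].to_numpy()
    if "cohort" not in df.columns:
        df["cohort"] = "all"

    unambiguous = df["histology"].isin(("ductal", "lobular"))
    n_excluded = int((~unambiguous).sum())
    d = df[unambiguous]
    if len(d) == 0:
        raise ValidationError("no unambiguous ductal/lobular samples")

    plain_ok = d["call_plain"] == d["histology"]
    called = d["call_strict"] != "indeterminate"
    strict_ok = d.loc[called, "call_strict"] == d.loc[called, "histology"]
    recl = (~plain_ok).mean()

    table = (d.groupby(["cohort", "histology", "call_strict"], observed=True)
             .size().rename("count").reset_index())
    return ConcordanceReport(
        table=table,
        plain_concordance=float(plain_ok.mean()),
        strict_concordance=float(strict_ok.mean()) if called.any() else np.nan,
        indeterminacy_rate=float((~called).mean()),
        reclassification_rate=float(recl),
        n=int(len(d)),
        n_excluded_histology=n_excluded,
    )


def grade_crosstab(calls: pd.DataFrame,
                   clinical: pd.DataFrame) -> pd.DataFrame:
    """Pathology x predicted x grade counts (Table-4 shape) with margins."""
    clin = clinical.set_index("sample_id")
    df = calls.copy()
    df["histology"] = clin.loc[df["sample_id"], "histology"].to_numpy()
    grade = clin.loc[df["sample_id"], "grade"].astype(object).to_numpy()
    df["grade"] = np.where(pd.isna(grade), "NA", grade.astype(str))
    call_col = "call_plain" if "call_plain" in df.columns else "call"
    tab = pd.crosstab([df["histology"], df[call_col]], df["grade"],
                      margins=True, margins_name="total")
    for g in ("1", "2", "3", "NA"):
        if g not in tab.columns:
            tab[g] = 0
    order = [c for c in ("1", "2", "3", "NA", "total") if c in tab.columns]
    return tab[order]


# ---------------------------------------------------------------------------
# Kaplan-Meier and logrank
# ---------------------------------------------------------------------------

@dataclass
class SurvivalResult:
    curves: dict                        # group -> DataFrame(time, survival, at_risk)
    horizon: float
    chi2: float = np.nan
    p_logrank: float = np.nan
    observed: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)
    hazard_ratio: float = np.nan
    hr_ci: tuple = (np.nan, np.nan)
    p_cox_lrt: float = np.nan


def _truncate(times, events, horizon):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValidationError("survival times must be nonnegative")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("event flags must be 0/1")
    over = times > horizon
    return np.where(over, horizon, times), np.where(over, 0, events)


def _product_limit(times, events) -> pd.DataFrame:
    """Kaplan-Meier estimate over the distinct observed times (plus t=0)."""
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = [] if times.min() == 0.0 else [(0.0, 1.0, len(times))]
    s = 1.0
    for t in np.unique(times):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        if d > 0:
            s *= 1.0 - d / at_risk
        rows.append((float(t), s, at_risk))
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk"])


def km_estimate(times, events, group=None,
                horizon: float = HORIZON_MONTHS) -> SurvivalResult:
    """Product-limit survival curves per group, truncated at the horizon."""
    times, events = _truncate(times, events, horizon)
    group = np.asarray(["all"] * len(times) if group is None else group)
    curves = {}
    for g in pd.unique(group):
        m = group == g
        curves[g] = _product_limit(times[m], events[m])
    return SurvivalResult(curves=curves, horizon=horizon)


def logrank_test(times, events, group,
                 horizon: float = HORIZON_MONTHS) -> SurvivalResult:
    """Two-group logrank test via the standard hypergeometric O/E/V tally."""
    times, events = _truncate(times, events, horizon)
    group = np.asarray(group)
    gs = pd.unique(group)
    if len(gs) != 2:
        raise GroupingError(f"logrank needs exactly 2 groups, found {len(gs)}")
    if events.sum() < 1:
        raise GroupingError("no events observed")
    g1 = group == gs[0]
    O = {g: 0.0 for g in gs}
    E = {g: 0.0 for g in gs}
    V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        dead = (times == t) & (events == 1)
        d = dead.sum()
        d1 = (dead & g1).sum()
        O[gs[0]] += d1
        O[gs[1]] += d - d1
        E[gs[0]] += d * n1 / n
        E[gs[1]] += d * (n - n1) / n
        if n > 1:
            V += d * (n1 / n) * ((n - n1) / n) * (n - d) / (n - 1)
    chi2 = (O[gs[0]] - E[gs[0]]) ** 2 / V if V > 0 else 0.0
    p = float(stats.chi2.sf(chi2, 1)) if V > 0 else 1.0

    res = km_estimate(times, events, group, horizon)
    res.chi2 = float(chi2)
    res.p_logrank = p
    res.observed = {g: float(O[g]) for g in gs}
    res.expected = {g: float(E[g]) for g in gs}
    return res


def cox_hazard_ratio(times, events, group, reference,
                     horizon: float = HORIZON_MONTHS) -> SurvivalResult:
    """Univariate Cox HR (non-reference vs reference) with the LRT p-value."""
    res = logrank_test(times, events, group, horizon)
    times, events = _truncate(times, events, horizon)
    df = pd.DataFrame({
        "time": times, "event": events,
        "x": (np.asarray(group) != reference).astype(int),
    })
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    res.hazard_ratio = float(np.exp(cph.params_["x"]))
    ci = cph.confidence_intervals_
    res.hr_ci = tuple(np.exp(ci.loc["x"]).tolist())
    res.p_cox_lrt = float(cph.log_likelihood_ratio_test().p_value)
    return res
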