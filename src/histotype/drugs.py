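"""Drug-sensitivity correlation of lobular scores across a cell-line panel.

Cell lines are scored with the histotype classifier exactly as tumors are;
each compound's -log10(GI50) profile is Pearson-correlated with the scores
(positive r: more lobular-like lines are more sensitive). Compound classes
are tested for shifted correlations with a Welch two-sample T of member vs
non-member correlations, Bonferroni-corrected over the classes tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import HistotypeClassifier, score_samples
from .exceptions import ConfigurationError, ValidationError
from .io import ExpressionMatrix


@dataclass
class DrugPanel:
    """GI50 screen: lines x compounds of -log10 molar GI50 + class labels."""

    gi50: pd.DataFrame                   # index line_ids, columns compound_ids
    class_map: dict                      # compound_id -> set of class labels

    def __post_init__(self):
        if self.gi50.isna().all(axis=0).any():
            bad = self.gi50.columns[self.gi50.isna().all(axis=0)].tolist()
            raise ValidationError(f"all-missing compound columns: {bad[:10]}")
        self.class_map = {c: set(v) if not isinstance(v, str) else {v}
                          for c, v in self.class_map.items()}
        if any(not lab for labs in self.class_map.values() for lab in labs):
            raise ValidationError("empty class label")

    @classmethod
    def from_tables(cls, gi50: pd.DataFrame, classes: pd.DataFrame,
                    neg_log10: bool = True) -> "DrugPanel":
        """Build from a GI50 table and a (compound_id, class) long table.

        ``neg_log10=False`` declares the table to carry raw molar GI50,
        which is converted to -log10 here.
        """
        g = gi50 if neg_log10 else -np.log10(gi50)
        cmap = {}
        for _, row in classes.iterrows():
            cmap.setdefault(row["compound_id"], set()).add(row["class"])
        return cls(gi50=g, class_map=cmap)


def score_panel(clf: HistotypeClassifier, X: ExpressionMatrix) -> pd.Series:
    """Lobular score per cell line (same scoring contract as tumors)."""
    scores = score_samples(clf, X)
    return pd.Series(scores["score"].to_numpy(),
                     index=scores["sample_id"].to_numpy(), name="score")


def compound_correlations(scores: pd.Series, panel: DrugPanel,
                          min_lines: int = 10) -> pd.DataFrame:
    """Pairwise-complete Pearson r of each compound's sensitivity vs score.

    Compounds with fewer than ``min_lines`` non-missing lines or with a
    constant sensitivity profile are dropped; drop counts are reported in
    ``result.attrs``.
    """
    common = [l for l in panel.gi50.index if l in scores.index]
    if len(common) < 3:
        raise ValidationError("need >= 3 cell lines shared with the scores")
    g = panel.gi50.loc[common]
    s = scores.loc[common].to_numpy(dtype=float)

    rows = []
    n_few, n_const = 0, 0
    for comp in g.columns:
        v = g[comp].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if ok.sum() < min_lines:
            n_few += 1
            continue
        if np.ptp(v[ok]) == 0 or np.ptp(s[ok]) == 0:
            n_const += 1
            continue
        r = float(stats.pearsonr(s[ok], v[ok]).statistic)
        rows.append({"compound_id": comp, "n_lines": int(ok.sum()), "r": r})
    out = pd.DataFrame(rows, columns=["compound_id", "n_lines", "r"])
    out.attrs["n_dropped_min_lines"] = n_few
    out.attrs["n_dropped_constant"] = n_const
    return out


def class_shift_test(per_compound: pd.DataFrame, class_map: dict,
                     classes_tested=None) -> pd.DataFrame:
    """Welch T of member vs non-member correlations per compound class.

    Bonferroni correction multiplies each raw p by the number of classes
    actually tested in this run. Classes with fewer than 3 members among
    the correlated compounds are skipped with a warning.
    """
    cmap = {c: (set(v) if not isinstance(v, str) else {v})
            for c, v in class_map.items()}
    if classes_tested is None:
        classes_tested = sorted({lab for labs in cmap.values() for lab in labs})
    r = per_compound.set_index("compound_id")["r"]

    rows = []
    for cls in classes_tested:
        members = [c for c in r.index if cls in cmap.get(c, ())]
        if len(members) < 3:
            warnings.warn(f"class {cls!r} has {len(members)} correlated "
                          "member(s) (< 3); skipped", UserWarning, stacklevel=2)
            continue
        rm = r.loc[members].to_numpy()
        rn = r.drop(index=members).to_numpy()
        if rn.size < 3:
            warnings.warn(f"class {cls!r} leaves too few non-members; skipped",
                          UserWarning, stacklevel=2)
            continue
        t, p = stats.ttest_ind(rm, rn, equal_var=False)
        rows.append({"class": cls, "n_compounds": len(members),
                     "mean_r": float(rm.mean()), "t": float(t),
                     "p_raw": float(p)})
    if not rows:
        raise ConfigurationError("no testable classes (all < 3 members)")
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * len(out))
    out.attrs["n_classes_tested"] = len(out)
    return out.sort_values("p_bonferroni").reset_index(drop=True)
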