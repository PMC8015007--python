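"""Scoring of detection results against simulated ground truth."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from tmtdiff.modeling import ISSUE_NONE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _truth_flags(results: pd.DataFrame, truth: pd.DataFrame) -> pd.Series:
    """Differential flag per result row, joined on protein (and label when
    the truth table is per-comparison)."""
    unknown = set(results["Protein"]) - set(truth["Protein"])
    if unknown:
        raise KeyError(
            f"proteins present in results but absent from ground truth: "
            f"{sorted(unknown)[:5]}"
        )
    if "Label" in truth.columns:
        t = truth.drop_duplicates(subset=["Protein", "Label"])
        merged = results.merge(
            t[["Protein", "Label", "Differential"]],
            on=["Protein", "Label"], how="left",
        )
        if not merged["Differential"].isna().any():
            return merged["Differential"].astype(bool)
    # fall back to a per-protein flag when the truth has no matching labels
    t = truth.groupby("Protein")["Differential"].any().reset_index()
    merged = results.merge(t, on="Protein", how="left")
    return merged["Differential"].astype(bool)


def confusion_counts(
    results: pd.DataFrame, truth: pd.DataFrame, alpha: float = 0.05
) -> ConfusionCounts:
    """TP/FP/TN/FN over the testable proteins of one comparison label.

    A protein is called positive when its BH-adjusted p-value is below
    ``alpha``.  The four counts partition the testable proteins.
    """
    if results["Label"].nunique() > 1:
        raise ValueError("confusion_counts expects results for a single label")
    testable = results[results["issue"] == ISSUE_NONE].reset_index(drop=True)
    flags = _truth_flags(testable, truth)
    called = testable["adj.pvalue"].to_numpy(dtype=float) < alpha
    tp = int(np.sum(called & flags))
    fp = int(np.sum(called & ~flags))
    fn = int(np.sum(~called & flags))
    tn = int(np.sum(~called & ~flags))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def efdr_sens_spec(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(eFDR, sensitivity, specificity).

    eFDR = FP/(TP+FP) (0 by convention when nothing is called),
    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
    """
    called = counts.tp + counts.fp
    efdr = counts.fp / called if called else 0.0
    pos = counts.tp + counts.fn
    sens = counts.tp / pos if pos else np.nan
    neg = counts.tn + counts.fp
    spec = counts.tn / neg if neg else np.nan
    return float(efdr), float(sens), float(spec)


def roc_auc(results: pd.DataFrame, truth: pd.DataFrame) -> float:
    """AUC of ranking proteins by ascending adjusted p-value.

    Computed through the Mann-Whitney identity, so ties contribute half.
    Returns NaN (with a warning) when the truth contains a single class.
    """
    testable = results[
        (results["issue"] == ISSUE_NONE) & results["adj.pvalue"].notna()
    ].reset_index(drop=True)
    flags = _truth_flags(testable, truth).to_numpy()
    n1 = int(flags.sum())
    n0 = int((~flags).sum())
    if n1 == 0 or n0 == 0:
        warnings.warn("roc_auc: ground truth has a single class; AUC undefined")
        return float("nan")
    score = -testable["adj.pvalue"].to_numpy(dtype=float)  # higher = more significant
    ranks = rankdata(score)
    u1 = ranks[flags].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))


def evaluate_all_labels(
    results: pd.DataFrame, truth: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-label metrics table: counts, eFDR, sensitivity, specificity, AUC."""
    rows = []
    for label, sub in results.groupby("Label", sort=True):
        counts = confusion_counts(sub, truth, alpha=alpha)
        efdr, sens, spec = efdr_sens_spec(counts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            auc = roc_auc(sub, truth)
        rows.append(
            {
                "Label": label,
                "Testable": counts.total,
                "TP": counts.tp, "FP": counts.fp,
                "TN": counts.tn, "FN": counts.fn,
                "eFDR": efdr, "Sensitivity": sens, "Specificity": spec,
                "AUC": auc,
            }
        )
    return pd.DataFrame(rows)
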