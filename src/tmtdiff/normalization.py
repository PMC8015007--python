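"""Normalization layers.

``global_median_normalize`` equalizes per-(run, channel) medians of the
log2 spectrum intensities across the whole experiment.

``reference_channel_normalize`` aligns, per protein, the reference-channel
("Norm") summaries of every run to their between-run median, shifting all
channels of the run along with them.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from tmtdiff.design import REFERENCE_CONDITION
from tmtdiff.errors import NoReferenceChannelsError

logger = logging.getLogger(__name__)


def global_median_normalize(ft: pd.DataFrame) -> pd.DataFrame:
    """Equalize the median log2 intensity of every (run, channel) column.

    Each column is shifted by ``g - m_rc`` where ``m_rc`` is the column's
    median over observed features and ``g`` is the median of all column
    medians, so the overall intensity scale is preserved.  Columns with no
    observed intensities are skipped with a warning.
    """
    out = ft.copy()
    med = out.groupby(["Run", "Channel"])["Log2Intensity"].median()
    empty = med.index[med.isna()]
    for run, channel in empty:
        logger.warning(
            "global_median_normalize: (run=%s, channel=%s) has no observed "
            "intensities; left untouched", run, channel,
        )
    g = med.median()
    shifts = (g - med).fillna(0.0)
    key = pd.MultiIndex.from_frame(out[["Run", "Channel"]])
    out["Log2Intensity"] = out["Log2Intensity"] + shifts.reindex(key).to_numpy()
    return out


def reference_channel_normalize(pst: pd.DataFrame) -> pd.DataFrame:
    """Per-protein between-run alignment using the reference channels.

    For each protein, the reference summary of run *r* (the mean of the run's
    "Norm"-channel summaries when there are several) is shifted to the median
    of the reference summaries over all runs; the same shift is applied to
    every channel of the protein in that run.  Runs where the protein has no
    reference summary are left unshifted and flagged in the ``NormIssue``
    column.
    """
    is_ref = pst["Condition"].astype(str) == REFERENCE_CONDITION
    if not is_ref.any():
        raise NoReferenceChannelsError(
            "the design has no reference ('Norm') channels; re-run with "
            "reference normalization disabled (no-reference mode)"
        )
    out = pst.copy()
    if "NormIssue" not in out.columns:
        out["NormIssue"] = ""

    refs = (
        out[is_ref]
        .groupby(["Protein", "Run"])["Abundance"]
        .mean()  # several reference channels in a run: average on log2 scale
        .rename("ref")
        .reset_index()
    )
    med = refs.groupby("Protein")["ref"].median().rename("ref_median")
    refs = refs.merge(med, on="Protein")
    refs["shift"] = refs["ref_median"] - refs["ref"]

    out = out.merge(refs[["Protein", "Run", "shift"]], on=["Protein", "Run"], how="left")
    no_ref = out["shift"].isna()
    if no_ref.any():
        out.loc[no_ref, "NormIssue"] = "noReferenceSummaryInRun"
        out.loc[no_ref, "shift"] = 0.0
    out["Abundance"] = out["Abundance"] + out["shift"]
    return out.drop(columns="shift")
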