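"""Read PSM quantification reports, apply feature-construction filters, and
build the canonical long-format feature table.

Canonical PSM columns
---------------------
``ProteinName, PeptideIon, PSM, Run, Fraction, Channel, Intensity,
Interference``.  One row per (spectrum, run, channel).  ``Fraction`` and
``Interference`` are optional and may be entirely NA.

Canonical feature-table columns
-------------------------------
``ProteinName, Feature, Run, Mixture, TechRepMixture, Channel, Condition,
BioReplicate, Log2Intensity, TestablePrecheck``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from tmtdiff.design import ANNOTATION_COLUMNS, REFERENCE_CONDITION, ExperimentDesign
from tmtdiff.errors import (
    AnnotationError,
    EmptyInputError,
    JoinError,
    SchemaError,
)

logger = logging.getLogger(__name__)

PSM_COLUMNS = [
    "ProteinName",
    "PeptideIon",
    "PSM",
    "Run",
    "Fraction",
    "Channel",
    "Intensity",
    "Interference",
]

FEATURE_COLUMNS = [
    "ProteinName",
    "Feature",
    "Run",
    "Mixture",
    "TechRepMixture",
    "Channel",
    "Condition",
    "BioReplicate",
    "Log2Intensity",
    "TestablePrecheck",
]

#: column requirements per supported report dialect
_LONG_REQUIRED = ["ProteinName", "Run", "Channel", "Intensity"]
_WIDE_META = ["ProteinName", "PeptideSequence", "Charge", "PSM", "Run", "Fraction",
              "Interference"]
_PD_RENAME = {
    "Master Protein Accessions": "ProteinName",
    "Protein Accessions": "ProteinName",
    "Annotated Sequence": "PeptideSequence",
    "Charge": "Charge",
    "Spectrum File": "Run",
    "First Scan": "Scan",
    "Isolation Interference [%]": "Interference",
    "Fraction": "Fraction",
}
_MQ_RENAME = {
    "Proteins": "ProteinName",
    "Modified sequence": "PeptideSequence",
    "Charge": "Charge",
    "Raw file": "Run",
    "MS/MS scan number": "Scan",
    "Fraction": "Fraction",
}


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file contains no data")
    if df.empty:
        raise EmptyInputError(f"{path}: file contains no data rows")
    return df


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def _make_ion(df: pd.DataFrame) -> pd.Series:
    """Peptide ion identifier = sequence + charge when charge is available."""
    seq = df["PeptideSequence"].astype(str)
    if "Charge" in df.columns:
        return seq + "_" + df["Charge"].astype(str)
    return seq


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    for col in PSM_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[PSM_COLUMNS].copy()
    df["Intensity"] = pd.to_numeric(df["Intensity"], errors="coerce")
    # zero / negative raw intensities carry no signal: treat as missing so
    # the later log2 transform stays finite
    df.loc[df["Intensity"] <= 0, "Intensity"] = np.nan
    for col in ("ProteinName", "PeptideIon", "PSM", "Run", "Channel"):
        df[col] = df[col].astype(str)
    dup = df.duplicated(subset=["PSM", "Run", "Channel"])
    if dup.any():
        offenders = df.loc[dup, ["PSM", "Run", "Channel"]].head(5).to_dict("records")
        raise SchemaError(
            f"duplicate (spectrum, run, channel) rows in PSM report, e.g. {offenders}"
        )
    return df.reset_index(drop=True)


def _melt_wide(df: pd.DataFrame, meta_cols, channel_cols) -> pd.DataFrame:
    if not channel_cols:
        raise SchemaError("wide PSM report has no channel intensity columns")
    long = df.melt(
        id_vars=[c for c in meta_cols if c in df.columns],
        value_vars=channel_cols,
        var_name="Channel",
        value_name="Intensity",
    )
    return long


def read_psm_report(path, dialect: str = "long") -> pd.DataFrame:
    """Read a PSM-level quantification report.

    Parameters
    ----------
    path:
        TSV (or ``.csv``) report file.
    dialect:
        One of ``"long"``, ``"wide"``, ``"pd_like"``, ``"mq_like"``.

    Returns
    -------
    pandas.DataFrame
        Canonical PSM table, one row per (spectrum, run, channel), with zero
        and negative intensities converted to missing.
    """
    df = _read_table(path)
    if dialect == "long":
        _require(df, _LONG_REQUIRED, "long PSM report")
        df = df.copy()
        if "PeptideIon" not in df.columns:
            _require(df, ["PeptideSequence"], "long PSM report")
            df["PeptideIon"] = _make_ion(df)
        if "PSM" not in df.columns:
            df["PSM"] = df["PeptideIon"]
        long = df
    elif dialect == "wide":
        _require(df, ["ProteinName", "PeptideSequence", "Run"], "wide PSM report")
        channel_cols = [c for c in df.columns if c not in _WIDE_META]
        long = _melt_wide(df, _WIDE_META, channel_cols)
        long["PeptideIon"] = _make_ion(long)
        if "PSM" not in long.columns:
            long["PSM"] = long["PeptideIon"]
    elif dialect == "pd_like":
        df = df.rename(columns=_PD_RENAME)
        _require(df, ["ProteinName", "PeptideSequence", "Run"], "pd_like PSM report")
        channel_cols = [c for c in df.columns if c.startswith("Abundance")]
        if not channel_cols:
            raise SchemaError("pd_like PSM report has no 'Abundance: <channel>' columns")
        meta = [c for c in df.columns if c not in channel_cols]
        long = _melt_wide(df, meta, channel_cols)
        long["Channel"] = long["Channel"].str.replace(r"^Abundance:?\s*", "", regex=True)
        long["PeptideIon"] = _make_ion(long)
        long["PSM"] = (
            long["Run"].astype(str) + "_" + long.get("Scan", long["PeptideIon"]).astype(str)
        )
    elif dialect == "mq_like":
        df = df.rename(columns=_MQ_RENAME)
        _require(df, ["ProteinName", "PeptideSequence", "Run"], "mq_like PSM report")
        channel_cols = [c for c in df.columns if c.startswith("Reporter intensity")]
        if not channel_cols:
            raise SchemaError("mq_like PSM report has no 'Reporter intensity' columns")
        meta = [c for c in df.columns if c not in channel_cols]
        long = _melt_wide(df, meta, channel_cols)
        long["Channel"] = long["Channel"].str.replace(
            r"^Reporter intensity( corrected)?\s*", "channel", regex=True
        )
        long["PeptideIon"] = _make_ion(long)
        long["PSM"] = (
            long["Run"].astype(str) + "_" + long.get("Scan", long["PeptideIon"]).astype(str)
        )
    else:
        raise ValueError(f"unknown PSM report dialect: {dialect!r}")
    return _finalize(long)


def read_annotation(path) -> pd.DataFrame:
    """Read and validate a Run x Channel annotation table.

    Reference channels are the rows whose ``Condition`` equals the reserved
    label ``"Norm"``.
    """
    ann = _read_table(path)
    _require(ann, ANNOTATION_COLUMNS, "annotation")
    ann = ann[ANNOTATION_COLUMNS].astype(str)
    return validate_annotation(ann)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    _require(ann, ANNOTATION_COLUMNS, "annotation")
    ann = ann[ANNOTATION_COLUMNS].astype(str).reset_index(drop=True)
    dup = ann.duplicated(subset=["Run", "Channel"])
    if dup.any():
        offenders = ann.loc[dup, ["Run", "Channel"]].head(5).to_dict("records")
        raise AnnotationError(f"duplicate (Run, Channel) annotation rows: {offenders}")
    per_run = ann.groupby("Run")[["Mixture", "TechRepMixture"]].nunique()
    bad = per_run[(per_run["Mixture"] > 1) | (per_run["TechRepMixture"] > 1)]
    if not bad.empty:
        raise AnnotationError(
            f"runs mapped to more than one (Mixture, TechRepMixture): {list(bad.index)}"
        )
    ann["IsReference"] = ann["Condition"] == REFERENCE_CONDITION
    return ann


def filter_shared_and_sparse(
    psm: pd.DataFrame, max_missing_fraction: float = 0.5
) -> pd.DataFrame:
    """Drop peptide ions shared between proteins, and spectra with an
    excessive fraction of missing reporter channels.

    A spectrum is removed when (# missing channels) / (# channels) exceeds
    ``max_missing_fraction``.  A peptide ion mapping to more than one
    ``ProteinName`` is removed entirely.
    """
    if psm.empty:
        return psm.copy()
    out = psm.copy()
    shared = out.groupby("PeptideIon")["ProteinName"].transform("nunique") > 1
    n_shared = out.loc[shared, "PeptideIon"].nunique()
    if n_shared:
        logger.info("removing %d peptide ions shared by multiple proteins", n_shared)
    out = out[~shared]
    if out.empty:
        return out.reset_index(drop=True)
    grp = out.groupby(["PSM", "Run"])["Intensity"]
    missing_frac = grp.transform(lambda s: s.isna().mean())
    out = out[missing_frac <= max_missing_fraction]
    return out.reset_index(drop=True)


def select_best_spectrum(psm: pd.DataFrame) -> pd.DataFrame:
    """Keep a single best spectrum per (peptide ion, run).

    Selection is lexicographic: fewest missing channels, then highest summed
    intensity, then lowest interference score, then first spectrum id.
    """
    if psm.empty:
        return psm.copy()

    stats = (
        psm.groupby(["PeptideIon", "Run", "PSM"], sort=False)
        .agg(
            n_missing=("Intensity", lambda s: int(s.isna().sum())),
            total=("Intensity", lambda s: float(np.nansum(s.to_numpy()))),
            interference=("Interference", "first"),
        )
        .reset_index()
    )
    # missing interference ranks last among candidates that report one
    stats["interference"] = pd.to_numeric(stats["interference"], errors="coerce")
    stats["interference"] = stats["interference"].fillna(np.inf)
    stats = stats.sort_values(
        ["PeptideIon", "Run", "n_missing", "total", "interference", "PSM"],
        ascending=[True, True, True, False, True, True],
        kind="mergesort",
    )
    best = stats.drop_duplicates(subset=["PeptideIon", "Run"], keep="first")
    keys = set(map(tuple, best[["PeptideIon", "Run", "PSM"]].to_numpy()))
    mask = [
        (ion, run, spec) in keys
        for ion, run, spec in zip(psm["PeptideIon"], psm["Run"], psm["PSM"])
    ]
    return psm[mask].reset_index(drop=True)


def deduplicate_fractions(psm: pd.DataFrame) -> pd.DataFrame:
    """Keep each peptide ion only in the fraction where it is strongest.

    The retained fraction is the one with the highest mean intensity over the
    ion's channels and runs; ties go to the fraction with the highest maximal
    intensity, then to the lexicographically first fraction id.  A no-op when
    fraction ids are absent.
    """
    if psm.empty or psm["Fraction"].isna().all():
        return psm.copy()
    stats = (
        psm.groupby(["PeptideIon", "Fraction"], sort=False)["Intensity"]
        .agg(mean="mean", max="max")
        .reset_index()
    )
    stats["Fraction"] = stats["Fraction"].astype(str)
    stats = stats.sort_values(
        ["PeptideIon", "mean", "max", "Fraction"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    best = stats.drop_duplicates(subset=["PeptideIon"], keep="first")
    keys = set(map(tuple, best[["PeptideIon", "Fraction"]].to_numpy()))
    mask = [
        (ion, str(frac)) in keys
        for ion, frac in zip(psm["PeptideIon"], psm["Fraction"])
    ]
    return psm[mask].reset_index(drop=True)


def _testable_precheck(ft: pd.DataFrame) -> pd.Series:
    """Flag proteins that can possibly yield 'more than one summary value in
    more than one condition' (reference channels excluded)."""
    endo = ft[(ft["Condition"] != REFERENCE_CONDITION) & ft["Log2Intensity"].notna()]
    cells = endo.drop_duplicates(subset=["ProteinName", "Run", "Channel"])
    per_cond = cells.groupby(["ProteinName", "Condition"]).size()
    gt1 = (per_cond > 1).groupby("ProteinName").sum()
    ok = set(gt1[gt1 > 1].index)
    return ft["ProteinName"].isin(ok)


def build_feature_table(
    psm: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, ExperimentDesign]:
    """Join filtered PSM records to the annotation and log2-transform.

    Returns the canonical feature table together with the summarized
    :class:`~tmtdiff.design.ExperimentDesign`.  Proteins that cannot possibly
    satisfy the testability precheck are flagged (``TestablePrecheck`` column)
    but kept.
    """
    ann = validate_annotation(annotation)
    design = ExperimentDesign.from_annotation(ann)
    psm = psm.copy()
    psm["Run"] = psm["Run"].astype(str)
    psm["Channel"] = psm["Channel"].astype(str)
    merged = psm.merge(ann, on=["Run", "Channel"], how="left", validate="m:1")
    unmatched = merged["Condition"].isna()
    if unmatched.any():
        offenders = (
            merged.loc[unmatched, ["Run", "Channel"]]
            .drop_duplicates()
            .head(10)
            .to_dict("records")
        )
        raise JoinError(
            f"PSM rows with (Run, Channel) absent from the annotation: {offenders}"
        )
    ft = pd.DataFrame(
        {
            "ProteinName": merged["ProteinName"],
            "Feature": merged["PeptideIon"],
            "Run": merged["Run"],
            "Mixture": merged["Mixture"],
            "TechRepMixture": merged["TechRepMixture"],
            "Channel": merged["Channel"],
            "Condition": merged["Condition"],
            "BioReplicate": merged["BioReplicate"],
            "Log2Intensity": np.log2(merged["Intensity"].astype(float)),
        }
    )
    multi = ft.groupby("Feature")["ProteinName"].nunique()
    if (multi > 1).any():
        raise JoinError(
            "features mapping to more than one protein after filtering: "
            f"{list(multi[multi > 1].index[:5])}"
        )
    ft["TestablePrecheck"] = _testable_precheck(ft)
    return ft.reset_index(drop=True), design


def write_feature_table(ft: pd.DataFrame, path) -> None:
    # %.17g guarantees float64 round-trips bit-for-bit through the TSV
    ft.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    ft = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require(ft, [c for c in FEATURE_COLUMNS if c != "TestablePrecheck"], "feature table")
    for col in ("ProteinName", "Feature", "Run", "Mixture", "TechRepMixture",
                "Channel", "Condition", "BioReplicate"):
        ft[col] = ft[col].astype(str)
    return ft
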