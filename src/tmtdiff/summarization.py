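"""Protein summarization: censored-regression imputation of missing feature
intensities followed by Tukey's median polish, one protein and one run at a
time.

The per-(protein, run) data are viewed as a two-way additive layout with
feature rows and channel columns.  Missing cells are assumed to arise mostly
from low-abundance analytes and are imputed under an accelerated-failure-time
(Gaussian log-location-scale) model, treating them as left-censored at the
minimum observed intensity of the matrix.  The additive decomposition is then
re-estimated robustly by median polish, and the per-channel summary is
``overall + column effect``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "Protein",
    "Mixture",
    "TechRepMixture",
    "Run",
    "Channel",
    "Condition",
    "BioReplicate",
    "Abundance",
    "NFeatures",
]

CELL_OBSERVED = 0
CELL_IMPUTED = 1
CELL_MISSING = 2


@dataclass
class ProteinRunMatrix:
    """Feature x channel log2 intensities of one protein in one run."""

    protein: str
    run: str
    features: list
    channels: list
    values: np.ndarray  # (F, K) float with NaN for unquantified cells
    state: np.ndarray = field(default=None)  # (F, K) int cell states

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.state is None:
            self.state = np.where(np.isnan(self.values), CELL_MISSING, CELL_OBSERVED)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iter: int
    converged: bool


def median_polish(
    matrix, tol: float = 1e-4, max_iter: int = 100
) -> MedianPolishResult:
    """Tukey's median polish of a two-way table with possible missing cells.

    Alternately sweeps row medians (into row effects) and column medians
    (into column effects), rows first, ignoring NaN cells, until the relative
    reduction of the sum of absolute residuals drops below ``tol`` or
    ``max_iter`` sweeps are reached.
    """
    z = np.array(matrix, dtype=float, copy=True)
    if z.ndim != 2 or z.size == 0:
        raise ValueError("median_polish requires a non-empty 2-d matrix")
    if np.isnan(z).all():
        raise ValueError("median_polish: all cells are missing")
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    oldsum = 0.0
    converged = False
    it = 0
    def _nanmedian(arr, axis):
        # all-NaN slices (fully missing rows/columns) legitimately occur;
        # treat their median as 0 without numpy's warning chatter
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(arr, axis=axis)
        return np.where(np.isnan(med), 0.0, med)

    for it in range(1, max_iter + 1):
        rdelta = _nanmedian(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        delta = np.median(col)
        col -= delta
        overall += delta

        cdelta = _nanmedian(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        delta = np.median(row)
        row -= delta
        overall += delta

        newsum = np.nansum(np.abs(z))
        if newsum == 0 or abs(newsum - oldsum) < tol * newsum:
            converged = True
            break
        oldsum = newsum
    return MedianPolishResult(
        overall=float(overall),
        row_effects=row,
        col_effects=col,
        residuals=z,
        n_iter=it,
        converged=converged,
    )


def _censored_loglik(params, X_obs, y_obs, X_cen, threshold):
    *beta, log_scale = params
    beta = np.asarray(beta)
    scale = np.exp(log_scale)
    ll = stats.norm.logpdf(y_obs, loc=X_obs @ beta, scale=scale).sum()
    if X_cen.shape[0]:
        ll += stats.norm.logcdf(threshold, loc=X_cen @ beta, scale=scale).sum()
    return -ll


def aft_impute(
    prm: ProteinRunMatrix, censor_multiplier: float = 1.0
) -> ProteinRunMatrix:
    """Impute eligible missing cells under a left-censored Gaussian AFT model.

    A missing cell (feature f, channel k) is imputed only when feature f has
    at least one observed channel in the run AND channel k has at least one
    observed feature of the protein in the run.  The model regresses log2
    intensity on feature and channel main effects, with the eligible missing
    cells entering the likelihood as left-censored observations at the
    censoring threshold (``censor_multiplier`` times the matrix minimum).
    Predictions are capped at the threshold.  Observed cells are never
    modified; a non-converged fit leaves the matrix unchanged.
    """
    F, K = prm.values.shape
    if F < 2:
        return prm
    obs = ~np.isnan(prm.values)
    if not obs.any():
        return prm
    feat_has_obs = obs.any(axis=1)
    chan_has_obs = obs.any(axis=0)
    eligible = (~obs) & feat_has_obs[:, None] & chan_has_obs[None, :]
    if not eligible.any():
        return prm

    threshold = censor_multiplier * np.nanmin(prm.values)

    def design_row(f, k):
        x = np.zeros(1 + (F - 1) + (K - 1))
        x[0] = 1.0
        if f > 0:
            x[f] = 1.0
        if k > 0:
            x[F - 1 + k] = 1.0
        return x

    fo, ko = np.nonzero(obs)
    X_obs = np.array([design_row(f, k) for f, k in zip(fo, ko)])
    y_obs = prm.values[fo, ko]
    fc, kc = np.nonzero(eligible)
    X_cen = np.array([design_row(f, k) for f, k in zip(fc, kc)])

    beta0, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta0
    scale0 = max(float(np.std(resid)), 0.1)
    x0 = np.concatenate([beta0, [np.log(scale0)]])
    try:
        res = optimize.minimize(
            _censored_loglik,
            x0,
            args=(X_obs, y_obs, X_cen, threshold),
            method="BFGS",
            options={"maxiter": 500},
        )
        if not np.all(np.isfinite(res.x)):
            raise RuntimeError("non-finite AFT solution")
        beta = res.x[:-1]
    except Exception as exc:  # pragma: no cover - defensive
        logger.warning(
            "aft_impute: fit failed for protein=%s run=%s (%s); no imputation",
            prm.protein, prm.run, exc,
        )
        return prm

    values = prm.values.copy()
    state = prm.state.copy()
    pred = np.minimum(X_cen @ beta, threshold)
    values[fc, kc] = pred
    state[fc, kc] = CELL_IMPUTED
    return ProteinRunMatrix(
        protein=prm.protein,
        run=prm.run,
        features=prm.features,
        channels=prm.channels,
        values=values,
        state=state,
    )


def summarize_protein_run(prm: ProteinRunMatrix) -> tuple[np.ndarray, int]:
    """Per-channel protein summary for one run.

    Returns ``(abundances, n_features_used)`` where ``abundances`` follows the
    channel order of the matrix.  Channels with no observed-or-imputed cell
    get NaN.  Single-feature proteins bypass median polish and pass the
    feature's intensities through.
    """
    usable = ~np.isnan(prm.values)
    n_used = int(usable.any(axis=1).sum())
    if prm.n_features == 1:
        return prm.values[0].copy(), n_used
    mp = median_polish(prm.values)
    y = mp.overall + mp.col_effects
    y = np.where(usable.any(axis=0), y, np.nan)
    return y, n_used


def iter_protein_run_matrices(ft: pd.DataFrame):
    """Yield (metadata frame, ProteinRunMatrix) per (protein, run).

    The metadata frame has one row per channel of the run (annotation order)
    with Mixture/TechRepMixture/Condition/BioReplicate columns.
    """
    for (protein, run), grp in ft.groupby(["ProteinName", "Run"], sort=True):
        channels = (
            grp[["Channel", "Mixture", "TechRepMixture", "Condition", "BioReplicate"]]
            .drop_duplicates(subset="Channel")
            .sort_values("Channel", kind="mergesort")
            .reset_index(drop=True)
        )
        mat = (
            grp.pivot_table(
                index="Feature",
                columns="Channel",
                values="Log2Intensity",
                aggfunc="first",
                dropna=False,
            )
            .reindex(columns=channels["Channel"])
            .sort_index()
        )
        prm = ProteinRunMatrix(
            protein=protein,
            run=run,
            features=list(mat.index),
            channels=list(mat.columns),
            values=mat.to_numpy(),
        )
        yield channels, prm


def summarize(ft: pd.DataFrame, impute: bool = True) -> pd.DataFrame:
    """Summarize a feature table into per-channel protein abundances.

    Parameters
    ----------
    ft:
        Canonical feature table (see :mod:`tmtdiff.io_psm`).
    impute:
        When True (default) apply :func:`aft_impute` before median polish;
        when False, median polish runs on observed cells only.
    """
    nfeat = ft.groupby("ProteinName")["Feature"].transform("nunique")
    rows = []

    # fast path: single-feature proteins pass through without polish/imputation
    single = ft[nfeat == 1]
    if not single.empty:
        observed_in_run = single.groupby(["ProteinName", "Run"])["Log2Intensity"].transform(
            lambda s: s.notna().any()
        )
        single = single[observed_in_run]
        block = pd.DataFrame(
            {
                "Protein": single["ProteinName"],
                "Mixture": single["Mixture"],
                "TechRepMixture": single["TechRepMixture"],
                "Run": single["Run"],
                "Channel": single["Channel"],
                "Condition": single["Condition"],
                "BioReplicate": single["BioReplicate"],
                "Abundance": single["Log2Intensity"],
                "NFeatures": 1,
            }
        )
        block = block.sort_values(["Protein", "Run", "Channel"], kind="mergesort")
        rows.append(block)

    for meta, prm in iter_protein_run_matrices(ft[nfeat > 1]):
        if np.isnan(prm.values).all():
            continue
        if impute:
            prm = aft_impute(prm)
        y, n_used = summarize_protein_run(prm)
        block = meta.copy()
        block["Protein"] = prm.protein
        block["Run"] = prm.run
        block["Abundance"] = y
        block["NFeatures"] = n_used
        rows.append(block[SUMMARY_COLUMNS])
    if not rows:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    out = pd.concat(rows, ignore_index=True)
    out = out.sort_values(["Protein", "Run", "Channel"], kind="mergesort")
    return out[SUMMARY_COLUMNS].reset_index(drop=True)


def write_summary_table(pst: pd.DataFrame, path) -> None:
    pst.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_summary_table(path) -> pd.DataFrame:
    pst = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("Protein", "Mixture", "TechRepMixture", "Run", "Channel",
                "Condition", "BioReplicate"):
        pst[col] = pst[col].astype(str)
    return pst
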