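"""Per-protein mixed-effects modeling, empirical-Bayes moderation, contrast
tests and multiplicity adjustment.

For designs with multiple mixtures and technical replicates the model is

    Y = mu + Mixture + TechRep(Mixture) + Condition + Subject + error

with Condition fixed and the remaining terms iid Gaussian random effects.
Simpler designs (or proteins whose data cannot support all terms) get
reduced models; the reduction rules are derived from the identifiability of
each random term given the design and the protein's observed data pattern
(a term needs at least two observed levels, and a term whose levels each
carry a single observation is confounded with the residual and folds into
it).  Residual variances are shrunk across proteins with the
standard log-variance moment-matching empirical-Bayes scheme, and contrasts
of condition effects are tested with moderated t-statistics on Satterthwaite
degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from tmtdiff.design import REFERENCE_CONDITION, ExperimentDesign
from tmtdiff.errors import ContrastError
from tmtdiff.mixed import _MAX_DF, MixedFitResult, VarCompModel

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "Protein", "Label", "log2FC", "SE", "DF", "tvalue", "pvalue",
    "adj.pvalue", "issue",
]

ISSUE_NONE = "none"
ISSUE_ONE_CONDITION = "oneConditionMissing"
ISSUE_COMPLETE_MISSING = "completeMissing"
ISSUE_UNESTIMABLE = "unestimableContrast"
ISSUE_FIT_FAILED = "fitFailed"

#: fallback order for dropping random terms from a singular/non-converged fit
_DROP_ORDER = ("techrep", "mixture", "subject")


@dataclass
class ModelSpec:
    has_mixture_effect: bool
    has_techrep_effect: bool
    has_subject_effect: bool
    label: str  # full | multi_mixture | single_mixture_techrep | single_run

    @property
    def random_terms(self) -> list:
        terms = []
        if self.has_mixture_effect:
            terms.append("mixture")
        if self.has_techrep_effect:
            terms.append("techrep")
        if self.has_subject_effect:
            terms.append("subject")
        return terms


@dataclass
class FitResult:
    protein: str
    model_used: str
    condition_estimates: dict = field(default_factory=dict)
    varcomps: dict = field(default_factory=dict)
    residual_df: float = np.nan
    sigma2: float = np.nan
    converged: bool = False
    singular: bool = False
    issue: str = ISSUE_NONE
    # internal handles for contrast computation
    _model: VarCompModel | None = None
    _fit: MixedFitResult | None = None
    _conditions: list = field(default_factory=list)


@dataclass
class EBPrior:
    d0: float  # prior degrees of freedom; 0 disables moderation, inf = full
    s0_sq: float

    @classmethod
    def identity(cls) -> "EBPrior":
        return cls(d0=0.0, s0_sq=np.nan)


def choose_model(design: ExperimentDesign, protein_pattern: pd.DataFrame | None = None) -> ModelSpec:
    """Select the model family from the design, then reduce it to what the
    protein's observed data can support.

    ``protein_pattern`` is the protein's non-missing summary rows (reference
    channels excluded); when omitted only the design-level choice is made.
    Any random term with fewer than two observed levels for the protein — or
    whose levels are confounded with single observations — is dropped.
    """
    M = design.n_mixtures
    some_t = design.max_techreps > 1
    if M > 1 and some_t:
        spec = ModelSpec(True, True, True, "full")
    elif M > 1:
        # single technical replicate: each subject measured once, so the
        # subject term is confounded with the residual and folds into it
        spec = ModelSpec(True, False, False, "multi_mixture")
    elif some_t:
        spec = ModelSpec(False, True, True, "single_mixture_techrep")
    else:
        return ModelSpec(False, False, False, "single_run")

    if protein_pattern is None or protein_pattern.empty:
        return spec

    pat = protein_pattern
    if spec.has_mixture_effect and pat["Mixture"].nunique() < 2:
        spec.has_mixture_effect = False
    if spec.has_techrep_effect:
        runs_per_mixture = pat.groupby("Mixture")["Run"].nunique()
        if not (runs_per_mixture > 1).any():
            spec.has_techrep_effect = False
    if spec.has_subject_effect:
        per_subject = pat.groupby("BioReplicate").size()
        if len(per_subject) < 2 or per_subject.max() < 2:
            spec.has_subject_effect = False
    return spec


def _build_design(rows: pd.DataFrame, terms: list):
    conditions = sorted(rows["Condition"].unique())
    cond_idx = {c: i for i, c in enumerate(conditions)}
    X = np.zeros((len(rows), len(conditions)))
    X[np.arange(len(rows)), rows["Condition"].map(cond_idx)] = 1.0
    codes = {
        "mixture": rows["Mixture"].to_numpy(),
        "techrep": rows["Run"].to_numpy(),
        "subject": rows["BioReplicate"].to_numpy(),
    }
    random_terms = {t: codes[t] for t in terms}
    return conditions, X, random_terms


def fit_protein(summaries: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """REML fit of one protein's normalized summaries.

    Reference-channel rows are excluded.  On a singular or non-converged fit
    the offending random terms are dropped in the order TechRep -> Mixture ->
    Subject and the model is refit.
    """
    protein = summaries["Protein"].iloc[0] if len(summaries) else ""
    rows = summaries[
        (summaries["Condition"].astype(str) != REFERENCE_CONDITION)
        & summaries["Abundance"].notna()
    ]
    if rows.empty:
        return FitResult(protein=protein, model_used=spec.label,
                         issue=ISSUE_COMPLETE_MISSING)
    if rows["Condition"].nunique() < 2:
        return FitResult(protein=protein, model_used=spec.label,
                         issue=ISSUE_ONE_CONDITION)

    terms = list(spec.random_terms)
    y = rows["Abundance"].to_numpy(dtype=float)
    singular_seen = False
    while True:
        conditions, X, random_terms = _build_design(rows, terms)
        if len(y) <= X.shape[1]:
            return FitResult(protein=protein, model_used=spec.label,
                             issue=ISSUE_FIT_FAILED)
        model = VarCompModel(y, X, random_terms)
        try:
            fit = model.fit()
        except (ValueError, np.linalg.LinAlgError):
            fit = None
        if fit is not None and fit.converged and not fit.singular:
            break
        if not terms:
            if fit is None:
                return FitResult(protein=protein, model_used=spec.label,
                                 issue=ISSUE_FIT_FAILED)
            break
        # drop singular terms first (in the fixed order), else the first term
        if fit is not None and fit.singular:
            singular_seen = True
            zeroed = {n for n, t in zip(model.names, fit.theta) if t < 1e-6}
            drop = next(t for t in _DROP_ORDER if t in terms and t in zeroed)
        else:
            drop = next(t for t in _DROP_ORDER if t in terms)
        terms.remove(drop)

    if fit.residual_df <= 0:
        return FitResult(protein=protein, model_used=spec.label,
                         issue=ISSUE_FIT_FAILED)
    estimates = dict(zip(conditions, fit.beta))
    return FitResult(
        protein=protein,
        model_used=spec.label,
        condition_estimates=estimates,
        varcomps=fit.varcomps,
        residual_df=fit.residual_df,
        sigma2=fit.sigma2,
        converged=True,
        singular=singular_seen,
        _model=model,
        _fit=fit,
        _conditions=conditions,
    )


# -- empirical Bayes ------------------------------------------------------


def _trigamma(x):
    return special.polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/x scale)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def estimate_eb_prior(ensemble) -> EBPrior:
    """Moment-matching of log residual variances to a scaled-F model.

    ``ensemble`` is an iterable of (sigma2_hat, residual_df) pairs.  Returns
    the prior (d0, s0_sq); d0 is infinite when the empirical spread of the
    log variances does not exceed pure sampling variation, and the identity
    prior (d0 = 0) when fewer than two usable variances exist.
    """
    pairs = [(s2, df) for s2, df in ensemble
             if np.isfinite(s2) and s2 > 0 and np.isfinite(df) and df > 0]
    if len(pairs) < 2:
        return EBPrior.identity()
    s2 = np.array([p[0] for p in pairs])
    df = np.array([p[1] for p in pairs])
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(_trigamma(df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return EBPrior(d0=float(d0), s0_sq=float(s0_sq))


def moderate(fit: FitResult, prior: EBPrior) -> tuple[float, float]:
    """Shrink the residual variance toward the prior.

    Returns (s2_tilde, df_prior_increment).  ``s2_tilde`` is the posterior
    variance (d0*s0 + df*s2)/(d0 + df); the df increment equals d0 (capped
    when infinite) and is added to the contrast degrees of freedom.
    """
    d0, s0 = prior.d0, prior.s0_sq
    s2, df = fit.sigma2, fit.residual_df
    if d0 == 0 or not np.isfinite(s0):
        return s2, 0.0
    if np.isinf(d0):
        return s0, _MAX_DF
    return (d0 * s0 + df * s2) / (d0 + df), d0


def test_contrast(fit: FitResult, moderated: tuple[float, float],
                  contrast: dict, label: str | None = None) -> dict:
    """Test a weighted comparison of condition effects for one protein.

    ``contrast`` maps condition -> weight with weights summing to zero;
    ``moderated`` is the (s2_tilde, df_increment) pair from :func:`moderate`.
    Returns one result row (dict) with the canonical columns.
    """
    weights = {c: w for c, w in contrast.items() if w != 0}
    if abs(sum(contrast.values())) > 1e-9:
        raise ContrastError(f"contrast weights must sum to zero: {contrast}")
    if label is None:
        pos = [c for c, w in weights.items() if w > 0]
        neg = [c for c, w in weights.items() if w < 0]
        label = " vs ".join(["+".join(pos), "+".join(neg)])
    row = {
        "Protein": fit.protein, "Label": label,
        "log2FC": np.nan, "SE": np.nan, "DF": np.nan, "tvalue": np.nan,
        "pvalue": np.nan, "adj.pvalue": np.nan, "issue": ISSUE_NONE,
    }
    if fit.issue != ISSUE_NONE:
        row["issue"] = fit.issue
        return row
    missing = [c for c in weights if c not in fit.condition_estimates]
    if missing:
        row["issue"] = ISSUE_ONE_CONDITION
        return row

    c_vec = np.array([weights.get(c, 0.0) for c in fit._conditions])
    fc = float(sum(w * fit.condition_estimates[c] for c, w in weights.items()))
    s2_tilde, df_inc = moderated

    model, mfit = fit._model, fit._fit
    var_unmod = model.contrast_variance(c_vec, mfit)
    if var_unmod <= 0:
        # noiseless data: zero estimated variance at every level
        row.update(log2FC=fc, SE=0.0, DF=float(fit.residual_df))
        if abs(fc) < 1e-10:
            row.update(tvalue=0.0, pvalue=1.0)
        else:
            row.update(tvalue=np.inf, pvalue=0.0)
        return row

    if model.k == 0:
        satt_df = float(fit.residual_df)
    else:
        satt_df = model.satterthwaite_df(c_vec, mfit)
    var_mod = model.contrast_variance(c_vec, mfit, sigma2=s2_tilde)
    df_total = float(min(satt_df + df_inc, _MAX_DF))
    se = float(np.sqrt(var_mod))
    t = fc / se
    p = float(2.0 * stats.t.sf(abs(t), df_total))
    row.update(log2FC=fc, SE=se, DF=df_total, tvalue=float(t), pvalue=p)
    return row


def adjust_bh(results: pd.DataFrame, per_label: bool = True) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment over testable proteins.

    Adjustment is computed within each comparison label (default) over rows
    with ``issue == "none"`` and a finite p-value; other rows keep a missing
    adjusted p-value.
    """
    out = results.copy()
    out["adj.pvalue"] = np.nan

    def _bh(p: np.ndarray) -> np.ndarray:
        m = p.size
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        return adj

    groups = out.groupby("Label").groups.items() if per_label else [("all", out.index)]
    for _, idx in groups:
        sub = out.loc[idx]
        ok = (sub["issue"] == ISSUE_NONE) & sub["pvalue"].notna()
        if ok.any():
            out.loc[sub.index[ok], "adj.pvalue"] = _bh(
                sub.loc[ok, "pvalue"].to_numpy(dtype=float)
            )
    return out


def testable_proteins(pst: pd.DataFrame) -> pd.Series:
    """Proteins with more than one summary value in more than one condition
    (reference channels excluded) — the precondition for any test."""
    endo = pst[(pst["Condition"].astype(str) != REFERENCE_CONDITION)
               & pst["Abundance"].notna()]
    per_cond = endo.groupby(["Protein", "Condition"]).size()
    gt1 = (per_cond > 1).groupby("Protein").sum()
    return gt1 > 1


def pairwise_contrasts(conditions) -> pd.DataFrame:
    """All-pairs contrast matrix (rows = labels, columns = conditions)."""
    conditions = list(conditions)
    rows = {}
    for i, a in enumerate(conditions):
        for b in conditions[i + 1:]:
            w = {c: 0.0 for c in conditions}
            w[a], w[b] = 1.0, -1.0
            rows[f"{a} vs {b}"] = w
    return pd.DataFrame.from_dict(rows, orient="index")[conditions]


def fit_proteins(
    pst: pd.DataFrame,
    design: ExperimentDesign,
    ablate_subject: bool = False,
) -> dict:
    """REML-fit every protein in a summary table.

    Untestable proteins get a :class:`FitResult` carrying only an issue code.
    ``ablate_subject`` deliberately removes the subject random effect from
    every chosen model (an ablation mode used to quantify the value of
    separating biological from technical variation).
    """
    testable = testable_proteins(pst)
    endo = pst[pst["Condition"].astype(str) != REFERENCE_CONDITION]
    fits: dict[str, FitResult] = {}
    for protein, rows in endo.groupby("Protein", sort=True):
        observed = rows[rows["Abundance"].notna()]
        if not testable.get(protein, False):
            if observed.empty:
                issue = ISSUE_COMPLETE_MISSING
            elif observed["Condition"].nunique() < 2:
                issue = ISSUE_ONE_CONDITION
            else:
                issue = ISSUE_UNESTIMABLE
            fits[protein] = FitResult(protein=protein, model_used="none", issue=issue)
            continue
        spec = choose_model(design, observed)
        if ablate_subject:
            spec.has_subject_effect = False
        fits[protein] = fit_protein(rows, spec)
    return fits


def group_comparison(
    pst: pd.DataFrame,
    design: ExperimentDesign,
    contrasts: pd.DataFrame | None = None,
    moderation: bool = True,
    ablate_subject: bool = False,
) -> pd.DataFrame:
    """Full inference pass: model choice, REML fits, EB moderation, contrast
    tests, and per-label BH adjustment.

    ``contrasts`` is a data frame with labels as index, conditions as columns
    and weights as entries; all pairwise comparisons are tested when omitted.
    Untestable proteins are reported with an issue code and excluded from the
    BH denominator.
    """
    if pst.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    if contrasts is None:
        contrasts = pairwise_contrasts(design.conditions)

    fits = fit_proteins(pst, design, ablate_subject=ablate_subject)

    if moderation:
        prior = estimate_eb_prior(
            (f.sigma2, f.residual_df) for f in fits.values() if f.converged
        )
    else:
        prior = EBPrior.identity()

    records = []
    for protein in sorted(fits):
        fit = fits[protein]
        mod = moderate(fit, prior) if fit.converged else (np.nan, 0.0)
        for label, weights in contrasts.iterrows():
            records.append(
                test_contrast(fit, mod, weights.to_dict(), label=label)
            )
    results = pd.DataFrame.from_records(records, columns=RESULT_COLUMNS)
    return adjust_bh(results, per_label=True)


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_contrasts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
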