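"""Synthetic TMT experiments with known ground truth.

Two generators mirror the two benchmark protocols used throughout the test
suite:

* :func:`simulate_controlled_mixture` builds a PSM-level spike-in experiment:
  a dilution series of spiked proteins (default concentrations 500 / 333 /
  250 / 62.5 fmol, i.e. conditions 1, 0.667, 0.5, 0.125) against a constant
  background, optionally with a pooled reference channel, multiple mixtures
  and technical replicate runs.

* :func:`add_biological_variation` augments protein summaries with a
  subject-level random effect: Z = Y + eps with eps ~ N(0, sigma_s^2) drawn
  once per (mixture, condition, bioreplicate) and shared by all technical
  replicates of that subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tmtdiff.design import REFERENCE_CONDITION
from tmtdiff.errors import SimulationConfigError

_TMT16 = [
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
    "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N",
]

DEFAULT_CONCENTRATIONS = (500.0, 333.0, 250.0, 62.5)
DEFAULT_CONDITIONS = ("1", "0.667", "0.5", "0.125")


def channel_names(n: int) -> list:
    if n <= len(_TMT16):
        return _TMT16[:n]
    return [f"channel_{i + 1:02d}" for i in range(n)]


@dataclass
class SimConfig:
    """Configuration of a controlled-mixture simulation."""

    n_mixtures: int = 5
    n_techreps: int = 3
    conditions: tuple = DEFAULT_CONDITIONS
    spike_concentrations: tuple = DEFAULT_CONCENTRATIONS
    bioreps_per_condition: object = 2  # int, or list of {condition: count} per mixture
    n_reference_channels: int = 2
    channels_per_run: int = 10
    n_proteins: int = 100
    n_spikein: int = 20
    features_per_protein: object = 3  # int or (lo, hi) inclusive uniform
    sigma_feature: float = 0.5
    sigma_channel_noise: float = 0.2
    sigma_mixture: float = 0.0
    sigma_run: float = 0.0
    sigma_s: float = 0.0
    missing_rate_random: float = 0.0
    mnar_threshold: float | None = None
    mnar_mode: str = "hard"  # "hard" censoring or "logistic" probability
    mnar_scale: float = 0.5
    reference_pool: bool = True
    base_mean: float = 16.0
    base_sd: float = 1.0
    seed: int = 0

    def bioreps_for(self, mixture_index: int) -> dict:
        if isinstance(self.bioreps_per_condition, (list, tuple)):
            return dict(self.bioreps_per_condition[mixture_index])
        return {c: int(self.bioreps_per_condition) for c in self.conditions}

    def validate(self) -> None:
        if self.n_mixtures < 1 or self.n_techreps < 1:
            raise SimulationConfigError("need at least one mixture and one techrep")
        if len(self.conditions) < 2:
            raise SimulationConfigError("need at least two conditions")
        if len(self.spike_concentrations) != len(self.conditions):
            raise SimulationConfigError(
                "spike_concentrations must have one entry per condition"
            )
        if any(c <= 0 for c in self.spike_concentrations):
            raise SimulationConfigError("spike concentrations must be positive")
        if not 0 <= self.n_spikein <= self.n_proteins:
            raise SimulationConfigError("n_spikein must be within [0, n_proteins]")
        if not 0.0 <= self.missing_rate_random <= 1.0:
            raise SimulationConfigError("missing_rate_random must be in [0, 1]")
        for name in ("sigma_feature", "sigma_channel_noise", "sigma_mixture",
                     "sigma_run", "sigma_s"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name} must be nonnegative")
        if isinstance(self.bioreps_per_condition, (list, tuple)) and len(
            self.bioreps_per_condition
        ) != self.n_mixtures:
            raise SimulationConfigError(
                "per-mixture biorep counts must list every mixture"
            )
        for m in range(self.n_mixtures):
            need = sum(self.bioreps_for(m).values()) + self.n_reference_channels
            if need > self.channels_per_run:
                raise SimulationConfigError(
                    f"mixture {m + 1} needs {need} channels but runs have "
                    f"{self.channels_per_run}"
                )


def allocate_design(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Randomly assign condition x bioreplicate slots to channels per mixture.

    All technical replicate runs of a mixture share the channel assignment.
    Extra channels beyond the required slots stay unused.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chans = channel_names(cfg.channels_per_run)
    rows = []
    for m in range(cfg.n_mixtures):
        mixture = f"Mixture{m + 1}"
        slots = []
        for cond in cfg.conditions:
            for b in range(cfg.bioreps_for(m)[cond]):
                slots.append((cond, f"{mixture}_{cond}_B{b + 1}"))
        for r in range(cfg.n_reference_channels):
            slots.append((REFERENCE_CONDITION, f"{mixture}_pool"))
        order = rng.permutation(len(chans))[: len(slots)]
        assigned = [chans[i] for i in sorted(order)]
        shuffled = rng.permutation(len(slots))
        for chan, j in zip(assigned, shuffled):
            cond, biorep = slots[j]
            for t in range(cfg.n_techreps):
                rows.append(
                    {
                        "Run": f"{mixture}_TechRep{t + 1}",
                        "Channel": chan,
                        "Condition": cond,
                        "BioReplicate": biorep,
                        "Mixture": mixture,
                        "TechRepMixture": f"TechRep{t + 1}",
                    }
                )
    ann = pd.DataFrame(rows).sort_values(
        ["Mixture", "TechRepMixture", "Channel"], kind="mergesort"
    )
    return ann.reset_index(drop=True)


def _feature_counts(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.features_per_protein, (tuple, list)):
        lo, hi = cfg.features_per_protein
        return rng.integers(lo, hi + 1, size=cfg.n_proteins)
    return np.full(cfg.n_proteins, int(cfg.features_per_protein))


def simulate_controlled_mixture(cfg: SimConfig):
    """Generate (psm, annotation, truth) tables for a spike-in experiment.

    Spiked proteins receive a per-condition offset of log2 of the condition's
    concentration (relative to the largest), the reference channel carries
    the pooled mean concentration, and background proteins are flat.  The
    output is reproducible for a fixed config and seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ann = allocate_design(cfg, rng)

    concs = np.asarray(cfg.spike_concentrations, dtype=float)
    ref_conc = concs.mean()
    top = concs.max()
    cond_offset = {c: float(np.log2(k / top)) for c, k in zip(cfg.conditions, concs)}
    cond_offset[REFERENCE_CONDITION] = (
        float(np.log2(ref_conc / top)) if cfg.reference_pool else 0.0
    )

    n_spike = cfg.n_spikein
    proteins = [f"UPS_{i + 1:04d}" for i in range(n_spike)] + [
        f"BG_{i + 1:04d}" for i in range(cfg.n_proteins - n_spike)
    ]
    is_spike = np.array([p.startswith("UPS_") for p in proteins])

    bases = rng.normal(cfg.base_mean, cfg.base_sd, size=cfg.n_proteins)
    fcounts = _feature_counts(cfg, rng)
    feat_effects = [rng.normal(0.0, cfg.sigma_feature, size=f) for f in fcounts]

    runs = ann[["Run", "Mixture", "TechRepMixture"]].drop_duplicates().reset_index(drop=True)
    n_runs = len(runs)
    mix_ids = sorted(ann["Mixture"].unique())
    mix_eff = rng.normal(0.0, cfg.sigma_mixture, size=(cfg.n_proteins, len(mix_ids)))
    run_eff = rng.normal(0.0, cfg.sigma_run, size=(cfg.n_proteins, n_runs))
    mix_of_run = [mix_ids.index(m) for m in runs["Mixture"]]

    # one "cell" per (run, channel); layouts are constant across techreps of
    # a mixture but may differ between mixtures
    cells = ann.sort_values(["Run", "Channel"], kind="mergesort").reset_index(drop=True)
    n_cells = len(cells)
    run_order = {run: i for i, run in enumerate(runs["Run"])}
    cell_run = cells["Run"].map(run_order).to_numpy()
    cell_mix = np.array([mix_of_run[r] for r in cell_run])
    cell_offs_spike = cells["Condition"].map(cond_offset).to_numpy(dtype=float)

    frames = []
    for p_idx, protein in enumerate(proteins):
        F = int(fcounts[p_idx])
        offs = cell_offs_spike if is_spike[p_idx] else np.zeros(n_cells)
        mu = bases[p_idx] + mix_eff[p_idx, cell_mix] + run_eff[p_idx, cell_run]
        noise = rng.normal(0.0, cfg.sigma_channel_noise, size=(F, n_cells))
        x = mu[None, :] + feat_effects[p_idx][:, None] + offs[None, :] + noise
        # feature-level missing completely at random: the whole run drops
        mcar = rng.random((F, n_runs)) < cfg.missing_rate_random
        x[mcar[:, cell_run]] = np.nan
        if cfg.mnar_threshold is not None:
            if cfg.mnar_mode == "hard":
                x[x < cfg.mnar_threshold] = np.nan
            else:
                with np.errstate(over="ignore", invalid="ignore"):
                    pmiss = 1.0 / (
                        1.0 + np.exp((x - cfg.mnar_threshold) / cfg.mnar_scale)
                    )
                x[rng.random(x.shape) < np.nan_to_num(pmiss)] = np.nan
        feat_names = np.array([f"{protein}_pep{f + 1}_2" for f in range(F)])
        ions = np.repeat(feat_names, n_cells)
        run_col = np.tile(cells["Run"].to_numpy(), F)
        frames.append(
            pd.DataFrame(
                {
                    "ProteinName": protein,
                    "PeptideIon": ions,
                    "PSM": np.char.add(np.char.add(ions.astype(str), "_"),
                                       run_col.astype(str)),
                    "Run": run_col,
                    "Fraction": np.nan,
                    "Channel": np.tile(cells["Channel"].to_numpy(), F),
                    "Intensity": np.exp2(x).ravel(),
                    "Interference": np.nan,
                }
            )
        )
    psm = pd.concat(frames, ignore_index=True)

    truth = ground_truth_table(cfg, proteins)
    return psm, ann, truth


def ground_truth_table(cfg: SimConfig, proteins=None) -> pd.DataFrame:
    """Per (protein, ordered condition pair) true fold changes."""
    if proteins is None:
        proteins = [f"UPS_{i + 1:04d}" for i in range(cfg.n_spikein)] + [
            f"BG_{i + 1:04d}" for i in range(cfg.n_proteins - cfg.n_spikein)
        ]
    conc = dict(zip(cfg.conditions, cfg.spike_concentrations))
    rows = []
    for protein in proteins:
        spike = protein.startswith("UPS_")
        for a in cfg.conditions:
            for b in cfg.conditions:
                if a == b:
                    continue
                fc = conc[a] / conc[b] if spike else 1.0
                rows.append(
                    {
                        "Protein": protein,
                        "Label": f"{a} vs {b}",
                        "TrueFC": fc,
                        "TrueLog2FC": float(np.log2(fc)),
                        "Differential": bool(spike),
                    }
                )
    return pd.DataFrame(rows)


def add_biological_variation(
    pst: pd.DataFrame, sigma_s: float, seed: int = 0
) -> pd.DataFrame:
    """Add a subject-level random shift shared by all technical replicates.

    eps ~ N(0, sigma_s^2) is drawn once per (protein, mixture, condition,
    bioreplicate) and added to every technical-replicate summary of that
    subject.  Reference-channel summaries are untouched.
    """
    if sigma_s < 0:
        raise ValueError("sigma_s must be nonnegative")
    out = pst.copy()
    if sigma_s == 0:
        return out
    rng = np.random.default_rng(seed)
    endo = out["Condition"].astype(str) != REFERENCE_CONDITION
    keys = (
        out.loc[endo, ["Protein", "Mixture", "Condition", "BioReplicate"]]
        .drop_duplicates()
        .sort_values(["Protein", "Mixture", "Condition", "BioReplicate"],
                     kind="mergesort")
        .reset_index(drop=True)
    )
    keys["_eps"] = rng.normal(0.0, sigma_s, size=len(keys))
    out = out.merge(
        keys, on=["Protein", "Mixture", "Condition", "BioReplicate"], how="left"
    )
    out["_eps"] = out["_eps"].fillna(0.0)
    out["Abundance"] = out["Abundance"] + out["_eps"]
    return out.drop(columns="_eps")
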