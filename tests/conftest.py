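import pandas as pd
import pytest

from tmtdiff import io_psm, summarization
from tmtdiff.normalization import global_median_normalize, reference_channel_normalize
from tmtdiff.simulator import SimConfig, add_biological_variation, simulate_controlled_mixture


def make_psm(rows):
    """PSM frame from (protein, ion, psm, run, fraction, channel, intensity,
    interference) tuples; None entries become NaN."""
    df = pd.DataFrame(
        rows,
        columns=["ProteinName", "PeptideIon", "PSM", "Run", "Fraction",
                 "Channel", "Intensity", "Interference"],
    )
    for col in ("ProteinName", "PeptideIon", "PSM", "Run", "Channel"):
        df[col] = df[col].astype(str)
    return df


def make_annotation(runs, channels, conditions, mixtures=None, techreps=None,
                    bioreps=None):
    """Annotation frame; per-run channel -> condition mapping given as dict."""
    rows = []
    for i, run in enumerate(runs):
        for j, ch in enumerate(channels):
            cond = conditions[j] if isinstance(conditions, (list, tuple)) else conditions[ch]
            rows.append({
                "Run": run,
                "Channel": ch,
                "Condition": cond,
                "BioReplicate": bioreps[(run, ch)] if bioreps else f"{run}_{ch}",
                "Mixture": mixtures[i] if mixtures else f"Mix{i + 1}",
                "TechRepMixture": techreps[i] if techreps else "T1",
            })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_sim():
    """A small spike-in simulation shared by read-only tests."""
    cfg = SimConfig(
        n_proteins=40, n_spikein=10, seed=42, features_per_protein=(1, 4),
        sigma_channel_noise=0.15,
    )
    psm, ann, truth = simulate_controlled_mixture(cfg)
    return cfg, psm, ann, truth


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    """Feature table, summaries and design for the small simulation."""
    cfg, psm, ann, truth = small_sim
    ft, design = io_psm.build_feature_table(psm, ann)
    ft = global_median_normalize(ft)
    pst = summarization.summarize(ft)
    pst = reference_channel_normalize(pst)
    return ft, pst, design, truth
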